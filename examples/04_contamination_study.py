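"""Run a reduced contamination study and build a CRC-vs-99mTc curve.

Runs the HE-collimator arm of the experiment schedule (0%, 6% and 13% 99mTc)
in the 90-120 and 160-200 keV windows with plain OSEM, prints the CRC table,
the 37 mm contamination curves, and the qualitative trend checks that are
evaluable on this subset. The full study (all six experiments, three windows,
both reconstructions) is `run_study(StudyConfig())`, ~2 min on one CPU.
"""

import bremspect as bs
from bremspect.iq import SphereCRC
from bremspect.study import StudyConfig, run_study

cfg = StudyConfig(
    rows=(1, 4, 5),             # HE experiments: 0%, 13%, 6% 99mTc
    windows=("90-120", "160-200"),
    modes=("local_site",),
    seed=2026,
)
report = run_study(cfg)
t = report.table
print(t[t.sphere_mm == 37.0][
    ["experiment", "window", "percent_tc", "crc_mean", "crc_sd"]
].to_string(index=False))

for window in cfg.windows:
    aggs = []
    for exp in cfg.rows:
        sel = t[(t.experiment == exp) & (t.window == window) & (t.sphere_mm == 37.0)]
        crc, sd, pct = (float(sel.crc_mean.iloc[0]), float(sel.crc_sd.iloc[0]),
                        int(sel.percent_tc.iloc[0]))
        res = bs.CRCResult(
            per_sphere={37.0: SphereCRC(37.0, 0.0, 1.0, crc)}, R=7.9,
            keys={"percent_tc": pct},
        )
        res.crc_mean, res.crc_sd = {37.0: crc}, {37.0: sd}
        aggs.append(res)
    curve = bs.crc_vs_contamination(aggs, 37.0)
    pts = ", ".join(f"{p[0]}%: {p[1]:.3f}+-{p[2]:.3f}" for p in curve.points)
    print(f"\n37 mm CRC vs contamination, {window} keV/HE: {pts}")

print("\ntrend checks on this subset (None = needs combinations not run here):")
for tr in report.trend_results:
    print(f"  {tr.name} passed={tr.passed}  {tr.evidence}")
print("\nReading: in 90-120 keV the CRC collapses with a few percent 99mTc;")
print("in 160-200 keV it declines only incrementally - the robust window.")
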