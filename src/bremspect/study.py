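"""Orchestration of the full image-quality study.

Runs simulate -> reconstruct -> analyze over the experiment schedule (six
acquisitions, three energy windows each, HE/ME collimators, 0-15% 99mTc in the
background) and evaluates the qualitative findings as explicit trend checks:

T-a  standard-window (90-120 keV, HE) CRC collapses (ratio < 0.5) from 0% to ~5% Tc
T-b  160-200 keV / HE CRC changes by < 15% relative between 0% and ~5% Tc
T-c  HE CRC >= ME CRC at matched settings
T-d  200-250 keV CRC < 160-200 keV CRC for 90Y-only
T-e  model-compensating reconstruction beats plain OSEM at matched settings
T-f  160-200 keV CRC decreases monotonically with contamination 0% -> ~5% -> ~14%

Trend thresholds are package-level acceptance gates motivated by, not equal
to, physical-scanner CRC values, which a kernel-based simulator does not
reproduce in absolute magnitude.
"""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .acquisition import (
    AcquisitionProtocol,
    ExperimentRow,
    SystemModel,
    TABLE1_SCHEDULE,
    collimator_by_kind,
    forward_project,
    load_schedule,
    make_system,
    simulate_experiment,
)
from .errors import BremspectError, DomainError
from .iq import DEFAULT_R, DEFAULT_REPORT_SPHERES_MM, aggregate_reps, build_vois, compute_crc
from .phantom import (
    CompartmentActivity,
    VoxelGrid,
    build_phantom_geometry,
    compartment_occupancies,
    voxelize_activity,
    voxelize_attenuation,
)
from .reconstruction import (
    ReconConfig,
    ReconVolume,
    SinogramSet,
    advanced_config,
    advanced_recon,
    local_site_config,
    osem,
    postfilter,
)
from .spectra import STUDY_WINDOWS, technetium99m, yttrium90

log = logging.getLogger("bremspect.study")

MODES = ("local_site", "advanced")


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions; defaults are the package's desk-scale defaults."""

    n_xy: int = 64
    n_z: int = 16
    spacing_xy_mm: float = 4.8
    spacing_z_mm: float = 6.0
    axial_length_mm: float = 90.0
    n_views: int = 64
    seed: int = 1234
    repetitions: int | None = None  # None -> per schedule row
    rows: tuple | None = None  # experiment ids to run; None -> all
    windows: tuple = tuple(w.label for w in STUDY_WINDOWS)
    modes: tuple = MODES
    iterations: int = 10
    subsets: int = 8
    post_filter_fwhm_mm: float = 5.0
    tc_enabled: bool = True  # negative-control switch: drop Tc from simulation
    supersample: int = 3
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("rows", "windows", "modes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
            sort_keys=True,
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class TrendResult:
    name: str
    description: str
    passed: bool | None  # None -> not evaluable
    evidence: str


@dataclass
class StudyReport:
    table: pd.DataFrame
    config: StudyConfig
    trend_results: list = field(default_factory=list)
    failures: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def crc_table_csv(self) -> str:
        return self.table.to_csv(index=False, float_format="%.8g")


def _grid(config: StudyConfig) -> VoxelGrid:
    return VoxelGrid.centered(
        (config.n_xy, config.n_xy, config.n_z),
        (config.spacing_xy_mm, config.spacing_xy_mm, config.spacing_z_mm),
    )


def build_row_maps(geometry, grid, row: ExperimentRow, occs=None, tc_enabled=True):
    """Activity maps scaled to a schedule row's effective activities.

    90Y fills spheres (2.37 MBq/mL) and background (0.30 MBq/mL); the whole map
    is rescaled so its total equals the row's A_eff. 99mTc goes in the
    background compartment only, scaled to its A_eff.
    """
    y90, tc = yttrium90(), technetium99m()
    y90_map = voxelize_activity(
        geometry, CompartmentActivity(isotope="Y90"), grid, occs=occs
    )
    target = row.aeff_y90_gbq * 1000.0
    if y90_map.total_mbq > 0:
        y90_map.values *= target / y90_map.total_mbq
    maps = {y90: y90_map}
    if tc_enabled and row.aeff_tc_mbq > 0:
        tc_map = voxelize_activity(
            geometry,
            CompartmentActivity(
                isotope="Tc99m", sphere_concentration=0.0, background_concentration=1.0
            ),
            grid,
            occs=occs,
        )
        tc_map.values *= row.aeff_tc_mbq / tc_map.total_mbq
        maps[tc] = tc_map
    return maps


def _window_by_label(label: str):
    for w in STUDY_WINDOWS:
        if w.label == label:
            return w
    raise DomainError(f"unknown window label {label!r}")


def _tc_expected_sinogram(sinos: SinogramSet, maps, mu, window, protocol, system):
    """Oracle 99mTc crosstalk expectation in one window (None if no Tc)."""
    for iso, amap in maps.items():
        if iso.name == "Tc99m" and amap.total_mbq > 0:
            return forward_project(amap, mu, protocol, window, iso, system=system)
    return None


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulate -> reconstruct -> analyze pipeline.

    Returns a report whose table has one row per
    experiment x window x mode x sphere, with repetition mean and SD of CRC.
    Partial failures are logged and collected; remaining combinations run.
    """
    t_start = time.time()
    geometry = build_phantom_geometry(axial_length=config.axial_length_mm)
    grid = _grid(config)
    occs = compartment_occupancies(geometry, grid, config.supersample)
    vois = build_vois(geometry, grid, supersample=config.supersample)
    schedule = [
        r for r in load_schedule()
        if config.rows is None or r.exp_id in config.rows
    ]
    if config.repetitions is not None:
        schedule = [replace(r, repetitions=config.repetitions) for r in schedule]
    windows = [_window_by_label(lb) for lb in config.windows]

    mu_maps = {
        w.label: voxelize_attenuation(
            geometry, grid, (w.low + w.high) / 2.0, occs=occs
        )
        for w in windows
    }

    protocols = {}
    sim_systems = {}
    recon_systems = {}
    for kind in sorted({r.collimator_kind for r in schedule}):
        coll = collimator_by_kind(kind)
        protocols[kind] = AcquisitionProtocol(
            collimator=coll, windows=tuple(windows), n_views=config.n_views
        )
        for w in windows:
            sim_systems[(kind, w.label)] = make_system(
                grid, mu_maps[w.label], protocols[kind], w
            )
    for w in windows:
        # plain OSEM projector: attenuation only, shared across collimators
        recon_systems[("local_site", w.label)] = SystemModel(
            grid,
            n_views=config.n_views,
            mu=mu_maps[w.label],
            attenuation=True,
            cdr=False,
            septal=False,
            flat=False,
        )

    local_cfg = replace(
        local_site_config(),
        iterations=config.iterations,
        subsets=config.subsets,
        post_filter_fwhm_mm=config.post_filter_fwhm_mm,
    )
    adv_cfg = replace(
        advanced_config(), iterations=config.iterations, subsets=config.subsets
    )

    records = []
    failures = []
    for row in schedule:
        protocol = replace(protocols[row.collimator_kind], scan_time_min=row.scan_time_min)
        maps = build_row_maps(geometry, grid, row, occs=occs, tc_enabled=config.tc_enabled)
        seed_row = config.seed + 1000 * row.exp_id
        t0 = time.time()
        reps = simulate_experiment(row, maps, mu_maps, protocol, seed_row,
                                   systems=sim_systems)
        log.info("exp %d simulated in %.1fs", row.exp_id, time.time() - t0)
        for window in windows:
            sim_sys = sim_systems[(row.collimator_kind, window.label)]
            tc_exp = _tc_expected_sinogram(reps[0], maps, mu_maps[window.label],
                                           window, protocol, sim_sys)
            for mode in config.modes:
                try:
                    results = []
                    for rep_i, sino in enumerate(reps):
                        if mode == "local_site":
                            vol = osem(sino, window,
                                       recon_systems[("local_site", window.label)],
                                       local_cfg)
                            vol = postfilter(vol, local_cfg.post_filter_fwhm_mm)
                        else:
                            models = {"mu": mu_maps[window.label],
                                      "tc_expected": tc_exp if tc_exp is not None else np.zeros(1)}
                            vol = advanced_recon(sino, window, models, adv_cfg)
                        keys = {
                            "experiment": row.exp_id,
                            "label": row.label,
                            "window": window.label,
                            "collimator": row.collimator_kind,
                            "mode": mode,
                            "percent_tc": row.percent_tc,
                        }
                        results.append(compute_crc(vol, vois, DEFAULT_R, keys=keys))
                    agg = aggregate_reps(results)
                    for d in sorted(agg.per_sphere):
                        records.append(
                            dict(agg.keys, sphere_mm=d,
                                 crc_mean=agg.crc_mean[d], crc_sd=agg.crc_sd[d],
                                 c_s=agg.per_sphere[d].c_s, c_b=agg.per_sphere[d].c_b,
                                 n_reps=agg.n_reps)
                        )
                except BremspectError as exc:
                    msg = (f"exp {row.exp_id} window {window.label} mode {mode}: {exc}")
                    log.error("failed: %s", msg)
                    failures.append(msg)
        log.info("exp %d done in %.1fs", row.exp_id, time.time() - t0)

    table = pd.DataFrame.from_records(records)
    if len(table):
        table = table.sort_values(
            ["experiment", "window", "mode", "sphere_mm"]
        ).reset_index(drop=True)
    report = StudyReport(
        table=table,
        config=config,
        failures=failures,
        provenance={
            "config_hash": config.config_hash,
            "package_version": _pkg_version,
            "runtime_s": round(time.time() - t_start, 1),
        },
    )
    report.trend_results = trend_checks(report)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "crc_table.csv").write_text(report.crc_table_csv())
        (out / "study_report.yaml").write_text(
            yaml.safe_dump(
                {
                    "provenance": report.provenance,
                    "config": yaml.safe_load(config.to_yaml()),
                    "failures": failures,
                    "trend_checks": [
                        {"name": t.name, "passed": t.passed, "evidence": t.evidence}
                        for t in report.trend_results
                    ],
                },
                sort_keys=True,
            )
        )
    return report


def parameter_recovery(
    config: StudyConfig | None = None,
    window_label: str = "160-200",
    iterations: int = 100,
    subsets: int = 16,
) -> dict:
    """Inverse-crime recovery check on noiseless, matched-model data.

    Simulates a 90Y-only acquisition (schedule row 1), feeds the noiseless
    expectation to the model-compensating reconstruction with the exact
    simulator models, and reports how well it recovers (a) the background
    activity concentration in the annulus VOI and (b) the 37 mm sphere CRC
    relative to the CRC of the true voxelized activity map.

    The check runs with a matched moderate-resolution collimator (distance
    slope 0.15 mm/cm instead of the HE study value 0.42): it validates that
    the compensating reconstruction inverts its own forward model, which
    requires conditions under which EM resolution recovery converges within a
    practical iteration budget. Under the full HE blur the same fixed point
    exists but is approached only asymptotically (see docs/methods.md).
    """
    config = config or StudyConfig()
    geometry = build_phantom_geometry(axial_length=config.axial_length_mm)
    grid = _grid(config)
    occs = compartment_occupancies(geometry, grid, config.supersample)
    vois = build_vois(geometry, grid, supersample=config.supersample)
    window = _window_by_label(window_label)
    mu = voxelize_attenuation(geometry, grid, (window.low + window.high) / 2.0, occs=occs)
    row = load_schedule()[0]
    base = collimator_by_kind(row.collimator_kind)
    collimator = replace(base, sigma_slope_mm_per_cm=0.15)
    protocol = AcquisitionProtocol(
        collimator=collimator,
        windows=(window,),
        scan_time_min=row.scan_time_min,
        n_views=config.n_views,
    )
    maps = build_row_maps(geometry, grid, row, occs=occs)
    (y90, y90_map), = maps.items()
    system = make_system(grid, mu, protocol, window)
    expected = forward_project(y90_map, mu, protocol, window, y90, system=system)
    noiseless = SinogramSet(
        counts=expected[None], expected=expected[None], windows=(window,),
        protocol=protocol, row=row, seed=0, grid=grid,
    )
    adv = replace(
        advanced_config(),
        iterations=iterations,
        subsets=subsets,
        crosstalk_compensation=False,  # 90Y-only input
    )
    vol = advanced_recon(noiseless, window, {"mu": mu}, adv)

    bg = vois.background_weights
    bg_recon = float((bg * vol.values).sum() / bg.sum())
    bg_true = float((bg * y90_map.values).sum() / bg.sum())
    bg_err = abs(bg_recon - bg_true) / bg_true

    truth_vol = ReconVolume(grid=grid, values=y90_map.values)
    crc_truth = compute_crc(truth_vol, vois, DEFAULT_R).crc_mean[37.0]
    crc_recon = compute_crc(vol, vois, DEFAULT_R).crc_mean[37.0]
    return {
        "background_true_mbq_ml": bg_true,
        "background_recon_mbq_ml": bg_recon,
        "background_rel_error": bg_err,
        "crc37_truth": crc_truth,
        "crc37_recon": crc_recon,
        "crc37_ratio": crc_recon / crc_truth,
    }


# ---------------------------------------------------------------------------
# Trend checks
# ---------------------------------------------------------------------------


def _crc(table, exp, window, mode, sphere=37.0):
    sel = table[
        (table["experiment"] == exp)
        & (table["window"] == window)
        & (table["mode"] == mode)
        & (table["sphere_mm"] == sphere)
    ]
    if len(sel) != 1:
        return None
    return float(sel.crc_mean.iloc[0])


def trend_checks(report: StudyReport) -> list:
    """Evaluate the six qualitative findings on the study table.

    A check whose required combinations are missing is reported as
    not-evaluable (passed=None), never silently passed.
    """
    t = report.table
    checks = []

    def add(name, desc, passed, evidence):
        checks.append(TrendResult(name, desc, passed, evidence))

    def not_eval(name, desc, what):
        add(name, desc, None, f"not evaluable: missing {what}")

    if not len(t):
        for name in ("T-a", "T-b", "T-c", "T-d", "T-e", "T-f"):
            not_eval(name, "", "all results")
        return checks

    # T-a: standard window collapses with ~5% Tc
    ref = _crc(t, 1, "90-120", "local_site")
    deg = _crc(t, 5, "90-120", "local_site")
    desc = "90-120 keV/HE CRC collapses (ratio < 0.5) from 0% to ~5% Tc (37 mm)"
    if ref is None or deg is None:
        not_eval("T-a", desc, "exp 1/5, 90-120 keV, local_site")
    else:
        ratio = deg / ref if ref > 0 else float("inf")
        add("T-a", desc, bool(ref > 0 and ratio < 0.5),
            f"CRC {ref:.3f} -> {deg:.3f}, ratio {ratio:.2f} (gate < 0.5)")

    # T-b: optimized window robust to ~5% Tc
    ref = _crc(t, 1, "160-200", "local_site")
    deg = _crc(t, 5, "160-200", "local_site")
    desc = "160-200 keV/HE CRC changes < 15% relative between 0% and ~5% Tc (37 mm)"
    if ref is None or deg is None:
        not_eval("T-b", desc, "exp 1/5, 160-200 keV, local_site")
    else:
        rel = abs(ref - deg) / ref if ref > 0 else float("inf")
        add("T-b", desc, bool(rel < 0.15),
            f"CRC {ref:.3f} vs {deg:.3f}, relative change {100*rel:.1f}% (gate < 15%)")

    # T-c: HE >= ME at matched settings (local_site OSEM)
    desc = "HE CRC >= ME CRC at matched settings (37 mm, OSEM)"
    pairs = [(1, 2, ("90-120", "160-200", "200-250")),
             (5, 6, ("160-200", "200-250"))]
    lines, ok, seen = [], True, False
    for he_exp, me_exp, wins in pairs:
        for w in wins:
            he = _crc(t, he_exp, w, "local_site")
            me = _crc(t, me_exp, w, "local_site")
            if he is None or me is None:
                continue
            seen = True
            ok = ok and (he >= me)
            lines.append(f"{w} exp{he_exp}/{me_exp}: HE {he:.3f} vs ME {me:.3f}")
    if not seen:
        not_eval("T-c", desc, "matched HE/ME pairs")
    else:
        add("T-c", desc, bool(ok), "; ".join(lines))

    # T-d: 200-250 < 160-200 for 90Y-only
    desc = "200-250 keV CRC < 160-200 keV CRC for 90Y-only (37 mm, OSEM)"
    lines, ok, seen = [], True, False
    for exp in (1, 2):
        lo = _crc(t, exp, "160-200", "local_site")
        hi = _crc(t, exp, "200-250", "local_site")
        if lo is None or hi is None:
            continue
        seen = True
        ok = ok and (hi < lo)
        lines.append(f"exp{exp}: 160-200 {lo:.3f} vs 200-250 {hi:.3f}")
    if not seen:
        not_eval("T-d", desc, "90Y-only rows in both upper windows")
    else:
        add("T-d", desc, bool(ok), "; ".join(lines))

    # T-e: advanced recon beats OSEM at matched settings
    desc = "model-compensating recon CRC > OSEM CRC at matched settings (37 mm)"
    lines, ok, seen = [], True, False
    for exp in (1, 5):
        for w in ("90-120", "160-200", "200-250"):
            o = _crc(t, exp, w, "local_site")
            a = _crc(t, exp, w, "advanced")
            if o is None or a is None:
                continue
            seen = True
            ok = ok and (a > o)
            lines.append(f"exp{exp} {w}: adv {a:.3f} vs osem {o:.3f}")
    if not seen:
        not_eval("T-e", desc, "matched local_site/advanced pairs")
    else:
        add("T-e", desc, bool(ok), "; ".join(lines))

    # T-f: monotone CRC decrease with contamination in 160-200 keV
    desc = "160-200 keV CRC decreases monotonically with Tc 0% -> ~5% -> ~14% (37 mm)"
    series = {"HE": (1, 5, 4), "ME": (2, 6, 3)}
    lines, ok, seen = [], True, False
    for kind, exps in series.items():
        vals = [_crc(t, e, "160-200", "local_site") for e in exps]
        if any(v is None for v in vals):
            continue
        seen = True
        ok = ok and (vals[0] > vals[1] > vals[2])
        lines.append(
            kind + ": " + " > ".join(f"{v:.3f}" for v in vals)
        )
    if not seen:
        not_eval("T-f", desc, "contamination series in 160-200 keV")
    else:
        add("T-f", desc, bool(ok), "; ".join(lines))

    return checks
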