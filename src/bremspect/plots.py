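"""Figure-analog plots: CRC by sphere diameter and CRC vs contamination."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .iq import DEFAULT_REPORT_SPHERES_MM


def plot_crc_by_sphere(table, window: str, mode: str, path,
                       spheres=DEFAULT_REPORT_SPHERES_MM):
    """CRC vs sphere diameter, one errorbar series per experiment."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sel = table[(table["window"] == window) & (table["mode"] == mode)
                & table["sphere_mm"].isin(spheres)]
    for exp, grp in sel.groupby("experiment"):
        grp = grp.sort_values("sphere_mm")
        label = (f"exp {exp} ({grp['collimator'].iloc[0]}, "
                 f"{grp['percent_tc'].iloc[0]}% Tc)")
        ax.errorbar(grp["sphere_mm"], grp["crc_mean"], yerr=grp["crc_sd"],
                    marker="o", capsize=3, label=label)
    ax.set_xlabel("sphere diameter (mm)")
    ax.set_ylabel("CRC")
    ax.set_title(f"{window} keV, {mode}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contamination_curve(curve, path):
    """CRC vs percent 99mTc for one sphere (errorbars = repetition SD)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    pct = [p[0] for p in curve.points]
    mean = [p[1] for p in curve.points]
    sd = [p[2] for p in curve.points]
    ax.errorbar(pct, mean, yerr=sd, marker="s", capsize=3)
    ax.set_xlabel("99mTc activity (% of 90Y)")
    ax.set_ylabel("CRC")
    ax.set_title(f"{curve.diameter_mm:.0f} mm sphere")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
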