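"""Image-quality analysis: VOIs, contrast recovery coefficients, curves.

CRC = ((C_S / C_B) - 1) / (R - 1), the measured sphere-to-background contrast
normalized by the nominal true contrast, with R the nominal sphere-to-
background activity-concentration ratio (2.37 / 0.30 = 7.9 by default).

VOIs are placed analytically from the known digital-phantom geometry (no image
registration). Sphere VOIs are fractional-occupancy masks matching the known
sphere volumes; the sphere mean uses a boundary-corrected occupancy-weighted
estimator that is exact on the true voxelized map, so CRC of the noiseless
unblurred activity map is 1 by construction. The background VOI is an annulus
around the lung insert on slices adjacent to (axially excluding) the sphere
plane.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AggregationError, DegenerateInputError, DomainError
from .phantom import PhantomGeometry, VoxelGrid, occupancy
from .reconstruction import ReconVolume

ANNULUS_INNER_RADIUS_MM = 39.0
ANNULUS_OUTER_RADIUS_MM = 76.0
ANNULUS_LENGTH_MM = 50.0

#: Partial volume effect and noise dominate the two smallest spheres; reporting
#: is restricted by default to the four largest.
DEFAULT_REPORT_SPHERES_MM = (17.0, 22.0, 28.0, 37.0)

DEFAULT_R = 2.37 / 0.30  # nominal 7.9 rather than the rounded 8:1


@dataclass
class VOISet:
    """Fractional-occupancy VOI masks on a reconstruction grid."""

    grid: VoxelGrid
    sphere_weights: dict  # diameter (mm) -> occupancy array
    background_weights: np.ndarray

    def sphere_volume_ml(self, diameter: float) -> float:
        return float(self.sphere_weights[diameter].sum() * self.grid.voxel_volume_ml)


def build_vois(
    geometry: PhantomGeometry,
    grid: VoxelGrid,
    inner_radius_mm: float = ANNULUS_INNER_RADIUS_MM,
    outer_radius_mm: float = ANNULUS_OUTER_RADIUS_MM,
    length_mm: float = ANNULUS_LENGTH_MM,
    supersample: int = 3,
) -> VOISet:
    """Analytic VOI placement on the known geometry.

    The annulus is centred axially on the sphere plane, excludes the slab of
    slices containing sphere VOIs (|z| <= largest sphere radius) and extends
    axially until its total length is ``length_mm`` (length/2 per side).
    """
    spheres = {}
    for i, d in enumerate(geometry.sphere_diameters):
        spheres[d] = occupancy(
            lambda x, y, z, i=i: geometry.inside_sphere(i, x, y, z), grid, supersample
        )

    half_w = geometry.straight_half_width
    if outer_radius_mm > geometry.arc_radius:
        warnings.warn(
            "background annulus exceeds the body outline; mask clipped to the body",
            stacklevel=2,
        )
    cx, cy = geometry.lung_centre
    # exclude every slice whose voxels touch a sphere ("slices adjacent to
    # those containing the spheres"): half a voxel beyond the largest radius
    z_excl = max(geometry.sphere_radii) if geometry.sphere_diameters else 0.0
    z_excl += grid.spacing[2] / 2.0
    z_hi = z_excl + length_mm / 2.0

    # Binary ring/axial-band selection at voxel centres (a VOI-selection
    # boundary, not a material boundary) times fractional body occupancy
    # (a material boundary: partial voxels there mix background with air).
    ax, ay, az = grid.axes()
    X = ax[:, None, None]
    Y = ay[None, :, None]
    Z = az[None, None, :]
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    select = (
        (r2 >= inner_radius_mm**2)
        & (r2 <= outer_radius_mm**2)
        & (np.abs(Z) > z_excl)
        & (np.abs(Z) <= z_hi)
    )
    body_occ = occupancy(geometry.inside_body, grid, supersample)
    bg = select * body_occ
    return VOISet(grid=grid, sphere_weights=spheres, background_weights=bg)


def crc_value(c_s: float, c_b: float, R: float) -> float:
    """Contrast recovery coefficient ((C_S/C_B) - 1) / (R - 1)."""
    if R <= 1:
        raise DomainError("nominal ratio R must be > 1")
    if c_b <= 0:
        raise DegenerateInputError("background mean must be positive")
    return (c_s / c_b - 1.0) / (R - 1.0)


@dataclass(frozen=True)
class SphereCRC:
    diameter_mm: float
    c_s: float
    c_b: float
    crc: float


@dataclass
class CRCResult:
    """Per-sphere contrast recovery for one repetition or an aggregate."""

    per_sphere: dict  # diameter -> SphereCRC
    R: float
    keys: dict = field(default_factory=dict)
    n_reps: int = 1
    crc_mean: dict = field(default_factory=dict)
    crc_sd: dict = field(default_factory=dict)
    sd_flagged: bool = False


def compute_crc(volume: ReconVolume, vois: VOISet, R: float = DEFAULT_R,
                keys: dict | None = None) -> CRCResult:
    """Single-repetition CRC per sphere.

    C_B is the occupancy-weighted background-annulus mean. C_S is the
    boundary-corrected sphere mean: with w the fractional occupancy and v the
    voxel values, C_S = (sum w*v - C_B * sum w*(1-w)) / sum w^2, which inverts
    the background/sphere mixing of boundary voxels exactly on the true map.
    """
    img = volume.values
    bw = vois.background_weights
    bsum = (bw**2).sum()
    if bsum <= 0:
        raise DegenerateInputError("background VOI is empty")
    # occupancy-corrected mean: exact on the true map where partially-occupied
    # annulus voxels mix background with air outside the body
    c_b = float((bw * img).sum() / bsum)
    if c_b <= 0:
        raise DegenerateInputError("background VOI mean is not positive")
    if R <= 1:
        raise DomainError("nominal ratio R must be > 1")
    per = {}
    for d, w in vois.sphere_weights.items():
        w2 = (w**2).sum()
        c_s = float(((w * img).sum() - c_b * (w * (1.0 - w)).sum()) / w2)
        crc = (c_s / c_b - 1.0) / (R - 1.0)
        per[d] = SphereCRC(diameter_mm=d, c_s=c_s, c_b=c_b, crc=crc)
    res = CRCResult(per_sphere=per, R=R, keys=dict(keys or {}))
    res.crc_mean = {d: s.crc for d, s in per.items()}
    res.crc_sd = {d: 0.0 for d in per}
    return res


def aggregate_reps(results) -> CRCResult:
    """Mean and sample SD of CRC over repetitions with identical keys."""
    results = list(results)
    if not results:
        raise AggregationError("no repetitions to aggregate")
    keys0 = results[0].keys
    diams = sorted(results[0].per_sphere)
    for r in results[1:]:
        if r.keys != keys0 or sorted(r.per_sphere) != diams:
            raise AggregationError(f"mixed keys in aggregation: {keys0} vs {r.keys}")
    n = len(results)
    mean, sd, per = {}, {}, {}
    for d in diams:
        vals = np.array([r.per_sphere[d].crc for r in results])
        mean[d] = float(vals.mean())
        sd[d] = float(vals.std(ddof=1)) if n > 1 else 0.0
        per[d] = SphereCRC(
            diameter_mm=d,
            c_s=float(np.mean([r.per_sphere[d].c_s for r in results])),
            c_b=float(np.mean([r.per_sphere[d].c_b for r in results])),
            crc=mean[d],
        )
    return CRCResult(
        per_sphere=per,
        R=results[0].R,
        keys=dict(keys0),
        n_reps=n,
        crc_mean=mean,
        crc_sd=sd,
        sd_flagged=(n == 1),
    )


@dataclass(frozen=True)
class RelativeReduction:
    percent: float
    rounded: int
    retention_percent: float


def relative_reduction(crc_reference: float, crc_degraded: float) -> RelativeReduction:
    """100 * (ref - degraded) / ref, rounded to the nearest integer percent."""
    if crc_reference <= 0:
        raise DomainError("reference CRC must be > 0")
    pct = 100.0 * (crc_reference - crc_degraded) / crc_reference
    return RelativeReduction(
        percent=pct,
        rounded=int(math.floor(pct + 0.5)),
        retention_percent=100.0 - pct,
    )


@dataclass
class ContaminationCurve:
    """CRC vs 99mTc contamination level for one sphere diameter."""

    diameter_mm: float
    points: list  # sorted (percent_tc, mean crc, sd)


def crc_vs_contamination(aggregates, diameter_mm: float) -> ContaminationCurve:
    """Build the sorted CRC-vs-contamination curve for one sphere."""
    pts = []
    seen = set()
    for agg in aggregates:
        if diameter_mm not in agg.per_sphere:
            raise DomainError(f"no sphere of diameter {diameter_mm} mm in results")
        pct = agg.keys.get("percent_tc")
        if pct in seen:
            raise DomainError(f"duplicate contamination level {pct}%")
        seen.add(pct)
        pts.append((pct, agg.crc_mean[diameter_mm], agg.crc_sd[diameter_mm]))
    if len(pts) < 2:
        raise DomainError("need at least two contamination levels for a curve")
    pts.sort(key=lambda p: p[0])
    return ContaminationCurve(diameter_mm=diameter_mm, points=pts)
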