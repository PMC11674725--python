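"""Synthetic SPECT acquisition: forward projection and Poisson noise.

Parallel-beam rotation-based projector with, per view:

* slice-wise in-plane rotation (bilinear, assembled as a sparse matrix so the
  back-projector is the exact matrix transpose),
* depth-dependent attenuation along each ray (from the rotated mu map),
* distance-dependent Gaussian collimator-detector response (separable
  detector-transverse and axial kernels per depth row),
* an additive broad septal-penetration component (wide Gaussian + small flat
  floor) with a window- and collimator-dependent weight,
* scaling by detected yield x window fraction x sensitivity x per-view time.

The same ``SystemModel`` class, with correction terms switched off, serves as
the reconstruction projector, so simulator and reconstruction share one
adjoint-consistent linear-operator implementation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .errors import AlignmentError, DomainError, GeometryError
from .phantom import ActivityMap, AttenuationMap, VoxelGrid
from .spectra import (
    DetectorEnergyResponse,
    EnergyWindow,
    IsotopeModel,
    STUDY_WINDOWS,
    _round_half_up,
    detected_spectrum,
    window_fraction,
)

DEFAULT_N_VIEWS = 64
DEFAULT_ORBIT_RADIUS_MM = 250.0
SEPTAL_BROAD_SIGMA_MM = 50.0
SEPTAL_FLAT_FRACTION = 0.2


@dataclass(frozen=True)
class CollimatorModel:
    """Collimator-detector response parameters.

    ``sigma0_mm`` + ``sigma_slope_mm_per_cm`` give the geometric Gaussian sigma
    as a function of source-to-collimator distance. ``septal_weight`` is the
    fraction of detected counts routed through the broad septal-penetration
    kernel, per energy-window label; thicker HE septa give smaller weights than
    ME at every window, and the weight grows with window energy.
    """

    kind: str
    sigma0_mm: float
    sigma_slope_mm_per_cm: float
    septal_weight: dict
    sensitivity: dict
    septal_sigma_mm: float = SEPTAL_BROAD_SIGMA_MM
    septal_flat_fraction: float = SEPTAL_FLAT_FRACTION

    def __post_init__(self):
        if any(not 0 <= w < 1 for w in self.septal_weight.values()):
            raise DomainError("septal weights must lie in [0, 1)")
        if any(s <= 0 for s in self.sensitivity.values()):
            raise DomainError("sensitivities must be > 0")

    def sigma_mm(self, distance_mm):
        d = np.maximum(np.asarray(distance_mm, dtype=float), 0.0)
        return self.sigma0_mm + self.sigma_slope_mm_per_cm * d / 10.0


def _window_dict(values) -> dict:
    return {w.label: v for w, v in zip(STUDY_WINDOWS, values)}


def he_collimator() -> CollimatorModel:
    """High-energy collimator: thick septa, little penetration, lower sensitivity."""
    return CollimatorModel(
        kind="HE",
        sigma0_mm=2.0,
        sigma_slope_mm_per_cm=0.42,
        septal_weight=_window_dict((0.05, 0.08, 0.18)),
        sensitivity=_window_dict((1600.0, 1600.0, 1600.0)),
    )


def me_collimator() -> CollimatorModel:
    """Medium-energy collimator: better resolution, much more septal penetration."""
    return CollimatorModel(
        kind="ME",
        sigma0_mm=1.8,
        sigma_slope_mm_per_cm=0.40,
        septal_weight=_window_dict((0.18, 0.25, 0.40)),
        sensitivity=_window_dict((2240.0, 2240.0, 2240.0)),
    )


def collimator_by_kind(kind: str) -> CollimatorModel:
    try:
        return {"HE": he_collimator, "ME": me_collimator}[kind]()
    except KeyError:
        raise DomainError(f"unknown collimator kind {kind!r}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One acquisition setting: windows, collimator, timing, orbit."""

    collimator: CollimatorModel
    windows: tuple = STUDY_WINDOWS
    scan_time_min: float = 20.0
    n_views: int = DEFAULT_N_VIEWS
    orbit_radius_mm: float = DEFAULT_ORBIT_RADIUS_MM
    response: DetectorEnergyResponse = DetectorEnergyResponse()

    def __post_init__(self):
        if self.scan_time_min <= 0:
            raise DomainError("scan_time must be > 0")
        if self.n_views < 2:
            raise DomainError("n_views must be >= 2")

    @property
    def view_time_s(self) -> float:
        return self.scan_time_min * 60.0 / self.n_views


@dataclass(frozen=True)
class ExperimentRow:
    """One row of the experiment schedule."""

    exp_id: int
    label: str
    scan_time_min: float
    repetitions: int
    collimator_kind: str
    aeff_y90_gbq: float
    aeff_tc_mbq: float
    percent_tc: int

    def __post_init__(self):
        if self.aeff_y90_gbq < 0 or self.aeff_tc_mbq < 0:
            raise DomainError("activities must be >= 0")
        derived = _round_half_up(100.0 * self.aeff_tc_mbq / (self.aeff_y90_gbq * 1000.0))
        if derived != self.percent_tc:
            raise DomainError(
                f"experiment {self.exp_id}: percent_tc {self.percent_tc} inconsistent "
                f"with activities (derived {derived})"
            )


#: Built-in experiment schedule: six acquisitions, 90Y-only then increasing
#: 99mTc added to the background, HE/ME collimators, three windows simultaneous.
TABLE1_SCHEDULE = (
    ExperimentRow(1, "90Y only", 20.0, 3, "HE", 3.2, 0.0, 0),
    ExperimentRow(2, "90Y only", 20.0, 3, "ME", 3.1, 0.0, 0),
    ExperimentRow(3, "90Y+99mTc", 20.0, 3, "ME", 3.1, 450.0, 15),
    ExperimentRow(4, "90Y+99mTc", 20.0, 3, "HE", 3.0, 376.0, 13),
    ExperimentRow(5, "90Y+99mTc", 25.0, 3, "HE", 3.1, 189.0, 6),
    ExperimentRow(6, "90Y+99mTc", 25.0, 3, "ME", 3.1, 165.0, 5),
)


def load_schedule(rows=None) -> tuple:
    """Return the built-in schedule, or validate user rows (list of dicts)."""
    if rows is None:
        return TABLE1_SCHEDULE
    return tuple(ExperimentRow(**r) if isinstance(r, dict) else r for r in rows)


# ---------------------------------------------------------------------------
# Rotation operators
# ---------------------------------------------------------------------------

_ROTATION_CACHE: dict = {}


def _bilinear_rotation(n: int, theta: float) -> sp.csr_matrix:
    """Sparse (n^2 x n^2) bilinear rotation of an n x n image about its centre."""
    c = (n - 1) / 2.0
    U, T = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u = U.ravel() - c
    t = T.ravel() - c
    su = math.cos(theta) * u - math.sin(theta) * t + c
    st = math.sin(theta) * u + math.cos(theta) * t + c
    i0 = np.floor(su).astype(int)
    j0 = np.floor(st).astype(int)
    fu = su - i0
    ft = st - j0
    rows, cols, vals = [], [], []
    out_idx = np.arange(n * n)
    for di, wi in ((0, 1.0 - fu), (1, fu)):
        for dj, wj in ((0, 1.0 - ft), (1, ft)):
            ii = i0 + di
            jj = j0 + dj
            w = wi * wj
            ok = (ii >= 0) & (ii < n) & (jj >= 0) & (jj < n) & (w > 0)
            rows.append(out_idx[ok])
            cols.append(ii[ok] * n + jj[ok])
            vals.append(w[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    return mat.tocsr()


def rotation_set(n: int, n_views: int):
    """Cached per-view rotation matrices and their transposes."""
    key = (n, n_views)
    if key not in _ROTATION_CACHE:
        angles = np.linspace(0.0, 2.0 * math.pi, n_views, endpoint=False)
        R = [_bilinear_rotation(n, a) for a in angles]
        RT = [m.T.tocsr() for m in R]
        _ROTATION_CACHE[key] = (R, RT)
    return _ROTATION_CACHE[key]


def _gauss_bank(n: int, sigmas_px: np.ndarray) -> np.ndarray:
    """(len(sigmas), n, n) column-normalized Gaussian convolution matrices."""
    idx = np.arange(n)
    d2 = (idx[:, None] - idx[None, :]) ** 2
    sig = np.maximum(sigmas_px, 1e-6)[:, None, None]
    K = np.exp(-0.5 * d2[None, :, :] / sig**2)
    K /= K.sum(axis=1, keepdims=True)
    return K


def _gauss_matrix(n: int, sigma_px: float) -> np.ndarray:
    return _gauss_bank(n, np.array([sigma_px]))[0]


class SystemModel:
    """Adjoint-consistent SPECT projector.

    Maps a voxel-activity array (nx, ny, nz) [MBq] to per-view expected
    relative counts (n_views, n_bins, nz); the physical scaling (yield,
    window fraction, sensitivity, view time) is applied by the caller.
    ``adjoint`` applies the exact matrix transpose of ``forward``.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        *,
        n_views: int = DEFAULT_N_VIEWS,
        orbit_radius_mm: float = DEFAULT_ORBIT_RADIUS_MM,
        mu: AttenuationMap | None = None,
        collimator: CollimatorModel | None = None,
        window_label: str | None = None,
        attenuation: bool = True,
        cdr: bool = True,
        septal: bool = True,
        flat: bool = True,
    ):
        nx, ny, nz = grid.dims
        if nx != ny:
            raise DomainError("projector requires square in-plane grid")
        self.grid = grid
        self.n = nx
        self.nz = nz
        self.n_views = n_views
        self.orbit_radius_mm = orbit_radius_mm
        self.use_att = attenuation
        self.use_cdr = cdr
        self.use_septal = septal
        self.use_flat = flat
        self.collimator = collimator
        self.window_label = window_label

        self.R, self.RT = rotation_set(nx, n_views)

        sxy = grid.spacing[0]
        sz = grid.spacing[2]
        c = (nx - 1) / 2.0
        # depth row 0 is nearest the detector
        self.distance_mm = orbit_radius_mm + (np.arange(nx) - c) * sxy

        if attenuation:
            if mu is None:
                raise DomainError("attenuation enabled but no mu map supplied")
            if mu.grid.dims != grid.dims:
                raise AlignmentError("mu map grid does not match projector grid")
            self.att = self._attenuation_factors(mu.values, sxy)
        else:
            self.att = None

        if cdr or septal:
            if collimator is None:
                raise DomainError("CDR/septal modelling requires a collimator model")
        if cdr:
            sig_mm = collimator.sigma_mm(self.distance_mm)
            self.Bdet = _gauss_bank(nx, sig_mm / sxy)
            self.Bz = _gauss_bank(nz, sig_mm / sz)
            self.BdetT = np.ascontiguousarray(self.Bdet.transpose(0, 2, 1))
            self.BzT = np.ascontiguousarray(self.Bz.transpose(0, 2, 1))
        if septal:
            if window_label is None:
                raise DomainError("septal modelling requires a window label")
            self.wsp = collimator.septal_weight[window_label]
            self.ffrac = collimator.septal_flat_fraction
            self.Bs_det = _gauss_matrix(nx, collimator.septal_sigma_mm / sxy)
            self.Bs_z = _gauss_matrix(nz, collimator.septal_sigma_mm / sz)
        else:
            self.wsp = 0.0
            self.ffrac = 0.0

    def _attenuation_factors(self, mu_values: np.ndarray, sxy: float) -> np.ndarray:
        """exp(-integral mu) from each voxel to the detector, per view."""
        mu_flat = np.ascontiguousarray(mu_values.reshape(self.n * self.n, self.nz))
        step_cm = sxy / 10.0
        att = np.empty((self.n_views, self.n, self.n, self.nz))
        for v in range(self.n_views):
            mu_rot = (self.R[v] @ mu_flat).reshape(self.n, self.n, self.nz)
            path = np.cumsum(mu_rot, axis=0) - 0.5 * mu_rot
            att[v] = np.exp(-step_cm * path)
        return att

    def _views(self, views):
        return range(self.n_views) if views is None else views

    def forward(self, x: np.ndarray, views=None) -> np.ndarray:
        views = list(self._views(views))
        xf = np.ascontiguousarray(x.reshape(self.n * self.n, self.nz))
        out = np.empty((len(views), self.n, self.nz))
        for k, v in enumerate(views):
            w3 = (self.R[v] @ xf).reshape(self.n, self.n, self.nz)
            if self.use_att:
                w3 = w3 * self.att[v]
            if self.use_cdr:
                g = np.matmul(self.Bdet, w3)
                g = np.matmul(g, self.BzT)
                p_geo = g.sum(axis=0)
            else:
                p_geo = w3.sum(axis=0)
            if self.use_septal:
                p0 = w3.sum(axis=0)
                p_b = self.Bs_det @ p0 @ self.Bs_z.T
                y = (1.0 - self.wsp) * p_geo + self.wsp * (1.0 - self.ffrac) * p_b
                if self.use_flat:
                    y = y + self.wsp * self.ffrac * p0.sum() / (self.n * self.nz)
                out[k] = y
            else:
                out[k] = p_geo
        return out

    def adjoint(self, y: np.ndarray, views=None) -> np.ndarray:
        views = list(self._views(views))
        xf = np.zeros((self.n * self.n, self.nz))
        for k, v in enumerate(views):
            g2 = np.ascontiguousarray(y[k])
            gg = (1.0 - self.wsp) * g2 if self.use_septal else g2
            if self.use_cdr:
                t = np.matmul(self.BdetT, gg[None, :, :])
                t = np.matmul(t, self.Bz)
            else:
                t = np.broadcast_to(gg, (self.n, self.n, self.nz)).copy()
            if self.use_septal:
                sb = self.wsp * (1.0 - self.ffrac) * (self.Bs_det.T @ g2 @ self.Bs_z)
                if self.use_flat:
                    sb = sb + self.wsp * self.ffrac * g2.sum() / (self.n * self.nz)
                t = t + sb[None, :, :]
            if self.use_att:
                t = t * self.att[v]
            xf += self.RT[v] @ t.reshape(self.n * self.n, self.nz)
        return xf.reshape(self.n, self.n, self.nz)

    def flat_component(self, x: np.ndarray, views=None) -> np.ndarray:
        """The flat septal floor alone (the additive model term in recon)."""
        views = list(self._views(views))
        xf = np.ascontiguousarray(x.reshape(self.n * self.n, self.nz))
        out = np.empty((len(views), self.n, self.nz))
        for k, v in enumerate(views):
            w3 = (self.R[v] @ xf).reshape(self.n, self.n, self.nz)
            if self.use_att:
                w3 = w3 * self.att[v]
            out[k] = self.wsp * self.ffrac * w3.sum() / (self.n * self.nz)
        return out


# ---------------------------------------------------------------------------
# Forward projection with physical scaling, noise, experiment simulation
# ---------------------------------------------------------------------------

_SPECTRUM_CACHE: dict = {}


def _cached_detected_spectrum(isotope: IsotopeModel, response: DetectorEnergyResponse):
    key = (isotope.name, isotope.emission_spectrum.tobytes(), response.fwhm_percent_at_140)
    if key not in _SPECTRUM_CACHE:
        _SPECTRUM_CACHE[key] = detected_spectrum(isotope, response)
    return _SPECTRUM_CACHE[key]


def projection_scale(
    protocol: AcquisitionProtocol, window: EnergyWindow, isotope: IsotopeModel
) -> float:
    """Counts per projected MBq: yield x window fraction x sensitivity x view time."""
    spec = _cached_detected_spectrum(isotope, protocol.response)
    wf = window_fraction(spec, window)
    sens = protocol.collimator.sensitivity[window.label]
    return isotope.detected_yield * wf * sens * protocol.view_time_s


def make_system(
    grid: VoxelGrid,
    mu: AttenuationMap,
    protocol: AcquisitionProtocol,
    window: EnergyWindow,
    **flags,
) -> SystemModel:
    """Full simulator system model (all physics on unless overridden)."""
    return SystemModel(
        grid,
        n_views=protocol.n_views,
        orbit_radius_mm=protocol.orbit_radius_mm,
        mu=mu,
        collimator=protocol.collimator,
        window_label=window.label,
        **flags,
    )


def forward_project(
    activity: ActivityMap,
    mu: AttenuationMap,
    protocol: AcquisitionProtocol,
    window: EnergyWindow,
    isotope: IsotopeModel,
    system: SystemModel | None = None,
) -> np.ndarray:
    """Expected counts (n_views, n_bins, nz) for one isotope in one window."""
    if mu is not None and activity.grid.dims != mu.grid.dims:
        raise AlignmentError("activity and mu maps are on different grids")
    if system is None:
        system = make_system(activity.grid, mu, protocol, window)
    scale = projection_scale(protocol, window, isotope)
    return system.forward(activity.voxel_activity_mbq()) * scale


@dataclass
class SinogramSet:
    """Per-window projection counts with full acquisition metadata."""

    counts: np.ndarray  # (n_windows, n_views, n_bins, nz) integer
    expected: np.ndarray  # same shape, real-valued means
    windows: tuple
    protocol: AcquisitionProtocol
    row: ExperimentRow | None
    seed: int
    grid: VoxelGrid

    def window_index(self, window: EnergyWindow) -> int:
        for i, w in enumerate(self.windows):
            if w.label == window.label:
                return i
        raise DomainError(f"window {window.label} not in sinogram set")


def add_noise(
    expected: np.ndarray,
    seed: int,
    *,
    windows=STUDY_WINDOWS,
    protocol: AcquisitionProtocol | None = None,
    row: ExperimentRow | None = None,
    grid: VoxelGrid | None = None,
) -> SinogramSet:
    """Independent Poisson draws per bin; identical seed -> identical counts."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise DomainError("expected counts must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    return SinogramSet(
        counts=counts,
        expected=expected,
        windows=tuple(windows),
        protocol=protocol,
        row=row,
        seed=seed,
        grid=grid,
    )


def simulate_experiment(
    row: ExperimentRow,
    isotope_maps: dict,
    mu_maps: dict,
    protocol: AcquisitionProtocol,
    seed: int,
    systems: dict | None = None,
) -> list:
    """Simulate one schedule row: one SinogramSet per repetition.

    ``isotope_maps`` maps IsotopeModel -> ActivityMap (already scaled to the
    row's effective activities; the 99mTc map has zero sphere concentration).
    Repetitions share the expectation and differ only by noise seed
    (seed, seed+1, ...).
    """
    grid = next(iter(isotope_maps.values())).grid
    n, nz = grid.dims[0], grid.dims[2]
    expected = np.zeros((len(protocol.windows), protocol.n_views, n, nz))
    for wi, window in enumerate(protocol.windows):
        mu = mu_maps[window.label]
        for isotope, amap in isotope_maps.items():
            if amap.total_mbq == 0.0:
                continue
            system = None if systems is None else systems.get(
                (protocol.collimator.kind, window.label)
            )
            expected[wi] += forward_project(amap, mu, protocol, window, isotope, system)
    return [
        add_noise(
            expected,
            seed + r,
            windows=protocol.windows,
            protocol=protocol,
            row=row,
            grid=grid,
        )
        for r in range(row.repetitions)
    ]
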