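"""Detected energy spectra for 90Y bremsstrahlung and 99mTc.

90Y is a pure beta emitter imaged through the continuous bremsstrahlung X-ray
spectrum; 99mTc emits a 140.5 keV gamma line. Spectra live on a fixed 1 keV
grid (20-400 keV, bin centres at half-keV). The detector energy response is a
Gaussian whose FWHM scales as sqrt(E), anchored as a percentage at 140 keV.

The 90Y detected-spectrum shape is a smooth monotonically decreasing
exponential (no tabulated published shape exists); the 99mTc model is the
photopeak plus a low-energy scatter tail and a small high-energy (pile-up /
detector-scatter analog) tail. Both are documented approximations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, DegenerateInputError, DomainError

ENERGY_MIN_KEV = 20.0
ENERGY_MAX_KEV = 400.0
ENERGY_EDGES_KEV = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + 1.0, 1.0)
ENERGY_CENTERS_KEV = 0.5 * (ENERGY_EDGES_KEV[:-1] + ENERGY_EDGES_KEV[1:])
N_BINS = ENERGY_CENTERS_KEV.size

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

HALF_LIFE_HOURS = {"Y90": 64.05, "Tc99m": 6.007}

TC_PEAK_KEV = 140.5


@dataclass(frozen=True)
class EnergyWindow:
    """Half-open acquisition energy window [low, high) in keV."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise DomainError(f"window low {self.low} must be < high {self.high}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.low:g}-{self.high:g}")


#: The three study windows, acquired simultaneously.
STUDY_WINDOWS = (
    EnergyWindow(90.0, 120.0),
    EnergyWindow(160.0, 200.0),
    EnergyWindow(200.0, 250.0),
)


@dataclass(frozen=True)
class DetectorEnergyResponse:
    """Gaussian energy resolution, FWHM(E) = fwhm%/100 * 140 * sqrt(E/140)."""

    fwhm_percent_at_140: float = 9.9

    def __post_init__(self):
        if self.fwhm_percent_at_140 < 0:
            raise DomainError("FWHM percentage must be >= 0")

    def fwhm_kev(self, energy_kev):
        return (
            self.fwhm_percent_at_140 / 100.0 * 140.0
            * np.sqrt(np.asarray(energy_kev, dtype=float) / 140.0)
        )

    def sigma_kev(self, energy_kev):
        return self.fwhm_kev(energy_kev) * GAUSS_FWHM_TO_SIGMA


@dataclass(frozen=True, eq=False)
class IsotopeModel:
    """Emission model: normalized spectrum + decay + detected photon yield.

    ``detected_yield`` is the relative number of detectable photons per decay;
    it sets the count-rate scale per MBq and is what makes a few percent of
    99mTc overwhelm the 90Y bremsstrahlung continuum in the low window.
    """

    name: str
    half_life_hours: float
    emission_spectrum: np.ndarray
    detected_yield: float

    def __post_init__(self):
        s = np.asarray(self.emission_spectrum, dtype=float)
        if s.shape != (N_BINS,):
            raise AlignmentError(
                f"spectrum must have {N_BINS} bins on the 1 keV grid, got {s.shape}"
            )
        if np.any(s < 0):
            raise DomainError("spectrum intensities must be >= 0")
        total = s.sum()
        if total <= 0:
            raise DegenerateInputError("spectrum has zero total intensity")
        object.__setattr__(self, "emission_spectrum", s / total)


def yttrium90(slope_kev: float = 120.0, detected_yield: float = 0.02) -> IsotopeModel:
    """90Y bremsstrahlung model: exp(-E/slope), monotonically decreasing."""
    spec = np.exp(-ENERGY_CENTERS_KEV / slope_kev)
    return IsotopeModel("Y90", HALF_LIFE_HOURS["Y90"], spec, detected_yield)


def technetium99m(
    low_tail_fraction: float = 0.30,
    low_tail_slope_kev: float = 30.0,
    high_tail_fraction: float = 0.0066,
    high_tail_slope_kev: float = 18.0,
    detected_yield: float = 0.89,
) -> IsotopeModel:
    """99mTc model: 140.5 keV photopeak + scatter tail + small high-energy tail."""
    e = ENERGY_CENTERS_KEV
    spec = np.zeros(N_BINS)
    low = np.where(e < TC_PEAK_KEV, np.exp((e - TC_PEAK_KEV) / low_tail_slope_kev), 0.0)
    high = np.where(e > TC_PEAK_KEV, np.exp(-(e - TC_PEAK_KEV) / high_tail_slope_kev), 0.0)
    if low.sum() > 0:
        spec += low_tail_fraction * low / low.sum()
    if high.sum() > 0:
        spec += high_tail_fraction * high / high.sum()
    peak_mass = 1.0 - low_tail_fraction - high_tail_fraction
    peak_bin = int(np.argmin(np.abs(e - TC_PEAK_KEV)))
    spec[peak_bin] += peak_mass
    return IsotopeModel("Tc99m", HALF_LIFE_HOURS["Tc99m"], spec, detected_yield)


def detected_spectrum(
    isotope: IsotopeModel, response: DetectorEnergyResponse
) -> np.ndarray:
    """Apply Gaussian energy broadening per bin; output renormalized to 1."""
    s = isotope.emission_spectrum
    if response.fwhm_percent_at_140 == 0:
        return s.copy()
    e = ENERGY_CENTERS_KEV
    sigma = np.maximum(response.sigma_kev(e), 1e-9)
    # K[i, j]: fraction of source bin j landing in detected bin i
    K = np.exp(-0.5 * ((e[:, None] - e[None, :]) / sigma[None, :]) ** 2)
    K /= K.sum(axis=0, keepdims=True)
    out = K @ s
    return out / out.sum()


def window_fraction(spectrum: np.ndarray, window: EnergyWindow) -> float:
    """Fraction of the (normalized) spectrum inside [low, high)."""
    if window.low < ENERGY_MIN_KEV or window.high > ENERGY_MAX_KEV:
        raise DomainError(
            f"window {window.label} outside spectrum range "
            f"{ENERGY_MIN_KEV:g}-{ENERGY_MAX_KEV:g} keV"
        )
    s = np.asarray(spectrum, dtype=float)
    if s.shape != (N_BINS,):
        raise AlignmentError("spectrum not on the package energy grid")
    mask = (ENERGY_CENTERS_KEV >= window.low) & (ENERGY_CENTERS_KEV < window.high)
    return float(s[mask].sum() / s.sum())


def compose_dual_spectrum(components) -> np.ndarray:
    """Weighted (unnormalized) sum of component spectra; linear in weights.

    ``components`` is a sequence of (IsotopeModel or spectrum array, weight).
    """
    specs, weights = [], []
    for comp, w in components:
        if w < 0:
            raise DomainError("component weights must be >= 0")
        s = comp.emission_spectrum if isinstance(comp, IsotopeModel) else np.asarray(comp, float)
        if s.shape != (N_BINS,):
            raise AlignmentError("component spectrum not on the package energy grid")
        specs.append(s)
        weights.append(w)
    if not specs or not any(w > 0 for w in weights):
        raise DegenerateInputError("all component weights are zero")
    out = np.zeros(N_BINS)
    for s, w in zip(specs, weights):
        out += w * s
    return out


@dataclass(frozen=True)
class SubtractionResult:
    spectrum: np.ndarray
    clipped_mass: float


def subtract_component(
    dual: np.ndarray, component: np.ndarray, weight: float
) -> SubtractionResult:
    """Bin-wise ``dual - weight * component``; negative bins clipped to zero.

    The clipped (lost) mass is reported so over-subtraction is visible.
    """
    d = np.asarray(dual, dtype=float)
    c = np.asarray(component, dtype=float)
    if d.shape != c.shape:
        raise AlignmentError(f"spectrum grids differ: {d.shape} vs {c.shape}")
    diff = d - weight * c
    clipped = float(-diff[diff < 0].sum()) if np.any(diff < 0) else 0.0
    return SubtractionResult(spectrum=np.clip(diff, 0.0, None), clipped_mass=clipped)


@dataclass(frozen=True)
class ActivityState:
    """An isotope activity (MBq) at a timestamp (hours from reference)."""

    isotope: str
    activity_mbq: float
    timestamp_h: float = 0.0

    def __post_init__(self):
        if self.activity_mbq < 0:
            raise DomainError("activity must be >= 0")


def decay_correct(
    state: ActivityState, dt_hours: float, half_life_hours: float | None = None
) -> ActivityState:
    """Decay the activity forward by ``dt_hours``: A * 2**(-dt/T_half)."""
    if dt_hours < 0:
        raise DomainError("dt must be >= 0")
    if half_life_hours is None:
        try:
            half_life_hours = HALF_LIFE_HOURS[state.isotope]
        except KeyError:
            raise DomainError(f"unknown isotope {state.isotope!r}: pass half_life_hours")
    factor = 2.0 ** (-dt_hours / half_life_hours)
    return replace(
        state,
        activity_mbq=state.activity_mbq * factor,
        timestamp_h=state.timestamp_h + dt_hours,
    )


@dataclass(frozen=True)
class PercentContamination:
    percent: float
    rounded: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent_contamination(tc: ActivityState, y90: ActivityState) -> PercentContamination:
    """100 * A_Tc / A_Y90, reported unrounded and to the nearest integer percent."""
    if y90.activity_mbq <= 0:
        raise DomainError("90Y activity must be > 0 for a contamination percentage")
    pct = 100.0 * tc.activity_mbq / y90.activity_mbq
    return PercentContamination(percent=pct, rounded=_round_half_up(pct))


def save_spectrum(path, spectrum: np.ndarray, header: str = "energy_keV intensity"):
    """Write a spectrum as two-column delimited text (energy keV, intensity)."""
    np.savetxt(path, np.column_stack([ENERGY_CENTERS_KEV, spectrum]), header=header)


def load_spectrum(path) -> np.ndarray:
    """Read a two-column spectrum and align it to the package energy grid."""
    data = np.loadtxt(path)
    if data.shape != (N_BINS, 2) or not np.allclose(data[:, 0], ENERGY_CENTERS_KEV):
        raise AlignmentError("spectrum file is not on the package 1 keV energy grid")
    return data[:, 1]
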