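"""Digital NEMA IEC body phantom.

Analytic geometry (torso-shaped body, six coplanar fillable spheres, cylindrical
lung insert) plus rasterization of per-isotope activity concentration maps and
per-energy linear-attenuation maps onto a voxel grid with sub-voxel
(supersampled fractional occupancy) anti-aliasing.

Coordinates are millimetres; the phantom is centred on the origin with the
sphere plane at z = 0 and the lung-insert axis along z.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ExtentError, GeometryError

DEFAULT_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SPHERE_RING_RADIUS_MM = 57.2

# Body cross-section: two circular arcs of radius 115 mm centred at x = +-35 mm,
# joined by straight segments -> overall 300 mm wide x 230 mm tall torso shape.
BODY_STRAIGHT_HALF_WIDTH_MM = 35.0
BODY_ARC_RADIUS_MM = 115.0
BODY_AXIAL_LENGTH_MM = 180.0

LUNG_RADIUS_MM = 25.0

SPHERE_CONC_MBQ_PER_ML = 2.37
BACKGROUND_CONC_MBQ_PER_ML = 0.30

# Water linear attenuation coefficient (1/cm) vs photon energy (keV).
# Values interpolated log-log between anchors; lung modelled as 0.30 x water
# (inflated-lung density analog).
MU_WATER_TABLE_KEV = (50.0, 80.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0)
MU_WATER_TABLE_PER_CM = (0.227, 0.184, 0.171, 0.151, 0.137, 0.127, 0.119, 0.106)
LUNG_RELATIVE_DENSITY = 0.30
MU_ENERGY_RANGE_KEV = (50.0, 400.0)


def mu_water(energy_kev: float) -> float:
    """Water linear attenuation coefficient (1/cm), log-log interpolation."""
    lo, hi = MU_ENERGY_RANGE_KEV
    if not lo <= energy_kev <= hi:
        raise DomainError(
            f"reference energy {energy_kev} keV outside modelled range {lo}-{hi} keV"
        )
    return float(
        np.exp(
            np.interp(
                np.log(energy_kev),
                np.log(MU_WATER_TABLE_KEV),
                np.log(MU_WATER_TABLE_PER_CM),
            )
        )
    )


def mu_lung(energy_kev: float) -> float:
    """Lung-insert linear attenuation coefficient (1/cm)."""
    return LUNG_RELATIVE_DENSITY * mu_water(energy_kev)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel grid. ``origin`` is the centre of voxel (0, 0, 0) in mm."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if any(d < 1 for d in self.dims):
            raise DomainError(f"grid dims must be positive, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise DomainError(f"grid spacing must be positive, got {self.spacing}")

    @classmethod
    def centered(cls, dims, spacing) -> "VoxelGrid":
        """Grid whose extent is centred on the origin."""
        dims = tuple(int(d) for d in dims)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, spacing))
        return cls(dims, spacing, origin)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    @property
    def voxel_volume_ml(self) -> float:
        return math.prod(self.spacing) / 1000.0

    def extent(self) -> tuple[tuple[float, float], ...]:
        """(min, max) outer-edge coordinate per axis."""
        return tuple(
            (
                self.origin[a] - self.spacing[a] / 2.0,
                self.origin[a] + self.spacing[a] * (self.dims[a] - 0.5),
            )
            for a in range(3)
        )


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic NEMA IEC IQ phantom description (all lengths mm)."""

    sphere_diameters: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS_MM
    sphere_centres: tuple[tuple[float, float, float], ...] = ()
    straight_half_width: float = BODY_STRAIGHT_HALF_WIDTH_MM
    arc_radius: float = BODY_ARC_RADIUS_MM
    axial_length: float = BODY_AXIAL_LENGTH_MM
    lung_centre: tuple[float, float] = (0.0, 0.0)
    lung_radius: float = LUNG_RADIUS_MM
    lung_length: float = BODY_AXIAL_LENGTH_MM

    @property
    def sphere_radii(self) -> tuple[float, ...]:
        return tuple(d / 2.0 for d in self.sphere_diameters)

    def sphere_volume_ml(self, diameter: float) -> float:
        """Analytic sphere volume in mL for a diameter in mm."""
        r_cm = diameter / 20.0
        return 4.0 / 3.0 * math.pi * r_cm**3

    # --- analytic inside-tests (broadcastable over numpy arrays) ------------

    def inside_body(self, x, y, z):
        dx = np.maximum(np.abs(x) - self.straight_half_width, 0.0)
        return (dx**2 + np.asarray(y) ** 2 <= self.arc_radius**2) & (
            np.abs(z) <= self.axial_length / 2.0
        )

    def inside_lung(self, x, y, z):
        cx, cy = self.lung_centre
        return ((np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
                <= self.lung_radius**2) & (np.abs(z) <= self.lung_length / 2.0)

    def inside_sphere(self, i: int, x, y, z):
        cx, cy, cz = self.sphere_centres[i]
        r = self.sphere_radii[i]
        return (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 + (
            np.asarray(z) - cz
        ) ** 2 <= r**2


def build_phantom_geometry(
    sphere_diameters=None,
    sphere_ring_radius: float = SPHERE_RING_RADIUS_MM,
    axial_length: float = BODY_AXIAL_LENGTH_MM,
    lung_radius: float = LUNG_RADIUS_MM,
    straight_half_width: float = BODY_STRAIGHT_HALF_WIDTH_MM,
    arc_radius: float = BODY_ARC_RADIUS_MM,
) -> PhantomGeometry:
    """Build and validate the phantom geometry.

    Spheres are placed coplanar (z = 0) at 60 degree spacing on a ring of radius
    ``sphere_ring_radius`` around the lung-insert axis, ordered by diameter.
    Passing an empty ``sphere_diameters`` sequence yields a sphere-free phantom.
    """
    if sphere_diameters is None:
        sphere_diameters = DEFAULT_SPHERE_DIAMETERS_MM
    diameters = tuple(float(d) for d in sphere_diameters)
    if any(d <= 0 for d in diameters):
        raise GeometryError(f"sphere diameters must be positive, got {diameters}")

    n = len(diameters)
    centres = []
    for i in range(n):
        theta = math.radians(60.0 * i) if n else 0.0
        centres.append(
            (
                sphere_ring_radius * math.cos(theta),
                sphere_ring_radius * math.sin(theta),
                0.0,
            )
        )
    geom = PhantomGeometry(
        sphere_diameters=diameters,
        sphere_centres=tuple(centres),
        straight_half_width=straight_half_width,
        arc_radius=arc_radius,
        axial_length=axial_length,
        lung_radius=lung_radius,
        lung_length=axial_length,
    )

    radii = geom.sphere_radii
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = centres[i], centres[j]
            dist = math.dist(ci, cj)
            if dist < radii[i] + radii[j]:
                raise GeometryError(
                    f"spheres of diameter {diameters[i]} mm and {diameters[j]} mm "
                    f"overlap (centre distance {dist:.1f} mm < "
                    f"{radii[i] + radii[j]:.1f} mm)"
                )
    for i in range(n):
        cx, cy, _ = centres[i]
        dx = max(abs(cx) - straight_half_width, 0.0)
        if math.hypot(dx, cy) + radii[i] > arc_radius:
            raise GeometryError(
                f"sphere of diameter {diameters[i]} mm extends outside the body outline"
            )
        if math.hypot(cx - geom.lung_centre[0], cy - geom.lung_centre[1]) < (
            lung_radius + radii[i]
        ):
            raise GeometryError(
                f"sphere of diameter {diameters[i]} mm intersects the lung insert"
            )
    return geom


@dataclass(frozen=True)
class CompartmentActivity:
    """Per-compartment activity concentrations (MBq/mL) for one isotope."""

    isotope: str
    sphere_concentration: float = SPHERE_CONC_MBQ_PER_ML
    background_concentration: float = BACKGROUND_CONC_MBQ_PER_ML
    lung_concentration: float = 0.0

    def __post_init__(self):
        for name in ("sphere_concentration", "background_concentration",
                     "lung_concentration"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def ratio(self) -> float:
        """Nominal sphere-to-background concentration ratio R."""
        if self.background_concentration <= 0:
            raise DomainError("ratio undefined for zero background concentration")
        return self.sphere_concentration / self.background_concentration


@dataclass
class ActivityMap:
    """Voxelized activity concentration (MBq/mL) for one isotope."""

    grid: VoxelGrid
    values: np.ndarray
    isotope: str

    @property
    def total_mbq(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume_ml)

    def voxel_activity_mbq(self) -> np.ndarray:
        """Per-voxel activity (MBq), the quantity forward-projected."""
        return self.values * self.grid.voxel_volume_ml


@dataclass
class AttenuationMap:
    """Voxelized linear attenuation coefficient (1/cm) at a reference energy."""

    grid: VoxelGrid
    values: np.ndarray
    reference_energy_kev: float


def occupancy(predicate, grid: VoxelGrid, supersample: int = 3) -> np.ndarray:
    """Fractional voxel occupancy of ``predicate(x, y, z)`` by supersampling.

    Each voxel is subdivided ``supersample`` times per axis; occupancy is the
    fraction of sub-voxel centres inside the region.
    """
    ax, ay, az = grid.axes()
    occ = np.zeros(grid.dims, dtype=float)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    for ox in offs:
        X = (ax + ox * grid.spacing[0])[:, None, None]
        for oy in offs:
            Y = (ay + oy * grid.spacing[1])[None, :, None]
            for oz in offs:
                Z = (az + oz * grid.spacing[2])[None, None, :]
                occ += predicate(X, Y, Z)
    occ /= supersample**3
    return occ


def _check_extent(geometry: PhantomGeometry, grid: VoxelGrid):
    half_w = geometry.straight_half_width + geometry.arc_radius
    bbox = (
        (-half_w, half_w),
        (-geometry.arc_radius, geometry.arc_radius),
        (-geometry.axial_length / 2.0, geometry.axial_length / 2.0),
    )
    ext = grid.extent()
    for a, ((blo, bhi), (glo, ghi)) in enumerate(zip(bbox, ext)):
        if blo < glo or bhi > ghi:
            raise ExtentError(
                f"grid axis {a} extent [{glo:.1f}, {ghi:.1f}] mm does not enclose "
                f"phantom [{blo:.1f}, {bhi:.1f}] mm"
            )


def compartment_occupancies(
    geometry: PhantomGeometry, grid: VoxelGrid, supersample: int = 3
) -> dict:
    """Fractional occupancies of body, lung and each sphere (dict of arrays)."""
    _check_extent(geometry, grid)
    occs = {
        "body": occupancy(geometry.inside_body, grid, supersample),
        "lung": occupancy(geometry.inside_lung, grid, supersample),
    }
    for i, d in enumerate(geometry.sphere_diameters):
        occs[("sphere", d)] = occupancy(
            lambda x, y, z, i=i: geometry.inside_sphere(i, x, y, z),
            grid,
            supersample,
        )
    return occs


def voxelize_activity(
    geometry: PhantomGeometry,
    activity: CompartmentActivity,
    grid: VoxelGrid,
    supersample: int = 3,
    occs: dict | None = None,
) -> ActivityMap:
    """Rasterize compartment concentrations onto the grid.

    Sub-voxel boundary anti-aliasing via fractional occupancy: a boundary voxel
    carries a mixture of the two adjoining compartment concentrations weighted by
    occupancy, so compartment-integrated activity matches the analytic
    volume x concentration to within the voxelization tolerance.
    """
    if occs is None:
        occs = compartment_occupancies(geometry, grid, supersample)
    spheres_total = np.zeros(grid.dims)
    for d in geometry.sphere_diameters:
        spheres_total = spheres_total + occs[("sphere", d)]
    bg_occ = np.clip(occs["body"] - occs["lung"] - spheres_total, 0.0, None)
    values = (
        activity.background_concentration * bg_occ
        + activity.sphere_concentration * spheres_total
        + activity.lung_concentration * occs["lung"]
    )
    return ActivityMap(grid=grid, values=values, isotope=activity.isotope)


def voxelize_attenuation(
    geometry: PhantomGeometry,
    grid: VoxelGrid,
    reference_energy_kev: float,
    supersample: int = 3,
    occs: dict | None = None,
) -> AttenuationMap:
    """Water-equivalent mu inside the body, lung-equivalent mu in the insert."""
    mu_w = mu_water(reference_energy_kev)  # validates the energy range
    mu_l = mu_lung(reference_energy_kev)
    if occs is None:
        _check_extent(geometry, grid)
        occs = {
            "body": occupancy(geometry.inside_body, grid, supersample),
            "lung": occupancy(geometry.inside_lung, grid, supersample),
        }
    values = mu_w * np.clip(occs["body"] - occs["lung"], 0.0, None) + mu_l * occs["lung"]
    return AttenuationMap(grid=grid, values=values, reference_energy_kev=reference_energy_kev)
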