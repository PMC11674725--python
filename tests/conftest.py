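import numpy as np
import pytest
from hypothesis import settings

import bremspect as bs

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return bs.build_phantom_geometry()


@pytest.fixture(scope="session")
def fine_setup():
    """Full phantom at 2 mm spacing (shortened axially to stay desk-scale)."""
    geom = bs.build_phantom_geometry(axial_length=100.0)
    grid = bs.VoxelGrid.centered((160, 128, 56), (2.0, 2.0, 2.0))
    return geom, grid


@pytest.fixture(scope="session")
def study_setup():
    """Phantom + default-study grid (64x64 @4.8 mm, 16 slices @6 mm)."""
    geom = bs.build_phantom_geometry(axial_length=90.0)
    grid = bs.VoxelGrid.centered((64, 64, 16), (4.8, 4.8, 6.0))
    return geom, grid


@pytest.fixture(scope="session")
def mini_setup():
    """A small two-sphere phantom on a 24^2 x 8 grid for fast projector tests."""
    geom = bs.build_phantom_geometry(
        sphere_diameters=(12.0, 20.0),
        sphere_ring_radius=22.0,
        axial_length=48.0,
        lung_radius=6.0,
        straight_half_width=8.0,
        arc_radius=32.0,
    )
    grid = bs.VoxelGrid.centered((24, 24, 8), (4.0, 4.0, 8.0))
    act = bs.voxelize_activity(geom, bs.CompartmentActivity(isotope="Y90"), grid)
    mu = bs.voxelize_attenuation(geom, grid, 180.0)
    return geom, grid, act, mu
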