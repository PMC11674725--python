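"""Volume / sinogram / table persistence.

Volumes travel as NIfTI (spacing and origin in the affine); sinogram sets as
one NIfTI per window plus a YAML sidecar carrying protocol, schedule row and
seed — enough metadata to reconstruct without side information.
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import (
    AcquisitionProtocol,
    ExperimentRow,
    SinogramSet,
    collimator_by_kind,
)
from .errors import AlignmentError
from .phantom import ActivityMap, AttenuationMap, VoxelGrid
from .spectra import DetectorEnergyResponse, EnergyWindow


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path, values: np.ndarray, grid: VoxelGrid):
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(grid)), str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise AlignmentError("only axis-aligned positive-spacing volumes are supported")
    grid = VoxelGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        spacing=spacing,
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return np.asarray(img.get_fdata(), dtype=float), grid


def save_sinogram_set(sino: SinogramSet, directory):
    """Persist counts (one NIfTI per window) + expected + YAML sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(sino.windows):
        nib.save(
            nib.Nifti1Image(sino.counts[i].astype(np.int32), np.eye(4)),
            str(directory / f"counts_{w.label}.nii"),
        )
        nib.save(
            nib.Nifti1Image(sino.expected[i], np.eye(4)),
            str(directory / f"expected_{w.label}.nii"),
        )
    meta = {
        "seed": int(sino.seed),
        "windows": [{"low": w.low, "high": w.high, "label": w.label} for w in sino.windows],
        "protocol": {
            "collimator_kind": sino.protocol.collimator.kind,
            "scan_time_min": sino.protocol.scan_time_min,
            "n_views": sino.protocol.n_views,
            "orbit_radius_mm": sino.protocol.orbit_radius_mm,
            "fwhm_percent_at_140": sino.protocol.response.fwhm_percent_at_140,
        },
        "row": asdict(sino.row) if sino.row is not None else None,
        "grid": {
            "dims": list(sino.grid.dims),
            "spacing": list(sino.grid.spacing),
            "origin": list(sino.grid.origin),
        } if sino.grid is not None else None,
    }
    (directory / "sinogram.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_sinogram_set(directory) -> SinogramSet:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "sinogram.yaml").read_text())
    windows = tuple(EnergyWindow(**w) for w in meta["windows"])
    counts = np.stack(
        [np.asarray(nib.load(str(directory / f"counts_{w.label}.nii")).dataobj)
         for w in windows]
    ).astype(np.int64)
    expected = np.stack(
        [np.asarray(nib.load(str(directory / f"expected_{w.label}.nii")).get_fdata())
         for w in windows]
    )
    p = meta["protocol"]
    protocol = AcquisitionProtocol(
        collimator=collimator_by_kind(p["collimator_kind"]),
        windows=windows,
        scan_time_min=p["scan_time_min"],
        n_views=p["n_views"],
        orbit_radius_mm=p["orbit_radius_mm"],
        response=DetectorEnergyResponse(p["fwhm_percent_at_140"]),
    )
    row = ExperimentRow(**meta["row"]) if meta["row"] else None
    grid = VoxelGrid(
        dims=tuple(meta["grid"]["dims"]),
        spacing=tuple(meta["grid"]["spacing"]),
        origin=tuple(meta["grid"]["origin"]),
    ) if meta["grid"] else None
    return SinogramSet(
        counts=counts, expected=expected, windows=windows,
        protocol=protocol, row=row, seed=meta["seed"], grid=grid,
    )


def save_activity_map(path, amap: ActivityMap):
    save_volume(path, amap.values, amap.grid)


def save_attenuation_map(path, mu: AttenuationMap):
    save_volume(path, mu.values, mu.grid)
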