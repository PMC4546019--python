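"""NIfTI and YAML interchange for grids, masks and configuration."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import VoxelGrid3D

__all__ = ["save_nifti", "load_nifti", "save_mask", "load_mask", "load_yaml", "save_yaml"]


def _affine(grid: VoxelGrid3D) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def save_nifti(grid: VoxelGrid3D, path: str | Path, dtype=np.float32) -> Path:
    """Write a grid as NIfTI-1; spacing/origin go through the affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=dtype), _affine(grid))
    img.header.set_zooms(grid.spacing)
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> VoxelGrid3D:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid3D(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_mask(mask: VoxelGrid3D, path: str | Path) -> Path:
    """Binary masks stored as uint8 {0,1}."""
    binary = mask.with_values((mask.values > 0).astype(np.uint8))
    return save_nifti(binary, path, dtype=np.uint8)


def load_mask(path: str | Path) -> VoxelGrid3D:
    g = load_nifti(path)
    return g.with_values(g.values > 0.5)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_sinogram(sino, path: str | Path) -> Path:
    """Sinogram as NIfTI (angles x bins x slices) plus a JSON geometry sidecar."""
    import dataclasses

    path = Path(path)
    img = nib.Nifti1Image(np.asarray(sino.prompts, dtype=np.float32), np.eye(4))
    nib.save(img, path)
    shape, spacing, origin = sino.grid_geometry
    sidecar = {
        "geometry": dataclasses.asdict(sino.geometry),
        "grid": {"shape": list(shape), "spacing": list(spacing), "origin": list(origin)},
    }
    save_json(sidecar, _sidecar_path(path))
    return path


def load_sinogram(path: str | Path):
    """Load a sinogram written by :func:`save_sinogram` (prompts only)."""
    from .petsim import ProjectionGeometry, SinogramSet

    path = Path(path)
    prompts = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    sidecar = json.loads(_sidecar_path(path).read_text())
    geom = ProjectionGeometry(**sidecar["geometry"])
    grid = sidecar["grid"]
    return SinogramSet(
        geometry=geom,
        grid_geometry=(tuple(grid["shape"]), tuple(grid["spacing"]), tuple(grid["origin"])),
        prompts=prompts,
        attenuation=np.ones_like(prompts),
        background=np.zeros_like(prompts),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")
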