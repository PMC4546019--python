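"""Core volumetric data model: axis-aligned 3-D grids, mu-maps, SUV maps, ROIs.

Every image in the package lives on a :class:`VoxelGrid3D` — a scalar array
over ``(nx, ny, nz)`` with positive voxel spacing in mm and a world origin at
the center of voxel ``(0, 0, 0)``.  The synthetic world is axis-aligned: world
coordinates are ``origin + index * spacing`` with no rotation component.

Voxelwise operations require *geometry compatibility* (equal shape, spacing
and origin); :func:`resample_to` bridges grids that differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "EmptyROIError",
    "VoxelGrid3D",
    "MuMap",
    "SUVMap",
    "ROISet",
    "SOFT_TISSUE_MU",
    "resample_to",
    "to_suv",
    "roi_stats",
]

#: Linear attenuation coefficient of soft tissue at 511 keV, cm^-1.
SOFT_TISSUE_MU = 0.1

#: Canonical reference-region names used by the reporting layer.
CANONICAL_ROI_NAMES = (
    "tongue",
    "lower_tongue",
    "masticatory_muscles",
    "cerebellum",
    "inpainted_area",
)


class GeometryError(ValueError):
    """Raised for invalid or incompatible grid geometries."""


class EmptyROIError(ValueError):
    """Raised when a ROI mask selects no voxels."""


@dataclass(frozen=True)
class VoxelGrid3D:
    """A 3-D scalar volume with voxel spacing (mm) and world origin (mm).

    Parameters
    ----------
    values
        Scalar array of shape ``(nx, ny, nz)``.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all > 0.
    origin
        World coordinates of the center of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise GeometryError(f"values must be 3-D with all dims >= 1, got shape {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def compatible_with(self, other: "VoxelGrid3D") -> bool:
        return self.geometry() == other.geometry()

    def require_compatible(self, other: "VoxelGrid3D") -> None:
        if not self.compatible_with(other):
            raise GeometryError(
                f"incompatible geometries: {self.geometry()} vs {other.geometry()}"
            )

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "VoxelGrid3D":
        """Same geometry, new values."""
        return replace(self, values=np.asarray(values))

    def like(self, fill: float = 0.0, dtype=np.float64) -> "VoxelGrid3D":
        return self.with_values(np.full(self.shape, fill, dtype=dtype))


@dataclass(frozen=True)
class MuMap:
    """Attenuation map in cm^-1 with a body mask and a provenance tag.

    ``provenance`` is one of ``{"dixon", "inpainted", "truth"}``.  Inpainting
    only adds attenuation: an inpainted map is voxelwise >= its Dixon source.
    """

    grid: VoxelGrid3D
    body_mask: VoxelGrid3D
    provenance: str = "dixon"

    _PROVENANCES = ("dixon", "inpainted", "truth")

    def __post_init__(self) -> None:
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")
        if np.any(self.grid.values < 0):
            raise ValueError("mu-map values must be >= 0 (cm^-1)")
        self.grid.require_compatible(self.body_mask)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def with_values(self, values: np.ndarray, provenance: str | None = None) -> "MuMap":
        return MuMap(
            grid=self.grid.with_values(values),
            body_mask=self.body_mask,
            provenance=provenance or self.provenance,
        )


@dataclass(frozen=True)
class SUVMap:
    """Dimensionless standardized-uptake-value image.

    SUV = activity concentration [Bq/mL] x body weight [g] / injected dose [Bq],
    i.e. activity normalized such that a uniform distribution of the dose over
    the body would read 1.0 everywhere.
    """

    grid: VoxelGrid3D
    injected_dose_bq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0 or self.body_weight_g <= 0:
            raise ValueError("dose and weight must be positive")
        if np.any(self.grid.values < 0):
            raise ValueError("SUV values must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class ROISet:
    """Named binary reference-region masks, all on one geometry."""

    masks: dict[str, VoxelGrid3D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.masks.values())
        for g in grids[1:]:
            grids[0].require_compatible(g)
        for name, g in self.masks.items():
            if not np.any(g.values):
                raise EmptyROIError(f"ROI {name!r} is empty")

    def __getitem__(self, name: str) -> VoxelGrid3D:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def items(self):
        return self.masks.items()

    def with_mask(self, name: str, mask: VoxelGrid3D) -> "ROISet":
        new = dict(self.masks)
        new[name] = mask
        return ROISet(new)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_to(
    grid_src: VoxelGrid3D,
    ref: VoxelGrid3D | tuple,
    order: int = 1,
) -> VoxelGrid3D:
    """Resample ``grid_src`` onto the geometry of ``ref``.

    ``order=1`` gives trilinear interpolation (scalars), ``order=0`` nearest
    neighbor (masks).  Voxels of the reference grid whose centers fall outside
    the source extent are set to 0.
    """
    if isinstance(ref, VoxelGrid3D):
        ref_shape, ref_spacing, ref_origin = ref.geometry()
    else:
        ref_shape, ref_spacing, ref_origin = ref
    ref_spacing = tuple(float(s) for s in ref_spacing)
    if any(s <= 0 for s in ref_spacing):
        raise GeometryError(f"reference spacing must be positive, got {ref_spacing}")

    if (grid_src.shape, grid_src.spacing, grid_src.origin) == (
        tuple(ref_shape),
        ref_spacing,
        tuple(float(o) for o in ref_origin),
    ):
        return grid_src.with_values(grid_src.values.copy())

    # Continuous source index of each reference voxel center:
    # idx_src = (origin_ref + i*spacing_ref - origin_src) / spacing_src
    coords = np.meshgrid(
        *[
            (ref_origin[a] + np.arange(ref_shape[a]) * ref_spacing[a] - grid_src.origin[a])
            / grid_src.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        grid_src.values.astype(np.float64),
        np.stack(coords),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return VoxelGrid3D(out, ref_spacing, tuple(float(o) for o in ref_origin))


def to_suv(
    activity_bq_ml: VoxelGrid3D,
    dose_bq: float,
    weight_g: float,
) -> SUVMap:
    """Convert an activity-concentration image (Bq/mL) to SUV."""
    if dose_bq <= 0:
        raise ValueError(f"dose must be > 0 Bq, got {dose_bq}")
    if weight_g <= 0:
        raise ValueError(f"weight must be > 0 g, got {weight_g}")
    suv = activity_bq_ml.with_values(activity_bq_ml.values * (weight_g / dose_bq))
    return SUVMap(grid=suv, injected_dose_bq=dose_bq, body_weight_g=weight_g)


def roi_stats(suv: SUVMap | VoxelGrid3D, mask: VoxelGrid3D) -> tuple[float, float, int]:
    """Mean, max and voxel count of an image over a binary mask."""
    grid = suv.grid if isinstance(suv, SUVMap) else suv
    grid.require_compatible(mask)
    sel = mask.values.astype(bool)
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError("ROI mask selects no voxels")
    vals = grid.values[sel]
    return float(vals.mean()), float(vals.max()), n
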