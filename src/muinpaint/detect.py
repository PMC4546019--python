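"""Detection and topological classification of signal-void components.

A *signal void* is a connected component of sub-air-threshold voxels inside
(or touching) the anatomical envelope of a mu-map.  Each component is
classified by reachability:

* ``outer`` — path-connected through air to the background air component that
  touches the grid boundary (the void breaches the body contour);
* ``inner`` — enclosed by the anatomical surface.

Voids are merged with 26-connectivity (generous), while the breach test uses
6-connectivity (conservative); both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import MuMap, VoxelGrid3D

__all__ = [
    "AIR_THRESHOLD",
    "VoidComponent",
    "VoidComponents",
    "detect_voids",
    "classify_component",
    "volume_ml",
    "background_air_mask",
    "body_envelope",
]

#: Default air threshold in cm^-1: well below fat (0.086), above float noise.
AIR_THRESHOLD = 0.005


@dataclass(frozen=True)
class VoidComponent:
    id: int
    voxel_count: int
    volume_ml: float
    artifact_class: str  # {"inner", "outer"}
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class VoidComponents:
    """Labeled air components intersecting the body envelope."""

    labels: VoxelGrid3D  # int labels, 0 = none
    components: tuple[VoidComponent, ...]

    def __len__(self) -> int:
        return len(self.components)

    def mask(self, comp_id: int) -> np.ndarray:
        return self.labels.values == comp_id

    def union_mask(self) -> np.ndarray:
        return self.labels.values > 0

    def by_class(self, artifact_class: str) -> tuple[VoidComponent, ...]:
        return tuple(c for c in self.components if c.artifact_class == artifact_class)

    def table(self) -> list[dict]:
        return [
            {
                "id": c.id,
                "class": c.artifact_class,
                "voxel_count": c.voxel_count,
                "volume_ml": c.volume_ml,
                "bbox": c.bbox,
            }
            for c in self.components
        ]


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def body_envelope(body_mask: np.ndarray) -> np.ndarray:
    """Anatomical envelope: largest non-air component plus internal cavities.

    Used when no generator truth is available; hole-filling recovers internal
    cavities as part of the envelope.
    """
    lab, n = ndimage.label(body_mask, structure=_structure(26))
    if n == 0:
        return np.zeros_like(body_mask, dtype=bool)
    largest = np.argmax(ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))) + 1
    return ndimage.binary_fill_holes(lab == largest)


def background_air_mask(air: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Air voxels path-connected (given connectivity) to the grid boundary."""
    lab, n = ndimage.label(air, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(air, dtype=bool)
    border_labels = np.unique(
        np.concatenate(
            [
                lab[0].ravel(), lab[-1].ravel(),
                lab[:, 0].ravel(), lab[:, -1].ravel(),
                lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels > 0]
    return np.isin(lab, border_labels)


def classify_component(
    comp_mask: np.ndarray,
    background_air: np.ndarray,
    air: np.ndarray,
    connectivity: int = 6,
) -> str:
    """``outer`` iff the component reaches background air through air voxels."""
    if not comp_mask.any():
        raise ValueError("empty component")
    # the component is itself air; reachability = shared connected air component
    lab, _ = ndimage.label(air | comp_mask, structure=_structure(connectivity))
    comp_labels = np.unique(lab[comp_mask])
    comp_labels = comp_labels[comp_labels > 0]
    if np.isin(lab[background_air], comp_labels).any():
        return "outer"
    return "inner"


def volume_ml(comp_mask: np.ndarray, grid: VoxelGrid3D) -> float:
    """Component volume in mL (voxel count x voxel volume)."""
    if not comp_mask.any():
        raise ValueError("empty component")
    return float(comp_mask.sum() * grid.voxel_volume_ml)


def detect_voids(
    mu: MuMap,
    air_threshold: float = AIR_THRESHOLD,
    connectivity: int = 26,
    reach_connectivity: int = 6,
) -> VoidComponents:
    """Label sub-threshold air components intersecting the body envelope.

    Components made purely of background air (no voxel inside the dilated
    body envelope's interior) are excluded; a breaching void that merges with
    background air is kept and restricted to the envelope.
    """
    if air_threshold <= 0:
        raise ValueError(f"air threshold must be > 0 cm^-1, got {air_threshold}")
    air = mu.values < air_threshold
    envelope = mu.body_mask.values.astype(bool)
    if not envelope.any():
        envelope = body_envelope(~air)
    envelope_d = ndimage.binary_dilation(envelope, _structure(26))

    candidate = air & envelope_d
    lab, n = ndimage.label(candidate, structure=_structure(connectivity))
    background = background_air_mask(air, reach_connectivity)

    out_labels = np.zeros_like(lab)
    comps: list[VoidComponent] = []
    next_id = 1
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp_full = lab[sl] == i
        inside = comp_full & envelope[sl]
        if not inside.any():
            continue  # background-only air
        # keep only the in-envelope part of the component as the void; the
        # breach test must also run on that part — the 26-connected candidate
        # can diagonally pick up background air across a sub-voxel body wall
        mask = _embed(inside, sl, lab.shape)
        cls = classify_component(mask, background, air, reach_connectivity)
        out_labels[mask] = next_id
        idx = np.argwhere(mask)
        bbox = tuple((int(idx[:, a].min()), int(idx[:, a].max()) + 1) for a in range(3))
        count = int(mask.sum())
        comps.append(
            VoidComponent(
                id=next_id,
                voxel_count=count,
                volume_ml=count * mu.grid.voxel_volume_ml,
                artifact_class=cls,
                bbox=bbox,
            )
        )
        next_id += 1
    return VoidComponents(
        labels=mu.grid.with_values(out_labels),
        components=tuple(comps),
    )


def _embed(sub: np.ndarray, sl, shape) -> np.ndarray:
    full = np.zeros(shape, dtype=bool)
    full[sl] = sub
    return full
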