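"""Seeded synthetic head/neck phantoms with dental-artifact signal voids.

The generator emulates the inputs of a PET/MR exam of the head and neck at
desk scale: a ground-truth attenuation map (soft tissue 0.1 cm^-1, a thin
subcutaneous fat shell, internal air in the oral cavity and paranasal
sinuses), a smooth tracer-activity map with designated reference regions
(tongue, lower tongue, left/right masticatory muscles, cerebellum), and a
Dixon-water-like anatomical image.  Dental-artifact voids of two topological
classes can be injected into the Dixon-style mu-map:

* ``inner``  — the void is fully enclosed by the anatomical surface;
* ``outer``  — the void breaches the cheek through a channel and is
  artificially connected to the background air.

The truth map is never modified by an artifact; only the Dixon-style map has
the void zeroed, which is exactly the failure mode of Dixon-based attenuation
maps near metal implants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import SOFT_TISSUE_MU, MuMap, ROISet, VoxelGrid3D

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "ArtifactSpec",
    "PhantomTruth",
    "make_phantom",
    "inject_artifact",
    "make_population",
]


class PhantomSpecError(ValueError):
    """Raised for phantom or artifact specifications that cannot be realized."""


# default reference-region placements: name -> ((dx, y, z) mm, semi-axes mm)
# dx is relative to the head axis, y relative to the in-plane center, z absolute.
_DEFAULT_ROIS = {
    "tongue": ((0.0, 32.0, 46.0), (15.0, 12.0, 8.0)),
    "lower_tongue": ((0.0, 18.0, 20.0), (13.0, 11.0, 8.0)),
    "masticatory_left": ((-41.0, 18.0, 62.0), (9.0, 9.0, 12.0)),
    "masticatory_right": ((41.0, 18.0, 62.0), (9.0, 9.0, 12.0)),
    "cerebellum": ((0.0, -45.0, 78.0), (21.0, 17.0, 13.0)),
}

_DEFAULT_ACTIVITY = {
    "soft": 1.0,
    "fat": 0.7,
    "tongue": 1.3,
    "lower_tongue": 1.0,
    "masticatory": 0.8,
    "cerebellum": 2.5,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head/neck phantom.

    All lengths in mm, attenuation in cm^-1, activity in arbitrary units.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.6, 2.6, 3.1)
    head_semiaxes: tuple[float, float, float] = (72.0, 88.0, 58.0)
    head_center_z: float = 85.0
    neck_radius: float = 44.0
    neck_top_z: float = 40.0
    neck_y_offset: float = -10.0
    oral_cavity_center: tuple[float, float, float] = (0.0, 38.0, 52.0)
    oral_cavity_semiaxes: tuple[float, float, float] = (24.0, 13.0, 10.0)
    sinus_centers: tuple[tuple[float, float, float], ...] = (
        (-17.0, 42.0, 86.0),
        (17.0, 42.0, 86.0),
    )
    sinus_radius: float = 8.0
    dental_centroid: tuple[float, float, float] = (0.0, 61.0, 52.0)
    rois: dict = field(default_factory=lambda: dict(_DEFAULT_ROIS))
    activity: dict = field(default_factory=lambda: dict(_DEFAULT_ACTIVITY))
    activity_smooth_mm: float = 3.0
    fat_thickness_mm: float = 6.0
    fat_mu: float = 0.086
    water_soft: float = 100.0
    water_fat: float = 50.0
    water_noise_sigma: float = 10.0
    water_noise_smooth_mm: float = 4.0
    jitter_std_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fat_mu >= SOFT_TISSUE_MU:
            raise PhantomSpecError("fat_mu must be < soft-tissue 0.1 cm^-1")

    def with_(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ArtifactSpec:
    """A dental-artifact void to inject into the Dixon-style mu-map.

    The void is a union of seeded random ellipsoids around ``centroid``
    (defaults to the phantom's dental region), scaled until the realized
    newly-air volume hits ``target_volume_ml`` within tolerance.  For the
    ``outer`` class a cylindrical breach channel connects the void to the
    background air through the cheek.
    """

    artifact_class: str = "inner"  # {"inner", "outer"}
    target_volume_ml: float = 6.0
    centroid: tuple[float, float, float] | None = None  # mm; None -> spec.dental_centroid
    n_lobes: int = 3
    lobe_scatter_mm: float = 6.0
    axis_ratios: tuple[float, float, float] = (2.0, 0.55, 0.9)
    channel_radius_mm: float = 5.0
    connect_to_air: bool = False  # allow the void to merge with anatomical air
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artifact_class not in ("inner", "outer"):
            raise PhantomSpecError("artifact_class must be 'inner' or 'outer'")
        if self.target_volume_ml < 0:
            raise PhantomSpecError("target volume must be >= 0 mL")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth bundle for one phantom."""

    spec: PhantomSpec
    mu_truth: MuMap
    mu_dixon: MuMap
    activity_truth: VoxelGrid3D
    water_image: VoxelGrid3D
    rois: ROISet
    void_truth_mask: VoxelGrid3D
    body_mask_truth: VoxelGrid3D
    air_cavity_mask: VoxelGrid3D
    artifact: ArtifactSpec | None = None
    artifact_volume_ml: float = 0.0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _coords(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid(X, Y, Z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def _smooth(values: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    if sigma_mm <= 0:
        return values
    sig = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_filter(values, sig)


def _jit(rng: np.random.Generator, std: float, n: int = 3) -> np.ndarray:
    return rng.normal(0.0, std, size=n) if std > 0 else np.zeros(n)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate an artifact-free phantom; deterministic for a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    X, Y, Z = _coords(shape, spacing)
    cx = (shape[0] - 1) / 2 * spacing[0]
    cy = (shape[1] - 1) / 2 * spacing[1]
    std = spec.jitter_std_mm

    # anatomy with per-structure jitter (drawn in a fixed order for determinism)
    head_c = np.array([cx, cy, spec.head_center_z]) + _jit(rng, std)
    head_ax = np.maximum(np.array(spec.head_semiaxes) + _jit(rng, std), 10.0)
    neck_c = np.array([cx, cy + spec.neck_y_offset]) + _jit(rng, std, 2)
    cav_c = np.array([cx, cy, 0.0]) + np.array(spec.oral_cavity_center) + _jit(rng, std)
    cav_ax = np.maximum(np.array(spec.oral_cavity_semiaxes) + _jit(rng, std * 0.5), 3.0)
    sinus_cs = [
        np.array([cx, cy, 0.0]) + np.array(c) + _jit(rng, std * 0.5)
        for c in spec.sinus_centers
    ]
    roi_jit = {name: _jit(rng, std * 0.5) for name in sorted(spec.rois)}

    head = _ellipsoid(X, Y, Z, head_c, head_ax)
    neck = (((X - neck_c[0]) ** 2 + (Y - neck_c[1]) ** 2) <= spec.neck_radius**2) & (
        Z <= spec.neck_top_z
    )
    body = head | neck

    cavity = _ellipsoid(X, Y, Z, cav_c, cav_ax)
    sinus = np.zeros(shape, dtype=bool)
    for c in sinus_cs:
        sinus |= _ellipsoid(X, Y, Z, c, (spec.sinus_radius,) * 3)
    # anatomical air keeps a full one-voxel tissue wall to the outside:
    # the synthetic mouth is closed, so internal cavities are always enclosed
    enclosed = ndimage.binary_erosion(
        body, ndimage.generate_binary_structure(3, 3)
    )
    air_cavities = (cavity | sinus) & enclosed
    tissue = body & ~air_cavities

    # subcutaneous fat shell: tissue within fat_thickness_mm of the outer surface
    dist_in = ndimage.distance_transform_edt(body, sampling=spacing)
    fat = tissue & (dist_in <= spec.fat_thickness_mm)

    mu = np.zeros(shape)
    mu[tissue] = SOFT_TISSUE_MU
    mu[fat] = spec.fat_mu

    # reference regions (trimmed to tissue)
    roi_masks: dict[str, np.ndarray] = {}
    for name, (offset, semiaxes) in spec.rois.items():
        c = np.array([cx + offset[0], cy + offset[1], offset[2]]) + roi_jit[name]
        m = _ellipsoid(X, Y, Z, c, semiaxes)
        inside = m & body
        if m.sum() == 0 or inside.sum() < 0.95 * m.sum():
            raise PhantomSpecError(f"ROI {name!r} is (partly) outside the body")
        roi_masks[name] = m & tissue

    # activity: per-region plateau levels, smoothed, air and background zeroed
    lv = spec.activity
    act = np.zeros(shape)
    act[tissue] = lv["soft"]
    act[fat] = lv["fat"]
    for name, key in (
        ("tongue", "tongue"),
        ("lower_tongue", "lower_tongue"),
        ("masticatory_left", "masticatory"),
        ("masticatory_right", "masticatory"),
        ("cerebellum", "cerebellum"),
    ):
        if name in roi_masks and key in lv:
            act[roi_masks[name]] = lv[key]
    act = _smooth(act, spec.activity_smooth_mm, spacing)
    act[~tissue] = 0.0
    act[tissue] = np.maximum(act[tissue], 0.05 * lv["soft"])

    # Dixon-water-like image: monotone in soft-tissue content plus smooth noise
    water = np.zeros(shape)
    water[tissue] = spec.water_soft
    water[fat] = spec.water_fat
    if spec.water_noise_sigma > 0:
        noise = _smooth(
            rng.normal(0.0, spec.water_noise_sigma, size=shape),
            spec.water_noise_smooth_mm,
            spacing,
        )
        water = np.clip(water + noise * tissue, 0.0, None)

    def grid(v):
        return VoxelGrid3D(v, spacing)

    body_grid = grid(body)
    mu_grid = grid(mu)
    rois = ROISet(
        {
            **{n: grid(m) for n, m in roi_masks.items()},
            "masticatory_muscles": grid(
                roi_masks["masticatory_left"] | roi_masks["masticatory_right"]
            ),
        }
    )
    mu_truth = MuMap(mu_grid, body_grid, provenance="truth")
    mu_dixon = MuMap(grid(mu.copy()), body_grid, provenance="dixon")
    return PhantomTruth(
        spec=spec,
        mu_truth=mu_truth,
        mu_dixon=mu_dixon,
        activity_truth=grid(act),
        water_image=grid(water),
        rois=rois,
        void_truth_mask=grid(np.zeros(shape, dtype=bool)),
        body_mask_truth=body_grid,
        air_cavity_mask=grid(air_cavities),
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def _void_union(X, Y, Z, centers, base_axes, scale) -> np.ndarray:
    m = np.zeros(np.broadcast(X, Y, Z).shape, dtype=bool)
    for c in centers:
        m |= _ellipsoid(X, Y, Z, c, tuple(a * scale for a in base_axes))
    return m


def inject_artifact(ph: PhantomTruth, art: ArtifactSpec) -> PhantomTruth:
    """Zero the Dixon-style mu-map on a generated void of the requested class.

    The realized newly-air volume is brought within 15% of the target by
    bisection on the lobe scale.  ``mu_truth`` is left untouched.
    """
    if art.target_volume_ml == 0:
        return ph
    spec = ph.spec
    shape, spacing = spec.shape, spec.spacing
    X, Y, Z = _coords(shape, spacing)
    cx = (shape[0] - 1) / 2 * spacing[0]
    cy = (shape[1] - 1) / 2 * spacing[1]
    rng = np.random.default_rng(art.seed)

    centroid = art.centroid
    if centroid is None:
        d = spec.dental_centroid
        centroid = (cx + d[0], cy + d[1], d[2])
    centroid = np.asarray(centroid, dtype=float)

    body = ph.body_mask_truth.values.astype(bool)
    air = ph.air_cavity_mask.values.astype(bool)
    struct = ndimage.generate_binary_structure(3, 3)
    if not body[tuple(np.round(centroid / spacing).astype(int))]:
        raise PhantomSpecError("artifact centroid is outside the body")

    # region the void may occupy
    if art.artifact_class == "inner":
        allowed = ndimage.binary_erosion(body, struct, iterations=2)
    else:
        allowed = body
    if not art.connect_to_air:
        allowed &= ~ndimage.binary_dilation(air, struct, iterations=2)
    else:
        allowed &= ~air
    # keep the void in the dental slab
    zc = centroid[2]
    allowed &= (np.broadcast_to(Z, shape) >= zc - 36) & (np.broadcast_to(Z, shape) <= zc + 36)

    voxvol = ph.mu_truth.grid.voxel_volume_ml
    capacity = allowed.sum() * voxvol
    if art.target_volume_ml > 0.9 * capacity:
        raise PhantomSpecError(
            f"target {art.target_volume_ml} mL exceeds dental-region capacity "
            f"({capacity:.1f} mL)"
        )

    offsets = rng.normal(0.0, art.lobe_scatter_mm, size=(max(art.n_lobes - 1, 0), 3))
    centers = [centroid] + [centroid + o for o in offsets]

    def realized(scale: float) -> np.ndarray:
        m = _void_union(X, Y, Z, centers, art.axis_ratios, scale) & allowed
        # one artifact = one connected void: drop satellite pieces clipped off
        # by the allowed region
        lab, n = ndimage.label(m, struct)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
            m = lab == (np.argmax(sizes) + 1)
        return m

    target = art.target_volume_ml
    lo, hi = 0.0, 2.0
    while realized(hi).sum() * voxvol < target:
        hi *= 1.6
        if hi > 300:
            raise PhantomSpecError("cannot realize target volume in dental region")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        v = realized(mid).sum() * voxvol
        if abs(v - target) <= 0.08 * target:
            lo = hi = mid
            break
        if v < target:
            lo = mid
        else:
            hi = mid
    void = realized(0.5 * (lo + hi))

    if art.artifact_class == "outer":
        # cylindrical breach channel through the cheek (+y) out of the body
        r2 = art.channel_radius_mm**2
        channel = (
            ((np.broadcast_to(X, shape) - centroid[0]) ** 2
             + (np.broadcast_to(Z, shape) - centroid[2]) ** 2) <= r2
        ) & (np.broadcast_to(Y, shape) >= centroid[1])
        void |= channel & body & ~air

    newly_air = void & (ph.mu_truth.values > 0)
    vol_ml = float(newly_air.sum() * voxvol)

    mu_dixon = ph.mu_dixon.values.copy()
    mu_dixon[newly_air] = 0.0
    # the susceptibility void hits every image of the MR acquisition
    water = ph.water_image.values.copy()
    water[newly_air] = 0.0
    grid = ph.mu_truth.grid
    return dataclasses.replace(
        ph,
        mu_dixon=MuMap(grid.with_values(mu_dixon), ph.body_mask_truth, provenance="dixon"),
        water_image=grid.with_values(water),
        void_truth_mask=grid.with_values(newly_air),
        artifact=art,
        artifact_volume_ml=vol_ml,
    )


def make_population(spec: PhantomSpec, n: int, seed: int = 0) -> list[PhantomTruth]:
    """``n`` artifact-free phantoms with independent anatomical jitter.

    Member ``i`` uses a seed derived deterministically from ``(seed, i)``.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    out = []
    for i in range(n):
        member_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        out.append(make_phantom(spec.with_(seed=member_seed)))
    return out
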