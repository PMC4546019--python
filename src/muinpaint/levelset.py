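"""Chan–Vese-type contour closing of breached body outlines (workflow step 1).

For voids that breach the anatomical surface, the attenuation map alone
cannot say where the body ends: the void and the background air are one
connected air region.  The non-attenuation-corrected PET image still shows
activity inside the true body, so the outer contour is recovered by a
two-region level-set energy with a *spatially switched* data term:

``E = nu |contour| + lambda_mr (1-w) two-region residual on the mu-map
                   + lambda_pet  w    two-region residual on NAC-PET``

where the switch field ``w`` is 1 on a dilation of the breaching (outer)
voids and 0 elsewhere.  In intact areas the contour therefore follows the
mu-map; inside breached regions it follows the NAC-PET edge.  Both channels
are normalized to [0, 1] by a robust percentile stretch, which makes the
parameterization invariant to global intensity scaling (and hence to tracer
and count level).

Void voxels that end up enclosed by the recovered contour are filled with
the soft-tissue attenuation value (0.1 cm^-1) by :func:`close_and_fill`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detect import AIR_THRESHOLD, VoidComponents, background_air_mask, detect_voids
from .grids import SOFT_TISSUE_MU, MuMap, VoxelGrid3D

__all__ = [
    "LevelSetParams",
    "ContourResult",
    "auto_parameters",
    "evolve_contour",
    "close_and_fill",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LevelSetParams:
    """Parameters of the switched two-channel Chan–Vese energy.

    Weights act on images normalized to [0, 1]; ``nu`` penalizes contour
    area (in voxel units), ``switch_dilation_vox`` sets how far around a
    breaching void the PET channel takes over.
    """

    nu: float = 0.15
    lambda_mr: float = 1.0
    lambda_pet: float = 1.5
    switch_dilation_vox: int = 3
    max_iterations: int = 300
    reinit_interval: int = 20
    tolerance: float = 1e-5
    dt: float = 0.45
    epsilon: float = 1.5  # smoothed-Heaviside width, voxels

    def __post_init__(self) -> None:
        if self.lambda_mr < 0 or self.lambda_pet < 0:
            raise ValueError("channel weights must be >= 0")
        if self.lambda_mr == 0 and self.lambda_pet == 0:
            raise ValueError("at least one channel weight must be > 0")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.nu < 0:
            raise ValueError("curvature weight must be >= 0")


@dataclass(frozen=True)
class ContourResult:
    body: VoxelGrid3D  # recovered body region (single component, holes kept inside)
    filled_by_closing: VoxelGrid3D  # void voxels enclosed by the contour
    iterations: int
    converged: bool
    energy: tuple = field(default=())


def _normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(values, [1, 99])
    if hi <= lo:
        hi = values.max()
        lo = values.min()
    if hi <= lo:
        return np.zeros_like(values, dtype=float)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def auto_parameters(nac_pet: VoxelGrid3D, mu_dixon: MuMap) -> LevelSetParams:
    """Derive level-set parameters from the PET signal outside the mu-map body.

    The PET weight is set from the contrast between the PET background
    (outside the mu-map's naive body) and the PET intensity adjacent to
    breaching voids, on the percentile-normalized PET image; it is clamped to
    [0.5, 4].  Deterministic, and invariant to global PET scaling.
    """
    mu_dixon.grid.require_compatible(nac_pet)
    naive_body = mu_dixon.values >= AIR_THRESHOLD
    outside = ~ndimage.binary_dilation(
        ndimage.binary_fill_holes(naive_body),
        ndimage.generate_binary_structure(3, 3),
        iterations=2,
    )
    if not outside.any():
        raise ValueError("degenerate input: no voxels outside the body envelope")
    pet = _normalize(nac_pet.values)
    bg_mean = float(pet[outside].mean())

    voids = detect_voids(mu_dixon)
    outer = [c for c in voids.components if c.artifact_class == "outer"]
    if outer:
        region = np.isin(voids.labels.values, [c.id for c in outer])
        region = ndimage.binary_dilation(region, iterations=2)
    else:  # no breach: sample the band just inside the naive body surface
        region = naive_body & ~ndimage.binary_erosion(naive_body, iterations=2)
    adj_mean = float(pet[region].mean()) if region.any() else bg_mean
    contrast = max(adj_mean - bg_mean, 0.05)
    lambda_pet = float(np.clip(0.6 / contrast, 0.5, 4.0))
    return LevelSetParams(lambda_mr=1.0, lambda_pet=lambda_pet)


def _curvature(phi: np.ndarray) -> np.ndarray:
    gx, gy, gz = np.gradient(phi)
    norm = np.sqrt(gx * gx + gy * gy + gz * gz) + 1e-8
    nxx = np.gradient(gx / norm, axis=0)
    nyy = np.gradient(gy / norm, axis=1)
    nzz = np.gradient(gz / norm, axis=2)
    return nxx + nyy + nzz


def _signed_distance(inside: np.ndarray) -> np.ndarray:
    # positive inside, negative outside, in voxel units
    if not inside.any():
        return -np.ones(inside.shape)
    d_out = ndimage.distance_transform_edt(~inside)
    d_in = ndimage.distance_transform_edt(inside)
    return np.where(inside, d_in, -d_out).astype(float)


def evolve_contour(
    mu_dixon: MuMap,
    nac_pet: VoxelGrid3D,
    params: LevelSetParams | None = None,
    voids: VoidComponents | None = None,
) -> ContourResult:
    """Minimize the switched two-channel energy; return the recovered body.

    The level set starts from the signed distance to the mu-map's naive body
    threshold and is re-initialized periodically.  Convergence is declared
    when the fraction of voxels changing side stays below ``tolerance`` for
    five consecutive iterations; otherwise the result is returned at
    ``max_iterations`` with ``converged=False``.
    """
    if params is None:
        params = auto_parameters(nac_pet, mu_dixon)
    mu_dixon.grid.require_compatible(nac_pet)
    if voids is None:
        voids = detect_voids(mu_dixon)

    i_mr = _normalize(mu_dixon.values)
    i_pet = _normalize(nac_pet.values)
    outer_ids = [c.id for c in voids.components if c.artifact_class == "outer"]
    w = np.zeros(i_mr.shape)
    if outer_ids and params.lambda_pet > 0:
        region = np.isin(voids.labels.values, outer_ids)
        region = ndimage.binary_dilation(region, iterations=params.switch_dilation_vox)
        w[region] = 1.0

    weights = ((params.lambda_mr, 1.0 - w, i_mr), (params.lambda_pet, w, i_pet))
    naive_inside = ndimage.binary_fill_holes(mu_dixon.values >= AIR_THRESHOLD)
    phi = _signed_distance(naive_inside)

    n_total = phi.size
    quiet = 0
    converged = False
    energy: list[float] = []
    it = 0
    for it in range(1, params.max_iterations + 1):
        inside = phi > 0
        delta = (params.epsilon / np.pi) / (params.epsilon**2 + phi * phi)

        force = np.zeros_like(phi)
        e_data = 0.0
        n_in = inside.sum()
        for lam, wch, img in weights:
            if lam == 0 or not np.any(wch):
                continue
            # global two-region means (classic Chan–Vese); the switch field
            # only localizes which channel drives the front
            c1 = float(img[inside].mean()) if n_in else 0.0
            c2 = float(img[~inside].mean()) if n_in < img.size else 0.0
            force += lam * wch * ((img - c2) ** 2 - (img - c1) ** 2)
            e_data += lam * float(
                (wch * np.where(inside, (img - c1) ** 2, (img - c2) ** 2)).sum()
            )
        if params.nu > 0:
            force = force + params.nu * _curvature(phi)
        energy.append(e_data)

        band = np.abs(phi) < 3 * params.epsilon
        scale = np.abs(force[band]).max() if band.any() else np.abs(force).max()
        if scale > 0:
            # normalize so the front moves at most ~dt voxels per iteration
            delta_max = 1.0 / (np.pi * params.epsilon)
            phi = phi + params.dt * (delta / delta_max) * (force / scale)
        flips = int(((phi > 0) ^ inside).sum())
        frac = flips / n_total
        quiet = quiet + 1 if frac < params.tolerance else 0
        if quiet >= 5:
            converged = True
            break
        if params.reinit_interval and it % params.reinit_interval == 0:
            phi = _signed_distance(phi > 0)

    if not converged:
        log.warning("level set did not converge after %d iterations", it)
    if len(energy) > 2 and energy[-1] > energy[0]:
        log.warning("level-set data energy increased over the run")

    inside = phi > 0
    # keep the largest connected component and treat enclosed air as interior
    lab, n = ndimage.label(inside)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        inside = lab == (np.argmax(sizes) + 1)
    body = ndimage.binary_fill_holes(inside)

    air = mu_dixon.values < AIR_THRESHOLD
    background = background_air_mask(air)
    envelope = mu_dixon.body_mask.values.astype(bool)
    if not envelope.any():
        from .detect import body_envelope

        envelope = body_envelope(~air)
    # Fill what the contour enclosed, restricted to the anatomical envelope so
    # that no true-background voxel is ever touched.  The zero level can sit
    # sub-voxel inside the true surface and leave a one-voxel air rim of the
    # void connected to background; within the PET-driven switch region the
    # fill is therefore grown to the envelope boundary.
    filled = air & background & body & envelope
    if w.any():
        switch = (w > 0) & envelope & air & background
        for _ in range(8):
            grown = ndimage.binary_dilation(body | filled) & switch & ~filled
            if not grown.any():
                break
            filled |= grown
    return ContourResult(
        body=mu_dixon.grid.with_values(body),
        filled_by_closing=mu_dixon.grid.with_values(filled),
        iterations=it,
        converged=converged,
        energy=tuple(energy),
    )


def close_and_fill(mu_dixon: MuMap, contour: ContourResult) -> MuMap:
    """Set background-connected void voxels inside the contour to 0.1 cm^-1.

    Only voxels that were sub-threshold air in the input and enclosed by the
    recovered contour are changed; everything else is untouched.  The result
    keeps ``dixon`` provenance — the atlas step is still pending.
    """
    fill = contour.filled_by_closing.values.astype(bool)
    out = mu_dixon.values.copy()
    out[fill] = SOFT_TISSUE_MU
    return MuMap(mu_dixon.grid.with_values(out), mu_dixon.body_mask, mu_dixon.provenance)
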