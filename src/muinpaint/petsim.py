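"""Attenuated parallel-beam projection and OP-OSEM reconstruction.

The scanner is modelled slice-by-slice as a 2-D parallel-beam system: the
attenuation-correction bias that matters here is in-plane mismatch between
the attenuation map used in the system model and the true attenuation, so a
fully 3-D geometry would add cost without adding coverage.

The projector is a sparse system matrix built by ray-driven sampling with
bilinear interpolation; the back projector is its transpose, so forward and
back projection are exact adjoints.  Expected data follow the ordinary-
Poisson model ``prompts = attenuation x line-integral(activity) + background``
and reconstruction is multiplicative (OS)EM with the attenuation factors of a
chosen mu-map in the system model, a flat background surrogate in the
denominator, and a Gaussian post-filter applied last.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, sparse

from .grids import GeometryError, MuMap, VoxelGrid3D

__all__ = [
    "ProjectionGeometry",
    "ReconParams",
    "SinogramSet",
    "system_matrix",
    "attenuation_factors",
    "forward_project",
    "sample_counts",
    "scale_to_counts",
    "reconstruct_osem",
    "poisson_loglik",
]

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class ProjectionGeometry:
    """2-D parallel-beam geometry, applied to every axial slice."""

    n_angles: int = 63
    n_bins: int = 96
    bin_spacing_mm: float = 2.6
    step_fraction: float = 0.5  # ray sampling step / min in-plane voxel size

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1 or self.bin_spacing_mm <= 0:
            raise GeometryError("invalid projection geometry")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def bin_offsets(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2) * self.bin_spacing_mm


@dataclass(frozen=True)
class ReconParams:
    """OP-OSEM settings (clinical defaults: 3 it, 21 subsets, 4-mm filter)."""

    n_iterations: int = 3
    n_subsets: int = 21
    postfilter_fwhm_mm: float = 4.0
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if self.postfilter_fwhm_mm < 0 or self.background_fraction < 0:
            raise ValueError("post-filter FWHM and background fraction must be >= 0")


@dataclass(frozen=True)
class SinogramSet:
    """Projection data of shape ``(n_angles, n_bins, nz)``.

    ``attenuation_factors`` are the *physical* factors used to generate the
    data; reconstruction derives its own model factors from the mu-map it is
    given, which is how attenuation-map errors enter the experiment.
    """

    geometry: ProjectionGeometry
    grid_geometry: tuple  # (shape, spacing, origin) of the image grid
    prompts: np.ndarray
    attenuation: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.geometry.n_angles, self.geometry.n_bins)
        for name in ("prompts", "attenuation", "background"):
            arr = getattr(self, name)
            if arr.shape[:2] != shape or arr.ndim != 3:
                raise GeometryError(f"{name} must have shape (angles, bins, nz)")
        if np.any(self.prompts < 0) or np.any(self.background < 0):
            raise ValueError("counts and background must be >= 0")
        if np.any(self.attenuation <= 0) or np.any(self.attenuation > 1 + 1e-12):
            raise ValueError("attenuation factors must lie in (0, 1]")

    @property
    def total_counts(self) -> float:
        return float(self.prompts.sum())


# ---------------------------------------------------------------------------
# system matrix
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _system_matrix_cached(
    n_angles: int,
    n_bins: int,
    bin_spacing: float,
    step_fraction: float,
    nx: int,
    ny: int,
    sx: float,
    sy: float,
) -> sparse.csr_matrix:
    step = step_fraction * min(sx, sy)
    half_diag = 0.5 * np.hypot(nx * sx, ny * sy)
    n_samples = int(np.ceil(2 * half_diag / step)) + 1
    t = -half_diag + np.arange(n_samples) * step
    r = (np.arange(n_bins) - (n_bins - 1) / 2) * bin_spacing
    cx, cy = (nx - 1) / 2 * sx, (ny - 1) / 2 * sy

    rows_all, cols_all, vals_all = [], [], []
    for a in range(n_angles):
        theta = a * np.pi / n_angles
        nvec = np.array([np.cos(theta), np.sin(theta)])
        dvec = np.array([-np.sin(theta), np.cos(theta)])
        # sample points: (n_bins, n_samples)
        px = cx + r[:, None] * nvec[0] + t[None, :] * dvec[0]
        py = cy + r[:, None] * nvec[1] + t[None, :] * dvec[1]
        fi, fj = px / sx, py / sy
        i0 = np.floor(fi).astype(np.int64)
        j0 = np.floor(fj).astype(np.int64)
        wi, wj = fi - i0, fj - j0
        ray = np.broadcast_to(
            (a * n_bins + np.arange(n_bins))[:, None], fi.shape
        )
        for di, dj, w in (
            (0, 0, (1 - wi) * (1 - wj)),
            (1, 0, wi * (1 - wj)),
            (0, 1, (1 - wi) * wj),
            (1, 1, wi * wj),
        ):
            ii, jj = i0 + di, j0 + dj
            ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (w > 0)
            rows_all.append(ray[ok])
            cols_all.append(ii[ok] * ny + jj[ok])
            vals_all.append(w[ok] * step)
    A = sparse.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(n_angles * n_bins, nx * ny),
    ).tocsr()
    A.sum_duplicates()
    return A


def system_matrix(geom: ProjectionGeometry, grid: VoxelGrid3D) -> sparse.csr_matrix:
    """Sparse projector ``(n_angles * n_bins, nx * ny)``; weights in mm."""
    nx, ny, _ = grid.shape
    sx, sy, _ = grid.spacing
    return _system_matrix_cached(
        geom.n_angles, geom.n_bins, geom.bin_spacing_mm, geom.step_fraction,
        nx, ny, sx, sy,
    )


def _project_volume(A: sparse.csr_matrix, values: np.ndarray, geom: ProjectionGeometry):
    nx, ny, nz = values.shape
    flat = values.reshape(nx * ny, nz)
    return (A @ flat).reshape(geom.n_angles, geom.n_bins, nz)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def attenuation_factors(mu: MuMap, geom: ProjectionGeometry) -> np.ndarray:
    """Per-ray survival factors ``exp(-integral mu dl)``, shape (angles, bins, nz).

    mu is in cm^-1 and path lengths in mm, hence the 0.1 conversion.
    """
    if np.any(mu.values < 0):
        raise ValueError("mu must be >= 0")
    A = system_matrix(geom, mu.grid)
    line_int_mm = _project_volume(A, mu.values, geom)
    return np.exp(-0.1 * line_int_mm)


def forward_project(
    activity: VoxelGrid3D,
    mu: MuMap | None,
    geom: ProjectionGeometry,
    background_fraction: float = 0.0,
) -> SinogramSet:
    """Expected (noiseless) prompts: attenuated line integrals plus background.

    The flat background is a scatter/randoms surrogate: per slice, a constant
    expected value per bin carrying ``background_fraction`` of total prompts.
    """
    if mu is not None:
        mu.grid.require_compatible(activity)
        att = attenuation_factors(mu, geom)
    else:
        att = np.ones((geom.n_angles, geom.n_bins, activity.shape[2]))
    A = system_matrix(geom, activity)
    trues = att * _project_volume(A, activity.values, geom)
    background = np.zeros_like(trues)
    if background_fraction > 0:
        if background_fraction >= 1:
            raise ValueError("background fraction must be < 1")
        per_slice = trues.sum(axis=(0, 1))
        f = background_fraction / (1 - background_fraction)
        background += (f * per_slice / (geom.n_angles * geom.n_bins))[None, None, :]
    return SinogramSet(
        geometry=geom,
        grid_geometry=activity.geometry(),
        prompts=trues + background,
        attenuation=att,
        background=background,
    )


def scale_to_counts(sino: SinogramSet, total_counts: float) -> SinogramSet:
    """Rescale expected prompts (and background) to a target total count."""
    tot = sino.total_counts
    if tot <= 0:
        return sino
    k = total_counts / tot
    return replace(sino, prompts=sino.prompts * k, background=sino.background * k)


def sample_counts(expected: SinogramSet, seed: int) -> SinogramSet:
    """Independent Poisson realization per bin; deterministic per seed."""
    if np.any(expected.prompts < 0):
        raise ValueError("expected counts must be >= 0")
    rng = np.random.default_rng(seed)
    return replace(expected, prompts=rng.poisson(expected.prompts).astype(np.float64))


def _subset_order(n: int) -> list[int]:
    """Angle-interleaved subset processing order (maximal angular spread)."""
    order, used = [], set()
    k = max(int(np.round(n * 0.382)), 1)  # golden-ratio stride
    while np.gcd(k, n) != 1:
        k += 1
    i = 0
    for _ in range(n):
        order.append(i)
        i = (i + k) % n
    return order


def poisson_loglik(counts: np.ndarray, expected: np.ndarray) -> float:
    """Poisson log-likelihood up to the data-only constant."""
    m = np.clip(expected, 1e-12, None)
    return float(np.sum(counts * np.log(m) - m))


def reconstruct_osem(
    sino: SinogramSet,
    mu_for_ac: MuMap | None,
    params: ReconParams = ReconParams(),
) -> VoxelGrid3D:
    """OP-OSEM reconstruction with attenuation factors from ``mu_for_ac``.

    ``mu_for_ac=None`` reconstructs without attenuation correction (NAC).
    Voxels with zero sensitivity are excluded from updates and reported zero.
    """
    geom = sino.geometry
    shape, spacing, origin = sino.grid_geometry
    nx, ny, nz = shape
    if geom.n_angles % params.n_subsets != 0:
        raise ValueError(
            f"n_subsets ({params.n_subsets}) must divide n_angles ({geom.n_angles})"
        )
    ref = VoxelGrid3D(np.zeros(shape), spacing, origin)
    A = system_matrix(geom, ref)
    if mu_for_ac is not None:
        # tolerant comparison: NIfTI round-trips store the affine as float32
        g_shape, g_spacing, g_origin = mu_for_ac.grid.geometry()
        if g_shape != tuple(shape) or not (
            np.allclose(g_spacing, spacing, atol=1e-3)
            and np.allclose(g_origin, origin, atol=1e-3)
        ):
            raise GeometryError("mu_for_ac grid does not match the sinogram's grid")
        att = attenuation_factors(mu_for_ac, geom)
    else:
        att = np.ones((geom.n_angles, geom.n_bins, nz))

    y = sino.prompts.reshape(geom.n_angles * geom.n_bins, nz)
    a = att.reshape(geom.n_angles * geom.n_bins, nz)
    b = sino.background.reshape(geom.n_angles * geom.n_bins, nz)

    # subset row selections (angles interleaved: angle % n_subsets)
    angle_subset = np.arange(geom.n_angles) % params.n_subsets
    row_angle = np.repeat(np.arange(geom.n_angles), geom.n_bins)
    subsets = []
    for s in _subset_order(params.n_subsets):
        rows = np.flatnonzero(angle_subset[row_angle] == s)
        subsets.append((A[rows], y[rows], a[rows], b[rows]))

    sens_total = A.T @ a  # used only for the support mask
    support = sens_total > 1e-12 * max(sens_total.max(), 1e-300)
    n_excluded = int((~support).sum())
    if n_excluded:
        log.debug("OSEM: %d zero-sensitivity voxels excluded from updates", n_excluded)

    x = np.where(support, 1.0, 0.0)
    eps = 1e-12
    for _ in range(params.n_iterations):
        for A_s, y_s, a_s, b_s in subsets:
            sens_s = A_s.T @ a_s
            q = a_s * (A_s @ x) + b_s
            ratio = np.divide(y_s, q, out=np.zeros_like(y_s), where=q > eps)
            corr = A_s.T @ (a_s * ratio)
            upd = np.divide(corr, sens_s, out=np.zeros_like(corr), where=sens_s > eps)
            x = x * upd
    vol = x.reshape(nx, ny, nz)
    if params.postfilter_fwhm_mm > 0:
        sig = [params.postfilter_fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
        vol = ndimage.gaussian_filter(vol, sig)
    return VoxelGrid3D(np.clip(vol, 0.0, None), spacing, origin)
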