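"""Quantification of attenuation-correction bias between paired PET images.

The central quantities compare PET reconstructed with the uncorrected
(Dixon-style) attenuation map against PET reconstructed with the inpainted
map, per region of interest, on mean and maximum SUV:

    eps_rel = (SUV_dixon - SUV_inpainted) / SUV_inpainted * 100   [%]
    eps_abs =  SUV_dixon - SUV_inpainted                          [SUV]

eps_rel = -100% marks a total loss of PET activity.  Both metrics are linked
by ``eps_rel = 100 * eps_abs / SUV_inpainted`` wherever the inpainted value
is positive; eps_rel is invariant under global rescaling of both images and
eps_abs is equivariant.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import EmptyROIError, ROISet, SUVMap, VoxelGrid3D, roi_stats

__all__ = [
    "ROIBias",
    "BiasReport",
    "CohortSummary",
    "epsilon_rel",
    "epsilon_abs",
    "roi_report",
    "difference_images",
    "wilcoxon_matched",
    "cohort_summary",
    "distance_shell_bias",
]

log = logging.getLogger(__name__)


def epsilon_rel(suv_dixon: float, suv_inpainted: float) -> float:
    """Relative SUV difference in percent; -100 means total signal loss."""
    if suv_inpainted == 0:
        if suv_dixon == 0:
            warnings.warn("eps_rel 0/0 reported as 0", stacklevel=2)
            return 0.0
        raise ValueError("eps_rel undefined: SUV_inpainted = 0 with SUV_dixon > 0")
    return (suv_dixon - suv_inpainted) / suv_inpainted * 100.0


def epsilon_abs(suv_dixon: float, suv_inpainted: float) -> float:
    """Absolute SUV difference (same sign as eps_rel for positive reference)."""
    if suv_dixon < 0 or suv_inpainted < 0:
        raise ValueError("SUV inputs must be >= 0")
    return suv_dixon - suv_inpainted


@dataclass(frozen=True)
class ROIBias:
    roi: str
    suv_mean_dixon: float
    suv_mean_inpainted: float
    suv_max_dixon: float
    suv_max_inpainted: float
    eps_rel_mean: float
    eps_rel_max: float
    eps_abs_mean: float
    eps_abs_max: float
    n_voxels: int
    error: str | None = None


@dataclass(frozen=True)
class BiasReport:
    """Per-ROI SUV pairs and bias metrics for one phantom/patient."""

    rois: dict[str, ROIBias]
    artifact_volume_ml: float = 0.0
    artifact_class: str = "none"

    def __getitem__(self, roi: str) -> ROIBias:
        return self.rois[roi]

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(b) for b in self.rois.values()]
        return pd.DataFrame(rows).set_index("roi")


def roi_report(
    pet_dixon: SUVMap,
    pet_inpainted: SUVMap,
    rois: ROISet,
    artifact_volume_ml: float = 0.0,
    artifact_class: str = "none",
) -> BiasReport:
    """Mean/max SUV of both reconstructions per ROI plus eps_rel / eps_abs.

    An empty or incompatible ROI yields an error entry; the report is still
    produced for the remaining regions.
    """
    out: dict[str, ROIBias] = {}
    for name, mask in rois.items():
        try:
            mean_d, max_d, n = roi_stats(pet_dixon, mask)
            mean_i, max_i, _ = roi_stats(pet_inpainted, mask)
            out[name] = ROIBias(
                roi=name,
                suv_mean_dixon=mean_d,
                suv_mean_inpainted=mean_i,
                suv_max_dixon=max_d,
                suv_max_inpainted=max_i,
                eps_rel_mean=epsilon_rel(mean_d, mean_i),
                eps_rel_max=epsilon_rel(max_d, max_i),
                eps_abs_mean=epsilon_abs(mean_d, mean_i),
                eps_abs_max=epsilon_abs(max_d, max_i),
                n_voxels=n,
            )
        except (EmptyROIError, ValueError) as err:
            log.warning("ROI %s skipped: %s", name, err)
            out[name] = ROIBias(name, *(np.nan,) * 8, n_voxels=0, error=str(err))
    return BiasReport(out, artifact_volume_ml, artifact_class)


def difference_images(
    pet_dixon: SUVMap,
    pet_inpainted: SUVMap,
) -> tuple[VoxelGrid3D, VoxelGrid3D]:
    """Voxelwise relative (%) and absolute (SUV) difference images, NaN-free.

    Voxels where both images are zero get a relative difference of 0 (so the
    images are displayable); such voxels should be masked from summaries.
    """
    pet_dixon.grid.require_compatible(pet_inpainted.grid)
    d, i = pet_dixon.values, pet_inpainted.values
    abs_img = d - i
    rel_img = np.where(i > 0, np.divide(abs_img, np.where(i > 0, i, 1.0)) * 100.0, 0.0)
    return (
        pet_dixon.grid.with_values(rel_img),
        pet_dixon.grid.with_values(abs_img),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank for matched pairs
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(diffs))


def wilcoxon_matched(pairs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on matched SUV pairs.

    Zero differences are discarded.  For n <= 12 the null is the exact
    enumeration of all 2^n sign assignments of the tied ranks; for larger n
    the normal approximation with tie and continuity correction is used.
    Returns ``(W_plus, p_value)``.
    """
    diffs = np.asarray([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all differences zero: degenerate Wilcoxon test", stacklevel=2)
        return 0.0, 1.0
    ranks = _signed_ranks(diffs)
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 12:
        total = ranks.sum()
        w_all = np.array(
            [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product((False, True), repeat=n)
            ]
        )
        n_assign = w_all.size
        p_le = np.count_nonzero(w_all <= w_plus + 1e-12) / n_assign
        p_ge = np.count_nonzero(w_all >= w_plus - 1e-12) / n_assign
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, p
    res = stats.wilcoxon(diffs, correction=True, method="approx", alternative="two-sided")
    return w_plus, float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Per-ROI, per-class mean (± sample std) and range of eps_rel values.

    Also carries the artifact-volume vs |eps_rel_mean(inpainted_area)|
    scatter per class and its Spearman rank correlation.
    """

    table: pd.DataFrame
    volume_bias: dict[str, pd.DataFrame] = field(default_factory=dict)
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)


def cohort_summary(reports: list[BiasReport]) -> CohortSummary:
    """Table-2-style summary over phantoms, split by artifact class."""
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        for name, b in rep.rois.items():
            if b.error:
                continue
            rows.append(
                {
                    "class": rep.artifact_class,
                    "roi": name,
                    "eps_rel_mean": b.eps_rel_mean,
                    "eps_rel_max": b.eps_rel_max,
                    "volume_ml": rep.artifact_volume_ml,
                }
            )
    df = pd.DataFrame(rows)

    def agg(series):
        return pd.Series(
            {
                "mean": series.mean(),
                "std": series.std(ddof=1) if len(series) > 1 else 0.0,
                "min": series.min(),
                "max": series.max(),
                "n": len(series),
            }
        )

    parts = []
    for col in ("eps_rel_mean", "eps_rel_max"):
        g = df.groupby(["class", "roi"])[col].apply(agg).unstack()
        g.columns = [f"{col}_{c}" for c in g.columns]
        parts.append(g)
    table = pd.concat(parts, axis=1)

    volume_bias: dict[str, pd.DataFrame] = {}
    spearman: dict[str, tuple[float, float]] = {}
    inp = df[df.roi == "inpainted_area"]
    for cls, sub in inp.groupby("class"):
        vb = sub[["volume_ml", "eps_rel_mean"]].reset_index(drop=True)
        vb["abs_eps_rel_mean"] = vb.eps_rel_mean.abs()
        volume_bias[cls] = vb
        if len(vb) > 2:
            rho, p = stats.spearmanr(vb.volume_ml, vb.abs_eps_rel_mean)
            spearman[cls] = (float(rho), float(p))
    return CohortSummary(table=table, volume_bias=volume_bias, spearman=spearman)


def distance_shell_bias(
    pet_dixon: SUVMap,
    pet_inpainted: SUVMap,
    void_mask: VoxelGrid3D,
    edges_mm=(0.0, 10.0, 20.0, 30.0, 50.0, 80.0),
    body_mask: VoxelGrid3D | None = None,
) -> pd.DataFrame:
    """eps_rel of mean SUV in Euclidean-distance shells around the void.

    Operationalizes the distance dependence of the bias; shell edges are in
    mm from the void surface (shell 0 is the void itself).
    """
    pet_dixon.grid.require_compatible(void_mask)
    dist = ndimage.distance_transform_edt(
        ~void_mask.values.astype(bool), sampling=void_mask.spacing
    )
    sel_base = np.ones(void_mask.shape, dtype=bool)
    if body_mask is not None:
        sel_base = body_mask.values.astype(bool)
    rows = []
    edges = list(edges_mm)
    for lo, hi in zip(edges[:-1], edges[1:]):
        shell = (dist >= lo) & (dist < hi) & sel_base if lo > 0 else (
            ((void_mask.values > 0) | ((dist > 0) & (dist < hi))) & sel_base
        )
        if not shell.any():
            continue
        mean_d = float(pet_dixon.values[shell].mean())
        mean_i = float(pet_inpainted.values[shell].mean())
        rows.append(
            {
                "shell_lo_mm": lo,
                "shell_hi_mm": hi,
                "n_voxels": int(shell.sum()),
                "eps_rel_mean": epsilon_rel(mean_d, mean_i) if mean_i > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
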