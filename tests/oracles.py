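"""Independent brute-force oracles used by the test suite.

These are deliberately naive (BFS flood fill, explicit loops, exhaustive
sign enumeration) and share no code with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    if connectivity == 6:
        offs = [o for o in offs if sum(abs(v) for v in o) == 1]
    elif connectivity == 18:
        offs = [o for o in offs if sum(abs(v) for v in o) <= 2]
    return offs


def bfs_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Connected-component labels by explicit flood fill."""
    offs = neighbor_offsets(connectivity)
    shape = mask.shape
    labels = np.zeros(shape, dtype=int)
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        labels[seed] = current
        stack = [seed]
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offs:
                q = (x + dx, y + dy, z + dz)
                if (
                    0 <= q[0] < shape[0]
                    and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2]
                    and mask[q]
                    and not labels[q]
                ):
                    labels[q] = current
                    stack.append(q)
    return labels


def same_partition(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """True iff two labelings define the same partition up to renaming."""
    if (lab_a > 0).sum() != (lab_b > 0).sum() or not np.array_equal(lab_a > 0, lab_b > 0):
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for a, b in zip(lab_a[lab_a > 0].ravel(), lab_b[lab_a > 0].ravel()):
        if mapping.setdefault(int(a), int(b)) != int(b):
            return False
        if reverse.setdefault(int(b), int(a)) != int(a):
            return False
    return True


def reaches_border_air(air: np.ndarray, start_mask: np.ndarray) -> bool:
    """Flood fill (6-connectivity) from ``start_mask`` through air: does it reach the border?"""
    lab = bfs_label(air | start_mask, connectivity=6)
    ids = set(lab[start_mask].ravel()) - {0}
    border = np.zeros_like(air, dtype=bool)
    border[0] = border[-1] = True
    border[:, 0] = border[:, -1] = True
    border[:, :, 0] = border[:, :, -1] = True
    return bool(set(lab[border & air].ravel()) & ids)


def wilcoxon_exact_enum(diffs: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided signed-rank p-value over all sign assignments."""
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    bits = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_all = bits @ ranks
    p_le = np.count_nonzero(w_all <= w_obs + 1e-12) / w_all.size
    p_ge = np.count_nonzero(w_all >= w_obs - 1e-12) / w_all.size
    return float(w_obs), min(1.0, 2.0 * min(p_le, p_ge))
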