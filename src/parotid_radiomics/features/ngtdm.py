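"""Neighboring gray-tone difference matrix (NGTDM) features.

For each gray level i, ``s_i`` sums |i - mean level of the in-ROI
26-neighbors| over ROI voxels of level i that have at least one in-ROI
neighbor. Five scalar features summarize the (p_i, s_i) table. Zero
denominators are guarded by an epsilon of 1e-6 (Busyness and Strength of
a constant ROI are 0; Coarseness saturates at 1e6, the conventional cap).
"""

from __future__ import annotations

import numpy as np

from ._common import EPS, NEIGHBORS_26, roi_levels, shift

FEATURE_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_COARSENESS_CAP = 1e6


def tone_difference_table(level_grid: np.ndarray, levels: np.ndarray):
    """Per-level counts ``n_i`` and tone-difference sums ``s_i``."""
    inmask = level_grid > 0
    nb_sum = np.zeros(level_grid.shape, dtype=np.float64)
    nb_cnt = np.zeros(level_grid.shape, dtype=np.int64)
    for offset in NEIGHBORS_26:
        nb = shift(level_grid, offset)
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0)
        nb_cnt += valid
    counted = inmask & (nb_cnt > 0)
    diff = np.zeros(level_grid.shape)
    diff[counted] = np.abs(
        level_grid[counted] - nb_sum[counted] / nb_cnt[counted]
    )
    idx = np.searchsorted(levels, level_grid[counted])
    n_i = np.bincount(idx, minlength=levels.size).astype(np.float64)
    s_i = np.bincount(idx, weights=diff[counted], minlength=levels.size)
    return n_i, s_i


def ngtdm_features_from_table(
    n_i: np.ndarray, s_i: np.ndarray, levels: np.ndarray
) -> dict[str, float]:
    n_total = n_i.sum()
    p = n_i / n_total
    lv = levels.astype(np.float64)
    present = p > 0
    ngp = int(present.sum())
    pi, si, li = p[present], s_i[present], lv[present]

    coarse_den = float((pi * si).sum())
    coarseness = min(_COARSENESS_CAP, 1.0 / max(coarse_den, EPS))

    if ngp > 1:
        ij2 = (li[:, None] - li[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * ij2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_total)
        )
        busy_den = float(np.abs(li[:, None] * pi[:, None] - li[None, :] * pi[None, :]).sum())
        busyness = coarse_den / busy_den if busy_den > EPS else 0.0
        absdiff = np.abs(li[:, None] - li[None, :])
        psps = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        complexity = float((absdiff * psps / (pi[:, None] + pi[None, :])).sum() / n_total)
        s_total = float(s_i.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * ij2).sum()) / s_total
            if s_total > EPS
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def ngtdm_features(level_grid: np.ndarray) -> dict[str, float]:
    """NGTDM features of a level grid (0 = outside ROI)."""
    levels = roi_levels(level_grid)
    n_i, s_i = tone_difference_table(level_grid, levels)
    if n_i.sum() == 0:
        # isolated voxels only: no neighborhood to compare against
        return {name: 0.0 for name in FEATURE_NAMES} | {"Coarseness": _COARSENESS_CAP}
    return ngtdm_features_from_table(n_i, s_i, levels)
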