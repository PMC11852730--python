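"""Gray-level dependence matrix (GLDM) features.

The dependence of a voxel is 1 plus the number of its 26-neighbors inside
the ROI whose gray level differs by at most alpha (default 0, i.e. equal
levels). P(i, d) counts voxels of level i with dependence d.
"""

from __future__ import annotations

import numpy as np

from ._common import NEIGHBORS_26, roi_levels, shift

FEATURE_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def dependence_matrix(level_grid: np.ndarray, levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P(i, d), columns d = 1..27."""
    inmask = level_grid > 0
    dep = np.zeros(level_grid.shape, dtype=np.int64)
    for offset in NEIGHBORS_26:
        nb = shift(level_grid, offset)
        dep += inmask & (nb > 0) & (np.abs(nb - level_grid) <= alpha)
    dep += 1
    mat = np.zeros((levels.size, 27))
    np.add.at(mat, (np.searchsorted(levels, level_grid[inmask]), dep[inmask] - 1), 1.0)
    return mat[:, : int(dep[inmask].max())]


def gldm_features_from_matrix(mat: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    lv = levels.astype(np.float64)
    d = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    nz_total = mat.sum()
    p = mat / nz_total
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float((pg * lv).sum())
    mu_d = float((pd * d).sum())
    nz = p > 0
    return {
        "SmallDependenceEmphasis": float((p / d[None, :] ** 2).sum()),
        "LargeDependenceEmphasis": float((p * d[None, :] ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz_total),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((pd**2).sum()),
        "GrayLevelVariance": float((pg * (lv - mu_i) ** 2).sum()),
        "DependenceVariance": float((pd * (d - mu_d) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((p / lv[:, None] ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * lv[:, None] ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (p / (lv[:, None] ** 2 * d[None, :] ** 2)).sum()
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (p * lv[:, None] ** 2 / d[None, :] ** 2).sum()
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (p * d[None, :] ** 2 / lv[:, None] ** 2).sum()
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (p * lv[:, None] ** 2 * d[None, :] ** 2).sum()
        ),
    }


def gldm_features(level_grid: np.ndarray, alpha: int = 0) -> dict[str, float]:
    """GLDM features of a level grid (0 = outside ROI)."""
    levels = roi_levels(level_grid)
    mat = dependence_matrix(level_grid, levels, alpha)
    return gldm_features_from_matrix(mat, levels)
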