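"""Gray-level size-zone matrix (GLSZM) features.

A zone is a 26-connected component of in-ROI voxels sharing one gray
level. P(i, s) counts zones of level i and size s; the matrix is
direction-free, so the 16 features are computed once.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import roi_levels

FEATURE_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def size_zone_matrix(level_grid: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Zone count matrix P(i, s) with columns s = 1..max zone size."""
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for idx, lv in enumerate(levels):
        labeled, n = ndimage.label(level_grid == lv, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zone_levels.extend([idx] * n)
            zone_sizes.extend(sizes.tolist())
    max_size = max(zone_sizes)
    mat = np.zeros((levels.size, max_size))
    np.add.at(mat, (np.asarray(zone_levels), np.asarray(zone_sizes) - 1), 1.0)
    return mat


def glszm_features_from_matrix(
    mat: np.ndarray, levels: np.ndarray, n_voxels: int
) -> dict[str, float]:
    lv = levels.astype(np.float64)
    s = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    nz_total = mat.sum()
    p = mat / nz_total
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((pg * lv).sum())
    mu_s = float((ps * s).sum())
    nz = p > 0
    return {
        "SmallAreaEmphasis": float((p / s[None, :] ** 2).sum()),
        "LargeAreaEmphasis": float((p * s[None, :] ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeZoneNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum()),
        "ZonePercentage": float(nz_total / n_voxels),
        "GrayLevelVariance": float((pg * (lv - mu_i) ** 2).sum()),
        "ZoneVariance": float((ps * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelZoneEmphasis": float((p / lv[:, None] ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * lv[:, None] ** 2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (lv[:, None] ** 2 * s[None, :] ** 2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * lv[:, None] ** 2 / s[None, :] ** 2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s[None, :] ** 2 / lv[:, None] ** 2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * lv[:, None] ** 2 * s[None, :] ** 2).sum()),
    }


def glszm_features(level_grid: np.ndarray) -> dict[str, float]:
    """GLSZM features of a level grid (0 = outside ROI)."""
    levels = roi_levels(level_grid)
    mat = size_zone_matrix(level_grid, levels)
    return glszm_features_from_matrix(mat, levels, int((level_grid > 0).sum()))
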