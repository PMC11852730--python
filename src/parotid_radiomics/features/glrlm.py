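"""Gray-level run-length matrix (GLRLM) features.

A run is a maximal straight segment of in-ROI voxels sharing one gray
level along one of the 13 unique directions. P(i, j) counts runs of level
i and length j; 16 features are computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ._common import DIRECTIONS_13, roi_levels, shift

FEATURE_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def run_length_matrix(
    level_grid: np.ndarray, offset: tuple[int, int, int], levels: np.ndarray
) -> np.ndarray:
    """Run-length count matrix P(i, j) for one direction (columns j = 1..max)."""
    inmask = level_grid > 0
    nxt = shift(level_grid, tuple(-d for d in offset))
    same_next = inmask & (nxt == level_grid) & (nxt > 0)
    # run starts where the predecessor along -offset does not continue the run
    start = inmask & ~shift(same_next, offset, fill=False)
    # run length by fixpoint iteration: L[x] = 1 + same_next[x] * L[x + offset]
    lengths = np.ones(level_grid.shape, dtype=np.int64)
    while True:
        nxt_len = shift(lengths, tuple(-d for d in offset))
        new = 1 + np.where(same_next, nxt_len, 0)
        if np.array_equal(new, lengths):
            break
        lengths = new
    run_levels = level_grid[start]
    run_lengths = lengths[start]
    max_len = int(run_lengths.max())
    mat = np.zeros((levels.size, max_len))
    np.add.at(mat, (np.searchsorted(levels, run_levels), run_lengths - 1), 1.0)
    return mat


def glrlm_features_single(mat: np.ndarray, levels: np.ndarray, n_voxels: int) -> dict[str, float]:
    lv = levels.astype(np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    nr = mat.sum()
    p = mat / nr
    pg = p.sum(axis=1)  # by gray level
    pr = p.sum(axis=0)  # by run length
    mu_i = float((pg * lv).sum())
    mu_j = float((pr * j).sum())
    nz = p > 0
    out = {
        "ShortRunEmphasis": float((p / j[None, :] ** 2).sum()),
        "LongRunEmphasis": float((p * j[None, :] ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum()),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((pg * (lv - mu_i) ** 2).sum()),
        "RunVariance": float((pr * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelRunEmphasis": float((p / lv[:, None] ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((p * lv[:, None] ** 2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (lv[:, None] ** 2 * j[None, :] ** 2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * lv[:, None] ** 2 / j[None, :] ** 2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * j[None, :] ** 2 / lv[:, None] ** 2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * lv[:, None] ** 2 * j[None, :] ** 2).sum()),
    }
    return out


def glrlm_features(level_grid: np.ndarray) -> dict[str, float]:
    """Per-direction-averaged GLRLM features of a level grid (0 = outside ROI)."""
    levels = roi_levels(level_grid)
    n_voxels = int((level_grid > 0).sum())
    acc = {name: 0.0 for name in FEATURE_NAMES}
    for offset in DIRECTIONS_13:
        mat = run_length_matrix(level_grid, offset, levels)
        feats = glrlm_features_single(mat, levels, n_voxels)
        for name in FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: acc[name] / len(DIRECTIONS_13) for name in FEATURE_NAMES}
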