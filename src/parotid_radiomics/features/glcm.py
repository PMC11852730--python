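"""Gray-level co-occurrence matrix (GLCM) features.

For each of the 13 unique distance-1 directions, in-ROI co-occurring level
pairs are counted, the matrix is symmetrized and normalized to a joint
probability p(i, j), 24 scalar features are computed, and features are
averaged over directions (directions with no valid pair are skipped).

Degenerate conventions (single gray level): Correlation and MCC are 1,
Imc1/Imc2 are 0 — the documented fixed values, never NaN.
"""

from __future__ import annotations

import numpy as np

from ._common import DIRECTIONS_13, EPS, entropy2, roi_levels, shift

FEATURE_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def cooccurrence_matrix(
    level_grid: np.ndarray, offset: tuple[int, int, int], levels: np.ndarray
) -> np.ndarray:
    """Symmetrized co-occurrence count matrix for one direction offset."""
    g = levels.size
    inmask = level_grid > 0
    nb = shift(level_grid, tuple(-d for d in offset))
    valid = inmask & (nb > 0)
    if not valid.any():
        return np.zeros((g, g))
    ii = np.searchsorted(levels, level_grid[valid])
    jj = np.searchsorted(levels, nb[valid])
    counts = np.zeros((g, g))
    np.add.at(counts, (ii, jj), 1.0)
    return counts + counts.T


def glcm_features_single(p: np.ndarray, levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 24 features of one normalized symmetric GLCM.

    ``n_levels`` is the number of distinct ROI gray levels (used by the
    normalized inverse-difference features Idmn/Idn).
    """
    lv = levels.astype(np.float64)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    mu = float((px * lv).sum())  # symmetric: mu_x == mu_y
    sigma2 = float((px * (lv - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(i - j)
    # distributions of |i-j| and i+j
    kd = np.arange(0, int(lv.max() - lv.min()) + 1)
    p_diff = np.zeros(kd.size)
    np.add.at(p_diff, np.abs(levels[:, None] - levels[None, :]).ravel(), p.ravel())
    ks = np.arange(int(2 * lv.min()), int(2 * lv.max()) + 1)
    p_sum = np.zeros(ks.size)
    np.add.at(p_sum, (levels[:, None] + levels[None, :] - ks[0]).ravel(), p.ravel())

    da = float((p_diff * kd).sum())
    hxy = entropy2(p)
    pxpy = px[:, None] * px[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx = entropy2(px)

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * i * j).sum())
    out["ClusterProminence"] = float((p * (i + j - 2 * mu) ** 4).sum())
    out["ClusterShade"] = float((p * (i + j - 2 * mu) ** 3).sum())
    out["ClusterTendency"] = float((p * (i + j - 2 * mu) ** 2).sum())
    out["Contrast"] = float((p * (i - j) ** 2).sum())
    if sigma2 > 0:
        out["Correlation"] = float(((p * i * j).sum() - mu * mu) / sigma2)
    else:
        out["Correlation"] = 1.0
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = entropy2(p_diff)
    out["DifferenceVariance"] = float((p_diff * (kd - da) ** 2).sum())
    out["Id"] = float((p / (1.0 + diff)).sum())
    out["Idm"] = float((p / (1.0 + diff**2)).sum())
    out["Idmn"] = float((p / (1.0 + (diff / n_levels) ** 2)).sum())
    out["Idn"] = float((p / (1.0 + diff / n_levels)).sum())
    out["Imc1"] = (hxy - hxy1) / max(hx, EPS) if hx > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = diff > 0
    out["InverseVariance"] = float((p[offdiag] / diff[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    out["JointAverage"] = mu
    out["JointEnergy"] = float((p**2).sum())
    out["JointEntropy"] = hxy
    out["MCC"] = _mcc(p, px)
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((p_sum * ks).sum())
    out["SumEntropy"] = entropy2(p_sum)
    out["SumSquares"] = float((p * (i - mu) ** 2).sum())
    return out


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    q = p[np.ix_(keep, keep)]
    marg = px[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); symmetric marginals
    qmat = (q / marg[:, None]) @ (q / marg[None, :]).T
    eig = np.sort(np.real(np.linalg.eigvals(qmat)))[::-1]
    second = max(0.0, float(eig[1]) if eig.size > 1 else 0.0)
    return float(np.sqrt(second))


def glcm_features(level_grid: np.ndarray) -> dict[str, float]:
    """Per-direction-averaged GLCM features of a level grid (0 = outside ROI)."""
    levels = roi_levels(level_grid)
    n_levels = levels.size
    acc: dict[str, float] = {name: 0.0 for name in FEATURE_NAMES}
    n_dirs = 0
    for offset in DIRECTIONS_13:
        counts = cooccurrence_matrix(level_grid, offset, levels)
        total = counts.sum()
        if total == 0:
            continue
        feats = glcm_features_single(counts / total, levels, n_levels)
        for name in FEATURE_NAMES:
            acc[name] += feats[name]
        n_dirs += 1
    if n_dirs == 0:
        raise ValueError("GLCM undefined: no co-occurring voxel pair in any direction")
    return {name: acc[name] / n_dirs for name in FEATURE_NAMES}
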