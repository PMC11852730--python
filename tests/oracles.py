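"""Independent brute-force oracles for the texture-matrix feature families.

Everything here is deliberately naive: explicit Python loops over voxels,
pairs, runs, zones and neighbors, with feature formulas written out
scalar-by-scalar. These implementations share no code with the package
(which is vectorized) and serve as ground truth for oracle-equivalence
tests on small random level grids.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)
]
NB_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


def _entropy(values):
    return -sum(p * math.log2(p) for p in values if p > 0)


# ---------------------------------------------------------------- GLCM


def glcm_matrix_oracle(grid, direction, levels):
    """Symmetrized co-occurrence counts by exhaustive pair enumeration."""
    g = len(levels)
    index = {lv: i for i, lv in enumerate(levels)}
    mat = np.zeros((g, g))
    dx, dy, dz = direction
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                if grid[x, y, z] == 0:
                    continue
                for sx, sy, sz in ((dx, dy, dz), (-dx, -dy, -dz)):
                    nx, ny, nz = x + sx, y + sy, z + sz
                    if _inside(grid.shape, nx, ny, nz) and grid[nx, ny, nz] > 0:
                        mat[index[grid[x, y, z]], index[grid[nx, ny, nz]]] += 1
    return mat


def glcm_features_oracle(grid):
    levels = sorted(int(v) for v in np.unique(grid) if v > 0)
    n_levels = len(levels)
    per_dir = []
    for d in DIRS_13:
        mat = glcm_matrix_oracle(grid, d, levels)
        if mat.sum() == 0:
            continue
        p = mat / mat.sum()
        per_dir.append(_glcm_from_p(p, levels, n_levels))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def _glcm_from_p(p, levels, n_levels):
    g = len(levels)
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    mu = sum(px[i] * levels[i] for i in range(g))
    sigma2 = sum(px[i] * (levels[i] - mu) ** 2 for i in range(g))
    pdiff = defaultdict(float)
    psum = defaultdict(float)
    for i in range(g):
        for j in range(g):
            pdiff[abs(levels[i] - levels[j])] += p[i][j]
            psum[levels[i] + levels[j]] += p[i][j]
    da = sum(k * v for k, v in pdiff.items())
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j] + 1e-6)
        for i in range(g)
        for j in range(g)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(g)
        for j in range(g)
        if px[i] * px[j] > 0
    )
    out = {}
    out["Autocorrelation"] = sum(
        p[i][j] * levels[i] * levels[j] for i in range(g) for j in range(g)
    )
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        out[name] = sum(
            p[i][j] * (levels[i] + levels[j] - 2 * mu) ** power
            for i in range(g)
            for j in range(g)
        )
    out["Contrast"] = sum(
        p[i][j] * (levels[i] - levels[j]) ** 2 for i in range(g) for j in range(g)
    )
    out["Correlation"] = (
        (out["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    )
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = _entropy(pdiff.values())
    out["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    out["Id"] = sum(
        p[i][j] / (1 + abs(levels[i] - levels[j])) for i in range(g) for j in range(g)
    )
    out["Idm"] = sum(
        p[i][j] / (1 + (levels[i] - levels[j]) ** 2) for i in range(g) for j in range(g)
    )
    out["Idmn"] = sum(
        p[i][j] / (1 + ((levels[i] - levels[j]) / n_levels) ** 2)
        for i in range(g)
        for j in range(g)
    )
    out["Idn"] = sum(
        p[i][j] / (1 + abs(levels[i] - levels[j]) / n_levels)
        for i in range(g)
        for j in range(g)
    )
    out["Imc1"] = (hxy - hxy1) / max(hx, 1e-6) if hx > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["InverseVariance"] = sum(
        p[i][j] / (levels[i] - levels[j]) ** 2
        for i in range(g)
        for j in range(g)
        if i != j and levels[i] != levels[j]
    )
    out["JointAverage"] = mu
    out["JointEnergy"] = sum(p[i][j] ** 2 for i in range(g) for j in range(g))
    out["JointEntropy"] = hxy
    out["MCC"] = _mcc_oracle(p, px, levels)
    out["MaximumProbability"] = p.max()
    out["SumAverage"] = sum(k * v for k, v in psum.items())
    out["SumEntropy"] = _entropy(psum.values())
    out["SumSquares"] = sum(
        p[i][j] * (levels[i] - mu) ** 2 for i in range(g) for j in range(g)
    )
    return out


def _mcc_oracle(p, px, levels):
    g = len(levels)
    keep = [i for i in range(g) if px[i] > 0]
    if len(keep) < 2:
        return 1.0
    q = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            q[a, b] = sum(
                p[i][k] * p[j][k] / (px[i] * px[k]) for k in keep
            )
    eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
    return math.sqrt(max(0.0, eig[1]))


# ---------------------------------------------------------------- GLRLM


def glrlm_runs_oracle(grid, direction):
    """All maximal runs (level, length) along one direction, by line walking."""
    runs = []
    d = np.array(direction)
    shape = grid.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if grid[x, y, z] == 0:
                    continue
                # start of a run: predecessor is outside or different
                px, py, pz = x - d[0], y - d[1], z - d[2]
                if _inside(shape, px, py, pz) and grid[px, py, pz] == grid[x, y, z]:
                    continue
                length = 1
                cx, cy, cz = x + d[0], y + d[1], z + d[2]
                while _inside(shape, cx, cy, cz) and grid[cx, cy, cz] == grid[x, y, z]:
                    length += 1
                    cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                runs.append((int(grid[x, y, z]), length))
    return runs


def glrlm_features_oracle(grid):
    n_vox = int((grid > 0).sum())
    per_dir = []
    for d in DIRS_13:
        runs = glrlm_runs_oracle(grid, d)
        per_dir.append(_rlm_from_runs(runs, n_vox))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def _rlm_from_runs(runs, n_vox):
    nr = len(runs)
    by_level = defaultdict(int)
    by_len = defaultdict(int)
    by_cell = defaultdict(int)
    for lv, ln in runs:
        by_level[lv] += 1
        by_len[ln] += 1
        by_cell[(lv, ln)] += 1
    p = {k: v / nr for k, v in by_cell.items()}
    mu_i = sum(lv * v / nr for lv, v in by_level.items())
    mu_j = sum(ln * v / nr for ln, v in by_len.items())
    return {
        "ShortRunEmphasis": sum(v / ln**2 for (lv, ln), v in p.items()),
        "LongRunEmphasis": sum(v * ln**2 for (lv, ln), v in p.items()),
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum((v / nr) ** 2 for v in by_level.values()),
        "RunLengthNonUniformity": sum(v**2 for v in by_len.values()) / nr,
        "RunLengthNonUniformityNormalized": sum((v / nr) ** 2 for v in by_len.values()),
        "RunPercentage": nr / n_vox,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * v / nr for lv, v in by_level.items()),
        "RunVariance": sum((ln - mu_j) ** 2 * v / nr for ln, v in by_len.items()),
        "RunEntropy": _entropy(p.values()),
        "LowGrayLevelRunEmphasis": sum(v / lv**2 for (lv, ln), v in p.items()),
        "HighGrayLevelRunEmphasis": sum(v * lv**2 for (lv, ln), v in p.items()),
        "ShortRunLowGrayLevelEmphasis": sum(v / (lv**2 * ln**2) for (lv, ln), v in p.items()),
        "ShortRunHighGrayLevelEmphasis": sum(v * lv**2 / ln**2 for (lv, ln), v in p.items()),
        "LongRunLowGrayLevelEmphasis": sum(v * ln**2 / lv**2 for (lv, ln), v in p.items()),
        "LongRunHighGrayLevelEmphasis": sum(v * lv**2 * ln**2 for (lv, ln), v in p.items()),
    }


# ---------------------------------------------------------------- GLSZM


def glszm_zones_oracle(grid):
    """All zones (level, size) by breadth-first flood fill, 26-connected."""
    visited = np.zeros(grid.shape, dtype=bool)
    zones = []
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                if grid[x, y, z] == 0 or visited[x, y, z]:
                    continue
                level = grid[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NB_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            _inside(grid.shape, nx, ny, nz)
                            and not visited[nx, ny, nz]
                            and grid[nx, ny, nz] == level
                        ):
                            visited[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones.append((int(level), size))
    return zones


def glszm_features_oracle(grid):
    zones = glszm_zones_oracle(grid)
    n_vox = int((grid > 0).sum())
    nz = len(zones)
    by_level = defaultdict(int)
    by_size = defaultdict(int)
    by_cell = defaultdict(int)
    for lv, s in zones:
        by_level[lv] += 1
        by_size[s] += 1
        by_cell[(lv, s)] += 1
    p = {k: v / nz for k, v in by_cell.items()}
    mu_i = sum(lv * v / nz for lv, v in by_level.items())
    mu_s = sum(s * v / nz for s, v in by_size.items())
    return {
        "SmallAreaEmphasis": sum(v / s**2 for (lv, s), v in p.items()),
        "LargeAreaEmphasis": sum(v * s**2 for (lv, s), v in p.items()),
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum((v / nz) ** 2 for v in by_level.values()),
        "SizeZoneNonUniformity": sum(v**2 for v in by_size.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum((v / nz) ** 2 for v in by_size.values()),
        "ZonePercentage": nz / n_vox,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * v / nz for lv, v in by_level.items()),
        "ZoneVariance": sum((s - mu_s) ** 2 * v / nz for s, v in by_size.items()),
        "ZoneEntropy": _entropy(p.values()),
        "LowGrayLevelZoneEmphasis": sum(v / lv**2 for (lv, s), v in p.items()),
        "HighGrayLevelZoneEmphasis": sum(v * lv**2 for (lv, s), v in p.items()),
        "SmallAreaLowGrayLevelEmphasis": sum(v / (lv**2 * s**2) for (lv, s), v in p.items()),
        "SmallAreaHighGrayLevelEmphasis": sum(v * lv**2 / s**2 for (lv, s), v in p.items()),
        "LargeAreaLowGrayLevelEmphasis": sum(v * s**2 / lv**2 for (lv, s), v in p.items()),
        "LargeAreaHighGrayLevelEmphasis": sum(v * lv**2 * s**2 for (lv, s), v in p.items()),
    }


# ---------------------------------------------------------------- GLDM


def gldm_dependence_oracle(grid, alpha=0):
    """(level, dependence) per ROI voxel by explicit neighbor counting."""
    out = []
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                if grid[x, y, z] == 0:
                    continue
                dep = 1
                for dx, dy, dz in NB_26:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if (
                        _inside(grid.shape, nx, ny, nz)
                        and grid[nx, ny, nz] > 0
                        and abs(int(grid[nx, ny, nz]) - int(grid[x, y, z])) <= alpha
                    ):
                        dep += 1
                out.append((int(grid[x, y, z]), dep))
    return out


def gldm_features_oracle(grid, alpha=0):
    cells = gldm_dependence_oracle(grid, alpha)
    n = len(cells)
    by_level = defaultdict(int)
    by_dep = defaultdict(int)
    by_cell = defaultdict(int)
    for lv, d in cells:
        by_level[lv] += 1
        by_dep[d] += 1
        by_cell[(lv, d)] += 1
    p = {k: v / n for k, v in by_cell.items()}
    mu_i = sum(lv * v / n for lv, v in by_level.items())
    mu_d = sum(d * v / n for d, v in by_dep.items())
    return {
        "SmallDependenceEmphasis": sum(v / d**2 for (lv, d), v in p.items()),
        "LargeDependenceEmphasis": sum(v * d**2 for (lv, d), v in p.items()),
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / n,
        "DependenceNonUniformity": sum(v**2 for v in by_dep.values()) / n,
        "DependenceNonUniformityNormalized": sum((v / n) ** 2 for v in by_dep.values()),
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * v / n for lv, v in by_level.items()),
        "DependenceVariance": sum((d - mu_d) ** 2 * v / n for d, v in by_dep.items()),
        "DependenceEntropy": _entropy(p.values()),
        "LowGrayLevelEmphasis": sum(v / lv**2 for (lv, d), v in p.items()),
        "HighGrayLevelEmphasis": sum(v * lv**2 for (lv, d), v in p.items()),
        "SmallDependenceLowGrayLevelEmphasis": sum(
            v / (lv**2 * d**2) for (lv, d), v in p.items()
        ),
        "SmallDependenceHighGrayLevelEmphasis": sum(
            v * lv**2 / d**2 for (lv, d), v in p.items()
        ),
        "LargeDependenceLowGrayLevelEmphasis": sum(
            v * d**2 / lv**2 for (lv, d), v in p.items()
        ),
        "LargeDependenceHighGrayLevelEmphasis": sum(
            v * lv**2 * d**2 for (lv, d), v in p.items()
        ),
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_table_oracle(grid):
    """Per-level (n_i, s_i) by explicit neighbor-mean computation."""
    n_i = defaultdict(int)
    s_i = defaultdict(float)
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                if grid[x, y, z] == 0:
                    continue
                nb = [
                    int(grid[x + dx, y + dy, z + dz])
                    for dx, dy, dz in NB_26
                    if _inside(grid.shape, x + dx, y + dy, z + dz)
                    and grid[x + dx, y + dy, z + dz] > 0
                ]
                if not nb:
                    continue
                n_i[int(grid[x, y, z])] += 1
                s_i[int(grid[x, y, z])] += abs(int(grid[x, y, z]) - sum(nb) / len(nb))
    return n_i, s_i


def ngtdm_features_oracle(grid):
    n_i, s_i = ngtdm_table_oracle(grid)
    n = sum(n_i.values())
    levels = sorted(n_i)
    p = {lv: n_i[lv] / n for lv in levels}
    ngp = len(levels)
    coarse_den = sum(p[lv] * s_i[lv] for lv in levels)
    coarseness = min(1e6, 1.0 / max(coarse_den, 1e-6))
    if ngp > 1:
        contrast = (
            sum(p[a] * p[b] * (a - b) ** 2 for a in levels for b in levels)
            / (ngp * (ngp - 1))
            * (sum(s_i.values()) / n)
        )
        busy_den = sum(abs(a * p[a] - b * p[b]) for a in levels for b in levels)
        busyness = coarse_den / busy_den if busy_den > 1e-6 else 0.0
        complexity = (
            sum(
                abs(a - b) * (p[a] * s_i[a] + p[b] * s_i[b]) / (p[a] + p[b])
                for a in levels
                for b in levels
            )
            / n
        )
        s_total = sum(s_i.values())
        strength = (
            sum((p[a] + p[b]) * (a - b) ** 2 for a in levels for b in levels) / s_total
            if s_total > 1e-6
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


# ---------------------------------------------------------------- misc


def auc_pair_counting(scores_pos_high, scores_other):
    """AUC by exhaustive pair counting: P(high > other) + 1/2 ties."""
    total = 0.0
    for a in scores_pos_high:
        for b in scores_other:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(scores_pos_high) * len(scores_other))


def separable_convolution_oracle(data, taps_per_axis):
    """Direct separable correlation with mirror boundary, triple loop."""

    def correlate_axis(arr, taps, axis):
        arr = np.moveaxis(arr, axis, 0)
        n = arr.shape[0]
        k = len(taps)
        half = k // 2
        out = np.zeros_like(arr)
        for i in range(n):
            acc = np.zeros_like(arr[0])
            for t in range(k):
                j = i + t - half
                # mirror boundary: ... 2 1 | 0 1 2 ... n-1 | n-2 n-3 ...
                while j < 0 or j >= n:
                    if j < 0:
                        j = -j
                    if j >= n:
                        j = 2 * n - 2 - j
                acc = acc + taps[t] * arr[j]
            out[i] = acc
        return np.moveaxis(out, 0, axis)

    out = data.astype(np.float64)
    for axis, taps in enumerate(taps_per_axis):
        out = correlate_axis(out, taps, axis)
    return out


def icc_anova_oracle(x1, x2):
    """ICC(A,1) for two raters via the explicit two-way ANOVA decomposition."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n, k = len(x1), 2
    data = np.stack([x1, x2], axis=1)
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
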