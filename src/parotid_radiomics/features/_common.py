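"""Shared machinery for the gray-level matrix feature families.

Level grids are int arrays with level 0 outside the ROI and levels >= 1
inside (fixed-bin-width discretization). All texture matrices are built
over the 13 unique direction offsets of the 26-neighborhood (one of each
antipodal pair) at distance 1, or over the full 26-neighborhood where the
family is direction-free (zones, dependence, tone difference).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-6

#: 13 unique distance-1 offsets: one representative of each antipodal pair.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)
)

#: Full 26-neighborhood.
NEIGHBORS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def shift(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """Translate ``arr`` by ``offset`` voxels, filling exposed edges.

    ``shift(a, d)[x] == a[x - d]`` where defined.
    """
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for d, n in zip(offset, arr.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def roi_levels(level_grid: np.ndarray) -> np.ndarray:
    """Sorted distinct gray levels present in the ROI."""
    levels = np.unique(level_grid)
    levels = levels[levels > 0]
    if levels.size == 0:
        raise ValueError("empty ROI: no gray levels present")
    return levels.astype(np.int64)


def entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits, ignoring zero cells."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
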