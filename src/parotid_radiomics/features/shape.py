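"""3D shape features of a binary lesion mask.

Surface area and mesh volume come from a marching-cubes triangulation of
the (zero-padded) binary mask at iso-level 0.5, in world (mm) units. Axis
lengths derive from the principal components of the voxel-centre point
cloud (axis length = 4 sqrt(eigenvalue), the full extent of an equivalent
ellipsoid). Degenerate masks (single voxel, flat slabs) report 0 for the
undefined axis lengths instead of crashing.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

FEATURE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except QhullError:
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def shape_features(mask_voxels: np.ndarray, spacing_mm: tuple[float, float, float]) -> dict[str, float]:
    """The 14 shape features of a binary mask with voxel spacing in mm."""
    m = np.asarray(mask_voxels, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    n = int(m.sum())
    voxel_volume = float(n * spacing.prod())

    padded = np.pad(m, 1).astype(np.float64)
    try:
        verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        surface_area = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    except (ValueError, RuntimeError):  # mask too thin to triangulate
        surface_area = 0.0
        mesh_volume = 0.0

    if mesh_volume > 0 and surface_area > 0:
        sphericity = float(np.pi ** (1 / 3) * (6 * mesh_volume) ** (2 / 3) / surface_area)
        sv_ratio = surface_area / mesh_volume
    else:
        sphericity = 0.0
        sv_ratio = 0.0

    surf = _surface_voxels(m).astype(np.float64) * spacing
    max3d = _max_pairwise_distance(surf)

    def max2d(drop_axis: int) -> float:
        best = 0.0
        keep = [a for a in range(3) if a != drop_axis]
        coords = _surface_voxels(m)
        for plane in np.unique(coords[:, drop_axis]):
            pts = coords[coords[:, drop_axis] == plane][:, keep] * spacing[keep]
            best = max(best, _max_pairwise_distance(pts))
        return best

    # Slice: in-plane (x, y); Column: (x, z); Row: (y, z)
    max2d_slice = max2d(2)
    max2d_column = max2d(1)
    max2d_row = max2d(0)

    pts = np.argwhere(m).astype(np.float64) * spacing
    if len(pts) > 1:
        cov = np.cov(pts, rowvar=False, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(eig)).tolist()
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    else:
        major = minor = least = elongation = flatness = 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": sv_ratio,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
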