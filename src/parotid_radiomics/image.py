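"""Core spatial containers: scalar volumes and binary segmentation masks.

A :class:`VolumeImage` is a 3D scalar grid (an MRI sequence such as a
T2-weighted image or an ADC map, or a filtered derivative of one) with
physical voxel spacing in millimetres. A :class:`SegmentationMask` is a
binary grid aligned voxel-for-voxel with its image; one mask is shared by
the paired T2-like and ADC-like volumes of a lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeImage", "SegmentationMask"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class VolumeImage:
    """3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    voxels
        3D float array, indexed ``[x, y, z]``. Values must be finite;
        removed/invalid voxels are tracked through the mask, never stored
        as NaN/inf in the image.
    spacing_mm
        Physical voxel size along (x, y, z), all > 0.
    origin
        World-space offset of the first voxel centre, in mm.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """Same geometry, new voxel data."""
        return VolumeImage(voxels, self.spacing_mm, self.origin)


@dataclass
class SegmentationMask:
    """Binary lesion mask aligned with a :class:`VolumeImage`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def check_aligned(self, img: VolumeImage) -> None:
        if self.voxels.shape != img.voxels.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != image shape {img.voxels.shape}"
            )

    def with_voxels(self, voxels: np.ndarray) -> "SegmentationMask":
        return SegmentationMask(voxels, self.spacing_mm, self.origin)
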