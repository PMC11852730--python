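"""NIfTI volume I/O, cohort manifests and report serialization.

Only axis-aligned affines are supported: spacing is read off the affine
diagonal and a sheared or rotated affine is rejected. Round-tripping a
volume preserves voxel data bit-exactly and spacing to 1e-6.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import SegmentationMask, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_cohort",
    "load_cohort_lesions",
    "write_json",
]


def _spacing_from_affine(affine: np.ndarray) -> tuple[tuple[float, float, float], np.ndarray]:
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(lin).max()):
        raise ValueError("only axis-aligned affines (no shear/rotation) are supported")
    spacing = np.abs(np.diag(lin))
    if np.any(spacing <= 0):
        raise ValueError(f"invalid affine spacing {spacing}")
    return tuple(float(s) for s in spacing), affine[:3, 3]


def read_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    spacing, origin = _spacing_from_affine(img.affine)
    return VolumeImage(data.astype(np.float64), spacing, tuple(origin))


def write_volume(img: VolumeImage, path: str | Path) -> None:
    affine = np.diag(list(img.spacing_mm) + [1.0])
    affine[:3, 3] = img.origin
    nib.save(nib.Nifti1Image(img.voxels, affine), str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask(vol.voxels >= 0.5, vol.spacing_mm, vol.origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing_mm) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def write_cohort(lesions, out_dir: str | Path) -> Path:
    """Write volume/mask NIfTI pairs and a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for les in lesions:
        t2_path = out / f"{les.lesion_id}_T2.nii.gz"
        adc_path = out / f"{les.lesion_id}_ADC.nii.gz"
        mask_path = out / f"{les.lesion_id}_mask.nii.gz"
        write_volume(les.t2_volume, t2_path)
        write_volume(les.adc_volume, adc_path)
        write_mask(les.mask, mask_path)
        reseg_path = ""
        if les.mask_reseg is not None:
            reseg_path = str(out / f"{les.lesion_id}_mask_reseg.nii.gz")
            write_mask(les.mask_reseg, reseg_path)
        rows.append(
            {
                "lesion_id": les.lesion_id,
                "patient_id": les.patient_id,
                "label": les.label,
                "t2": str(t2_path),
                "adc": str(adc_path),
                "mask": str(mask_path),
                "mask_reseg": reseg_path,
            }
        )
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort_lesions(manifest_path: str | Path):
    """Rebuild lesion objects from a manifest CSV written by :func:`write_cohort`."""
    from .cohort import SyntheticLesion

    df = pd.read_csv(manifest_path, keep_default_na=False)
    lesions = []
    for _, row in df.iterrows():
        lesions.append(
            SyntheticLesion(
                lesion_id=row["lesion_id"],
                patient_id=row["patient_id"],
                label=row["label"],
                t2_volume=read_volume(row["t2"]),
                adc_volume=read_volume(row["adc"]),
                mask=read_mask(row["mask"]),
                mask_reseg=read_mask(row["mask_reseg"]) if row["mask_reseg"] else None,
            )
        )
    return lesions


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
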