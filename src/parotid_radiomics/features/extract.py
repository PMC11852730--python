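"""Whole-lesion feature extraction: 1037 named features per MRI sequence.

Per sequence the budget decomposes as 14 shape features (original
geometry only) plus 93 intensity/texture features (18 first-order, 24
GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) on each of 11 images: the
original, 8 wavelet sub-bands and 2 LoG responses. Shape is computed once
from the shared mask but reported under both sequences, so a lesion's
paired T2+ADC vector has 2074 entries.

Feature names follow the grammar ``{sequence}|{filter}|{family}|{feature}``,
e.g. ``T2|wavelet-LLH|glrlm|HighGrayLevelRunEmphasis``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..filters import FilterBankConfig, filter_bank
from ..image import SegmentationMask, VolumeImage
from ..preprocess import (
    PreprocessConfig,
    bias_field_correct,
    discretize_roi,
    normalize_intensity,
    remove_outlier_voxels,
    resample_isotropic,
)
from . import firstorder, gldm, glcm, glrlm, glszm, ngtdm, shape

__all__ = [
    "ExtractionConfig",
    "FAMILY_SIZES",
    "FEATURES_PER_SEQUENCE",
    "extract_sequence",
    "extract_all",
    "extract_table",
]

FAMILY_SIZES = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}

#: 14 shape + 11 images x 93 intensity/texture features
FEATURES_PER_SEQUENCE = 14 + 11 * 93


@dataclass
class ExtractionConfig:
    """Extraction settings (defaults reproduce the 1037-feature budget).

    ``images="original"`` skips the filter bank (14 shape + 93 features per
    sequence) — used by simulation studies that repeat extraction many times.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    gldm_alpha: int = 0
    images: str = "all"  # "all" | "original"

    def __post_init__(self) -> None:
        if self.images not in ("all", "original"):
            raise ValueError("images must be 'all' or 'original'")


def _texture_families(level_grid: np.ndarray, alpha: int) -> dict[str, dict[str, float]]:
    return {
        "glcm": glcm.glcm_features(level_grid),
        "glrlm": glrlm.glrlm_features(level_grid),
        "glszm": glszm.glszm_features(level_grid),
        "gldm": gldm.gldm_features(level_grid, alpha),
        "ngtdm": ngtdm.ngtdm_features(level_grid),
    }


def preprocess_sequence(
    img: VolumeImage,
    mask: SegmentationMask,
    cfg: PreprocessConfig,
    apply_bias: bool,
) -> tuple[VolumeImage, SegmentationMask]:
    """Run the fixed preparation chain for one sequence."""
    if apply_bias:
        img = bias_field_correct(img, mask, cfg.bias_degree)
    img = normalize_intensity(img, cfg)
    mask = remove_outlier_voxels(img, mask, cfg)
    return resample_isotropic(img, mask, cfg)


def extract_sequence(
    img: VolumeImage,
    mask: SegmentationMask,
    sequence: str,
    cfg: ExtractionConfig | None = None,
    apply_bias: bool | None = None,
) -> dict[str, float]:
    """All 1037 features of one sequence, keyed by full feature name."""
    cfg = cfg or ExtractionConfig()
    if apply_bias is None:
        apply_bias = cfg.preprocess.bias_on in (sequence, "both") or (
            cfg.preprocess.bias_on == "T2" and sequence == "T2"
        )
    img_r, mask_r = preprocess_sequence(img, mask, cfg.preprocess, apply_bias)

    out: dict[str, float] = {}
    for name, value in shape.shape_features(mask_r.voxels, mask_r.spacing_mm).items():
        out[f"{sequence}|original|shape|{name}"] = value

    if cfg.images == "all":
        images = filter_bank(img_r, cfg.filters)
    else:
        images = {"original": img_r}
    for filt_name, filt_img in images.items():
        levels = discretize_roi(filt_img, mask_r, cfg.preprocess)
        roi_vals = filt_img.voxels[mask_r.voxels]
        fo = firstorder.first_order_features(
            roi_vals, levels[mask_r.voxels], filt_img.voxel_volume_mm3
        )
        for name, value in fo.items():
            out[f"{sequence}|{filt_name}|firstorder|{name}"] = value
        for family, feats in _texture_families(levels, cfg.gldm_alpha).items():
            for name, value in feats.items():
                out[f"{sequence}|{filt_name}|{family}|{name}"] = value

    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature value(s): {bad[:5]}")
    expected = FEATURES_PER_SEQUENCE if cfg.images == "all" else 14 + 93
    if len(out) != expected:
        raise RuntimeError(f"feature budget violated: {len(out)} != {expected}")
    return out


def extract_all(lesion, cfg: ExtractionConfig | None = None) -> dict[str, float]:
    """Paired T2+ADC feature vector (2074 entries) of one lesion.

    ``lesion`` provides ``t2_volume``, ``adc_volume`` and the shared
    ``mask`` (the T2 segmentation transferred onto the ADC map).
    """
    cfg = cfg or ExtractionConfig()
    out: dict[str, float] = {}
    for sequence, img in (("T2", lesion.t2_volume), ("ADC", lesion.adc_volume)):
        out.update(extract_sequence(img, lesion.mask, sequence, cfg))
    return out


def extract_table(
    lesions,
    cfg: ExtractionConfig | None = None,
    use_reseg_mask: bool = False,
) -> pd.DataFrame:
    """Feature table: one row per lesion, ``label`` column plus 2074 features.

    With ``use_reseg_mask`` the perturbed second segmentation replaces the
    primary mask (lesions lacking one are skipped) — the input to the ICC
    stability gate.
    """
    cfg = cfg or ExtractionConfig()
    rows = {}
    labels = {}
    for les in lesions:
        mask = les.mask_reseg if use_reseg_mask else les.mask
        if mask is None:
            continue
        work = _MaskOverride(les, mask)
        try:
            rows[les.lesion_id] = extract_all(work, cfg)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for lesion {les.lesion_id}") from exc
        labels[les.lesion_id] = les.label
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "lesion_id"
    table.insert(0, "label", pd.Series(labels))
    return table


class _MaskOverride:
    """Lesion view with a substituted segmentation mask."""

    def __init__(self, lesion, mask):
        self.t2_volume = lesion.t2_volume
        self.adc_volume = lesion.adc_volume
        self.mask = mask
        self.lesion_id = lesion.lesion_id
        self.label = lesion.label
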