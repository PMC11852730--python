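"""Synthetic parotid-lesion cohort generator.

Emulates the statistical structure the analysis assumes: ~106 lesions
(66 Warthin's tumors, 40 malignant tumors, some patients carrying
multiple same-class lesions), each an ellipsoidal lesion of diameter
> 1 cm embedded in a paired T2-weighted-like volume and ADC-map-like
volume sharing one segmentation mask, plus a perturbed re-segmentation
for a subset of lesions to exercise the ICC stability gate.

Lesion texture is a class-conditional Gaussian random field: white noise
smoothed with a class-specific kernel, then scaled and shifted to
class-specific intensity statistics. The three class contrasts planted by
the default :class:`EffectProfile` target the three feature families the
downstream score is built from:

* gray-level mean shift  -> high-gray-level run emphasis (GLRLM);
* spatial correlation length -> zone size/variance structure (GLSZM);
* intensity variance ratio -> first-order root-mean-squared.

The ADC-like volume is generated on a physically plausible scale
(values in units of 1e-3 mm^2/s, roughly 0.4-2.5) and is anti-correlated
with the T2 "cellularity" field, so both sequences carry the class
signal, as in real parotid imaging where cell-dense tumor tissue is
T2-bright-heterogeneous and diffusion-restricted. With a null effect
profile the two classes are exchangeable. Generation is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import SegmentationMask, VolumeImage

__all__ = [
    "EffectProfile",
    "CohortSpec",
    "SyntheticLesion",
    "generate_cohort",
    "simulate_resegmentation",
]


@dataclass(frozen=True)
class EffectProfile:
    """Class-contrast parameters (WT vs MT) of the generator.

    mean_shift
        MT lesion mean is shifted down by this many WT standard deviations.
    corr_length_ratio
        MT spatial correlation length / WT correlation length.
    variance_ratio
        MT intensity variance / WT intensity variance.

    ``EffectProfile.null()`` (0, 1, 1) makes the classes exchangeable.
    """

    mean_shift: float = 1.0
    corr_length_ratio: float = 1.6
    variance_ratio: float = 1.8

    @classmethod
    def null(cls) -> "EffectProfile":
        return cls(mean_shift=0.0, corr_length_ratio=1.0, variance_ratio=1.0)

    def scaled(self, strength: float) -> "EffectProfile":
        """Interpolate between the null profile (0) and this profile (1)."""
        return EffectProfile(
            mean_shift=self.mean_shift * strength,
            corr_length_ratio=self.corr_length_ratio**strength,
            variance_ratio=self.variance_ratio**strength,
        )


@dataclass
class CohortSpec:
    n_wt: int = 66
    n_mt: int = 40
    roi_shape: tuple[int, int, int] = (32, 32, 16)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 3.0)
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    noise_sd: float = 10.0
    n_reseg: int = 30
    reseg_jitter_mm: float | None = None  # default: one in-plane voxel
    multi_lesion_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt < 2 or self.n_mt < 2:
            raise ValueError("need at least 2 lesions per class")
        if any(int(d) < 4 for d in self.roi_shape):
            raise ValueError(f"degenerate roi_shape {self.roi_shape}: every dim must be >= 4")
        self.roi_shape = tuple(int(d) for d in self.roi_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be > 0")
        if self.n_reseg > self.n_wt + self.n_mt:
            raise ValueError("n_reseg exceeds cohort size")
        if self.reseg_jitter_mm is None:
            self.reseg_jitter_mm = self.spacing_mm[0]


@dataclass
class SyntheticLesion:
    lesion_id: str
    patient_id: str
    label: str  # "WT" | "MT"
    t2_volume: VolumeImage
    adc_volume: VolumeImage
    mask: SegmentationMask
    mask_reseg: SegmentationMask | None = None

    def __post_init__(self) -> None:
        if self.label not in ("WT", "MT"):
            raise ValueError(f"label must be WT or MT, got {self.label}")
        if self.mask.is_empty():
            raise ValueError("lesion mask is empty")
        self.mask.check_aligned(self.t2_volume)
        self.mask.check_aligned(self.adc_volume)


# WT baseline texture parameters (T2-like arbitrary units)
_T2_MEAN = 300.0
_T2_SD = 60.0
_CORR_LEN_MM = 2.0
_BG_MEAN = 150.0
_BG_SD = 30.0
_BG_CORR_LEN_MM = 1.5


def _world_grid(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _random_field(rng, shape, spacing, corr_len_mm):
    """Unit-variance, zero-mean Gaussian random field with given correlation length."""
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm):
    gx, gy, gz = _world_grid(shape, spacing)
    ax, ay, az = semi_axes_mm
    cx, cy, cz = center_mm
    return (
        ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
    ) <= 1.0


def _make_lesion(
    rng: np.random.Generator, spec: CohortSpec, label: str
) -> tuple[VolumeImage, VolumeImage, SegmentationMask]:
    shape, spacing = spec.roi_shape, spec.spacing_mm
    extent = [n * s for n, s in zip(shape, spacing)]

    # lesion geometry: diameter > 1 cm, sized to fit the ROI grid
    max_diam = min(19.0, min(extent[0], extent[1]) - 3.0)
    diam = rng.uniform(12.0, max(12.5, max_diam))
    ax = diam / 2.0
    ay = ax * rng.uniform(0.8, 1.0)
    az = min(ax * rng.uniform(0.7, 1.0), extent[2] / 2.0 - spacing[2])
    center = [e / 2.0 + rng.uniform(-1.0, 1.0) for e in extent]
    mask = _ellipsoid_mask(shape, spacing, center, (ax, ay, az))

    prof = spec.effect_profile
    if label == "MT":
        mean = _T2_MEAN - prof.mean_shift * _T2_SD
        sd = _T2_SD * np.sqrt(prof.variance_ratio)
        corr = _CORR_LEN_MM * prof.corr_length_ratio
    else:
        mean, sd, corr = _T2_MEAN, _T2_SD, _CORR_LEN_MM

    lesion_field = _random_field(rng, shape, spacing, corr)
    background = _BG_MEAN + _BG_SD * _random_field(rng, shape, spacing, _BG_CORR_LEN_MM)
    t2 = np.where(mask, mean + sd * lesion_field, background)
    t2 = t2 + spec.noise_sd * rng.standard_normal(shape)

    # mild multiplicative coil-inhomogeneity field (exercised by bias correction)
    gx, gy, gz = _world_grid(shape, spacing)

    def unit(g):
        return (g - g.mean()) / (g.max() - g.min() + 1e-12)

    b = rng.uniform(-0.08, 0.08, size=3)
    t2 = t2 * np.exp(b[0] * unit(gx) + b[1] * unit(gy) + b[2] * unit(gx) * unit(gy))
    t2 = np.clip(t2, 1.0, None)

    # ADC (1e-3 mm^2/s): anti-correlated with T2 cellularity, physiological range
    z_t2 = (t2 - mean) / sd
    adc_lesion = 1.3 - 0.35 * z_t2
    adc_bg = 1.2 + 0.15 * _random_field(rng, shape, spacing, _BG_CORR_LEN_MM)
    adc = np.where(mask, adc_lesion, adc_bg)
    adc = adc + 0.05 * rng.standard_normal(shape)
    adc = np.clip(adc, 0.4, 2.5)

    return (
        VolumeImage(t2, spacing),
        VolumeImage(adc, spacing),
        SegmentationMask(mask, spacing),
    )


def simulate_resegmentation(
    mask: SegmentationMask, jitter_mm: float, seed: int
) -> SegmentationMask:
    """Emulate an intra-observer re-segmentation by boundary perturbation.

    The mask boundary (zero level of the signed Euclidean distance in mm)
    is shifted locally by a smooth random field bounded by +-``jitter_mm``,
    then the component overlapping the original lesion is kept. With
    ``jitter_mm = 0`` the mask is returned unchanged.
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    if jitter_mm == 0:
        return mask.with_voxels(mask.voxels.copy())
    rng = np.random.default_rng(seed)
    m = mask.voxels
    spacing = mask.spacing_mm
    dist_out = ndimage.distance_transform_edt(~m, sampling=spacing)
    dist_in = ndimage.distance_transform_edt(m, sampling=spacing)
    sdf = dist_out - dist_in  # positive outside, negative inside

    raw = _random_field(rng, m.shape, spacing, corr_len_mm=3.0)
    jitter_field = np.clip(jitter_mm * raw, -jitter_mm, jitter_mm)
    new = sdf <= jitter_field

    # keep the lesion component only (perturbation must not spawn islands)
    labeled, n = ndimage.label(new)
    overlap = np.unique(labeled[m & new])
    overlap = overlap[overlap > 0]
    if overlap.size == 0:
        raise ValueError("resegmentation jitter emptied the mask")
    new = np.isin(labeled, overlap)
    if not new.any():
        raise ValueError("resegmentation jitter emptied the mask")
    return mask.with_voxels(new)


def generate_cohort(spec: CohortSpec) -> list[SyntheticLesion]:
    """Generate the labeled synthetic cohort (WT lesions first, then MT)."""
    root = np.random.SeedSequence(spec.seed)
    lesion_seeds = root.spawn(spec.n_wt + spec.n_mt)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    labels = ["WT"] * spec.n_wt + ["MT"] * spec.n_mt
    lesions: list[SyntheticLesion] = []
    patient_counter = 0
    pending_patient: tuple[str, str] | None = None  # (patient_id, label)
    for k, (label, seed_seq) in enumerate(zip(labels, lesion_seeds)):
        rng = np.random.default_rng(seed_seq)
        t2, adc, mask = _make_lesion(rng, spec, label)
        if pending_patient is not None and pending_patient[1] == label:
            patient_id = pending_patient[0]
            pending_patient = None
        else:
            patient_counter += 1
            patient_id = f"P{patient_counter:03d}"
            if assign_rng.random() < spec.multi_lesion_rate:
                pending_patient = (patient_id, label)
        lesions.append(
            SyntheticLesion(
                lesion_id=f"L{k + 1:03d}",
                patient_id=patient_id,
                label=label,
                t2_volume=t2,
                adc_volume=adc,
                mask=mask,
            )
        )

    # perturbed re-segmentations: n_reseg lesions, balanced across classes
    reseg_rng = np.random.default_rng(root.spawn(2)[1])
    n_mt_reseg = min(spec.n_reseg // 2, spec.n_mt)
    n_wt_reseg = min(spec.n_reseg - n_mt_reseg, spec.n_wt)
    wt_idx = reseg_rng.choice(spec.n_wt, size=n_wt_reseg, replace=False)
    mt_idx = spec.n_wt + reseg_rng.choice(spec.n_mt, size=n_mt_reseg, replace=False)
    for idx in np.concatenate([wt_idx, mt_idx]):
        les = lesions[int(idx)]
        les.mask_reseg = simulate_resegmentation(
            les.mask, spec.reseg_jitter_mm, seed=int(reseg_rng.integers(2**31))
        )
    return lesions
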