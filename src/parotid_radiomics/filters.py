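"""Filter bank: Laplacian-of-Gaussian responses and level-1 undecimated wavelet sub-bands.

The bank mirrors the standard radiomics configuration: per sequence, one
original image, two LoG responses (fine sigma 3 mm, coarse sigma 5 mm)
emphasising edge-like structure at two scales, and the 8 sub-bands of a
single-level 3D stationary wavelet transform (default Coiflet-1). The
undecimated transform keeps every sub-band voxel-aligned with the lesion
mask, so the same mask indexes all filtered images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .image import VolumeImage

__all__ = ["FilterBankConfig", "log_filter", "wavelet_subbands", "filter_bank", "WAVELET_LABELS"]

#: Sub-band labels: one letter per axis in (x, y, z) order; L = low-pass, H = high-pass.
WAVELET_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class FilterBankConfig:
    wavelet_family: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = (3.0, 5.0)

    def __post_init__(self) -> None:
        self.log_sigmas_mm = tuple(float(s) for s in self.log_sigmas_mm)
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be > 0")
        pywt.Wavelet(self.wavelet_family)  # validates the name


def log_filter(img: VolumeImage, sigma_mm: float) -> VolumeImage:
    """Scale-normalized Laplacian-of-Gaussian response.

    ``sigma_mm`` is converted to voxels per axis through the image spacing
    and the response is multiplied by sigma^2 (scale normalization), so
    responses at different sigmas are comparable and a ball of radius r
    yields its strongest centre response near sigma = r/sqrt(3).
    """
    sig_vox = [sigma_mm / s for s in img.spacing_mm]
    if any(s < 0.5 for s in sig_vox):
        raise ValueError(
            f"sigma {sigma_mm} mm is under half a voxel for spacing {img.spacing_mm}"
        )
    # truncate=8: at the default 4-sigma support the kernel taps do not sum
    # to zero and a constant image leaks ~1e-4 of its level into the response
    out = ndimage.gaussian_laplace(img.voxels, sigma=sig_vox, mode="nearest", truncate=8.0)
    return img.with_voxels(out * sigma_mm**2)


def _separable_filter(data: np.ndarray, taps_per_axis) -> np.ndarray:
    out = data
    for axis, taps in enumerate(taps_per_axis):
        out = ndimage.correlate1d(out, taps, axis=axis, mode="mirror")
    return out


def wavelet_subbands(
    img: VolumeImage, cfg: FilterBankConfig | None = None
) -> dict[str, VolumeImage]:
    """Single-level undecimated 3D wavelet transform.

    Returns the 8 sub-bands keyed ``LLL`` ... ``HHH`` (letters in (x, y, z)
    axis order), each with the input's dimensions. Boundaries are handled
    by symmetric (mirror) extension.
    """
    cfg = cfg or FilterBankConfig()
    wav = pywt.Wavelet(cfg.wavelet_family)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    if min(img.shape) < len(lo):
        raise ValueError(
            f"image dims {img.shape} smaller than the {len(lo)}-tap wavelet filter"
        )
    bank = {"L": lo, "H": hi}
    out: dict[str, VolumeImage] = {}
    for label in WAVELET_LABELS:
        taps = [bank[c] for c in label]
        out[label] = img.with_voxels(_separable_filter(img.voxels, taps))
    return out


def filter_bank(
    img: VolumeImage, cfg: FilterBankConfig | None = None
) -> dict[str, VolumeImage]:
    """All filtered derivatives of ``img``, keyed by filter label.

    Keys: ``original``, ``wavelet-LLL`` ... ``wavelet-HHH``,
    ``log-sigma-3-mm`` / ``log-sigma-5-mm`` (one per configured sigma).
    """
    cfg = cfg or FilterBankConfig()
    images = {"original": img}
    for label, sub in wavelet_subbands(img, cfg).items():
        images[f"wavelet-{label}"] = sub
    for sigma in cfg.log_sigmas_mm:
        images[f"log-sigma-{sigma:g}-mm"] = log_filter(img, sigma)
    return images
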