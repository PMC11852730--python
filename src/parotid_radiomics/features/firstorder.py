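"""First-order (histogram) intensity features.

Computed from the raw ROI intensities, except Entropy and Uniformity,
which use the fixed-bin-width discretized levels. Skewness and Kurtosis
use uncorrected population moments (Pearson kurtosis, normal = 3);
for a constant ROI both are defined as 0 so feature tables stay complete.
"""

from __future__ import annotations

import numpy as np

FEATURE_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Uniformity",
)


def first_order_features(
    intensities: np.ndarray, level_values: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """The 18 first-order features.

    Parameters
    ----------
    intensities
        1D array of raw ROI voxel intensities.
    level_values
        1D array of the same voxels' discretized gray levels (>= 1).
    voxel_volume_mm3
        Physical volume of one voxel (TotalEnergy scaling).
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    sd = float(np.sqrt(m2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    counts = np.bincount(np.asarray(level_values, dtype=np.int64))[1:]
    p = counts[counts > 0] / counts.sum()

    if m2 > 0:
        skew = float(((x - mean) ** 3).mean() / m2**1.5)
        kurt = float(((x - mean) ** 4).mean() / m2**2)
    else:
        skew = kurt = 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Uniformity": float((p**2).sum()),
    }
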