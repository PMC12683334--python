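"""First-order (intensity histogram) features.

Eighteen statistics of the ROI intensity distribution. All but Entropy and
Uniformity are computed on the raw (continuous) intensities; those two are
computed on the discretized gray levels, since they depend on a finite
histogram.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_FEATURE_NAMES = (
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
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray, labels: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """Compute the 18 first-order features.

    Parameters
    ----------
    values : 1D array
        Raw ROI intensities.
    labels : 1D int array
        Discretized gray levels of the same voxels (for Entropy/Uniformity).
    voxel_volume_mm3 : float
        Physical voxel volume (for TotalEnergy).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        centered = x - mean
        m2 = var
        skew = float((centered**3).mean() / m2**1.5)
        kurt = float((centered**4).mean() / m2**2)  # Pearson kurtosis (normal = 3)
    else:
        skew, kurt = 0.0, 0.0

    counts = np.bincount(np.asarray(labels, dtype=np.int64).ravel())
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
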