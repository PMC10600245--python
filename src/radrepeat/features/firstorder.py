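"""First-order (intensity histogram) features.

The 18 standardized first-order statistics of the ROI intensity
distribution.  Entropy and Uniformity are computed on the discretized
gray levels; all other statistics use the raw (filtered) intensities.
Skewness and Kurtosis are population moments; Kurtosis is reported
non-excess (a normal distribution scores 3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def first_order_features(
    values: np.ndarray,
    discretized: np.ndarray | None = None,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """Compute the 18 first-order features of a 1D ROI intensity array.

    ``discretized`` supplies integer gray levels for Entropy/Uniformity;
    when omitted the raw values are treated as the levels.
    """
    x = np.asarray(values, dtype=np.float64).reshape(-1)
    if x.size == 0:
        raise ValueError("first-order features require at least one voxel")
    if discretized is None:
        discretized = x
    d = np.asarray(discretized).reshape(-1)
    _, counts = np.unique(d, return_counts=True)
    p = counts / counts.sum()

    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    if m2 > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
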