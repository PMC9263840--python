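"""First-order (intensity histogram) statistics: 18 features.

Moments use the population convention; Kurtosis is non-excess (a normal
distribution scores 3).  Entropy and Uniformity operate on the same
fixed-bin-width discretization used by the texture families.
"""

from __future__ import annotations

import numpy as np

from .texture import DiscretizedRoi

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(droi: DiscretizedRoi,
                        voxel_volume_mm3: float) -> dict[str, float]:
    x = droi.intensities
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m = x - mean
        skew = float((m ** 3).mean() / var ** 1.5)
        kurt = float((m ** 4).mean() / var ** 2)
    else:
        skew, kurt = 0.0, 0.0
    counts = np.bincount(droi.levels[droi.mask] - 1)
    p = counts[counts > 0] / n
    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
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
        "RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }
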