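"""First-order intensity statistics (19 features).

Computed on the raw (un-discretized) intensities inside the mask, except
``Entropy`` and ``Uniformity`` which are defined on the fixed-bin-width
histogram so that they are consistent with the texture families.

Degenerate conventions: skewness and kurtosis of a constant distribution are
0 (kurtosis is otherwise the *non-excess* Pearson kurtosis, i.e. 3 for a
normal distribution).  Percentiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import numpy as np

from .catalogue import FIRSTORDER_FEATURES
from .discretize import discretize


def first_order_features(
    values: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """Compute the 19 first-order features of a masked intensity sample.

    Parameters
    ----------
    values : 1-D array of intensities inside the region.
    voxel_volume_mm3 : physical volume of one voxel, used by TotalEnergy.
    bin_width : histogram bin width for Entropy / Uniformity.

    Returns
    -------
    dict mapping feature name (without family prefix) to value.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first-order features require a non-empty region")

    mean = float(v.mean())
    var = float(v.var())  # population variance
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])

    # robust MAD: mean absolute deviation of the 10-90 percentile subset
    robust = v[(v >= p10) & (v <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:  # pragma: no cover - only for pathological two-point samples
        rmad = 0.0

    if sd > 0:
        centered = v - mean
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4)
    else:
        skew = 0.0
        kurt = 0.0

    levels = discretize(v, bin_width)
    counts = np.bincount(levels)[1:]  # level 0 unused
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((v**2).sum())
    out = {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": entropy,
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
        "StandardDeviation": sd,
    }
    assert tuple(out) == FIRSTORDER_FEATURES
    return out
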