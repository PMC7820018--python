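"""First-order (intensity histogram) features: 17 statistics.

All statistics are computed on the raw in-mask intensities except Entropy
and Uniformity, which are computed on the fixed-bin-width discretized
histogram.  Variance, skewness and kurtosis use population (n) moments;
kurtosis is the non-excess (Pearson) form.  On a constant or single-voxel
ROI the dispersion features are 0 and skewness/kurtosis are undefined:
they are emitted as the documented sentinel 0.0 with a log entry.
"""

from __future__ import annotations

import logging

import numpy as np

from ..volume import ImageVolume, check_mask
from .preprocess import DiscretizedRoi, discretize

logger = logging.getLogger(__name__)

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = [
    "Energy",
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
]


def firstorder_features(
    volume: ImageVolume,
    mask: ImageVolume,
    bin_width: float = 25.0,
    droi: DiscretizedRoi | None = None,
) -> dict[str, float]:
    """The 17 first-order statistics of the in-mask intensity distribution."""
    fg = check_mask(volume, mask)
    x = volume.values[fg].astype(float)
    if droi is None:
        droi = discretize(volume, mask, bin_width)
    p = droi.histogram() / droi.n_voxels
    p = p[p > 0]

    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2**2)
    else:
        logger.info("flat ROI: skewness/kurtosis undefined, emitting sentinel 0.0")
        skew = 0.0
        kurt = 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float(np.sum(p**2)),
    }
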