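"""First-order (histogram) intensity statistics of an ROI."""

from __future__ import annotations

import numpy as np

from ..core import Mask3D, Volume3D
from .discretize import discretize

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
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
    "Variance",
    "Uniformity",
)


def firstorder_features(
    image: Volume3D | np.ndarray,
    roi: Mask3D | np.ndarray,
    bin_count: int = 32,
    voxel_volume_mm3: float | None = None,
) -> dict[str, float]:
    """19 first-order statistics; Entropy/Uniformity use the discretized
    ``bin_count``-level histogram.  Population (ddof = 0) moments; Kurtosis
    is the non-excess (Pearson) form; Skewness/Kurtosis of a constant ROI
    are 0 by convention.
    """
    if isinstance(image, Volume3D):
        arr = image.voxels
        vv = image.voxel_volume_mm3 if voxel_volume_mm3 is None else voxel_volume_mm3
    else:
        arr = np.asarray(image, dtype=float)
        vv = 1.0 if voxel_volume_mm3 is None else voxel_volume_mm3
    mask = roi.voxels if isinstance(roi, Mask3D) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    x = arr[mask].astype(float)
    n = x.size

    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))

    d = discretize(arr, mask, bin_count)
    counts = np.bincount(d.levels[mask] - 1, minlength=d.Ng).astype(float)
    p = counts / n
    nz = p > 0

    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(vv * (x**2).sum()),
        "Entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(np.ptp(x)),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": sd,
        "Skewness": float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0,
        "Kurtosis": float(((x - mean) ** 4).mean() / sd**4) if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
    return out
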