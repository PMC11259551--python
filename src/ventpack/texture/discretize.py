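"""Gray-level discretization of an ROI into equal-width bins."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Mask3D, Volume3D

__all__ = ["DiscretizedROI", "discretize"]


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels 1..Ng inside the ROI, 0 outside."""

    levels: np.ndarray
    Ng: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.Ng < 1:
            raise ValueError("Ng must be >= 1")
        inside = self.levels[self.levels > 0]
        if inside.size and inside.max() > self.Ng:
            raise ValueError("levels exceed Ng")

    @property
    def roi_mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())


def discretize(image: Volume3D | np.ndarray, roi: Mask3D | np.ndarray, bin_count: int = 32) -> DiscretizedROI:
    """Equal-width binning of ROI intensities into ``bin_count`` gray levels.

    Bins span [min, max] of the ROI intensities; level = bin index + 1.
    A constant ROI collapses to a single level (Ng = 1).  Matrix features
    depending on the gray-level count (e.g. Idn, Idmn) therefore see
    Ng = ``bin_count`` whenever the ROI has any intensity spread.
    """
    arr = image.voxels if isinstance(image, Volume3D) else np.asarray(image, dtype=float)
    mask = roi.voxels if isinstance(roi, Mask3D) else np.asarray(roi, dtype=bool)
    if arr.shape != mask.shape:
        raise ValueError("image and roi shapes differ")
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    if not mask.any():
        raise ValueError("ROI is empty")

    vals = arr[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(arr.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return DiscretizedROI(levels=levels, Ng=1, bin_edges=np.array([lo, hi]))

    edges = np.linspace(lo, hi, bin_count + 1)
    # right-closed last bin so the maximum lands in level bin_count
    idx = np.minimum(((vals - lo) / (hi - lo) * bin_count).astype(int), bin_count - 1)
    levels[mask] = idx + 1
    return DiscretizedROI(levels=levels, Ng=int(bin_count), bin_edges=edges)
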