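"""Slice-wise stationary wavelet subbands of a 3-D volume.

A single-level 2-D undecimated (stationary) wavelet transform is applied
to every slice along the third axis and the four subbands are restacked
to the input grid, so subband voxels stay aligned with the ROI.  LL is
low-pass in both in-plane directions (the smoothed approximation); LH
responds to intensity variation along the first in-plane axis (horizontal
edges), HL to variation along the second in-plane axis (vertical edges),
and HH to diagonal detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ..core import Volume3D

__all__ = ["WaveletSubbands", "wavelet_subbands", "SUBBAND_NAMES"]

SUBBAND_NAMES = ("LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class WaveletSubbands:
    """Exactly four subband volumes aligned to the input grid."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.LL.shape, self.LH.shape, self.HL.shape, self.HH.shape}
        if len(shapes) != 1:
            raise ValueError("subband shapes differ")

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _swt2_slice(sl: np.ndarray, wavelet: str):
    # SWT needs even extents: reflect-pad odd axes, crop afterwards
    pad0 = sl.shape[0] % 2
    pad1 = sl.shape[1] % 2
    padded = np.pad(sl, ((0, pad0), (0, pad1)), mode="symmetric")
    (cA, (cH, cV, cD)), = pywt.swt2(padded, wavelet, level=1)
    n0, n1 = sl.shape
    return cA[:n0, :n1], cH[:n0, :n1], cV[:n0, :n1], cD[:n0, :n1]


def wavelet_subbands(image: Volume3D | np.ndarray, wavelet: str = "coif1") -> WaveletSubbands:
    """Four single-level stationary-wavelet subbands, slice by slice.

    ``LH`` carries detail along the first in-plane axis, ``HL`` along the
    second; a constant image has identically zero LH/HL/HH.  The transform
    is linear in the input.  Default wavelet ``coif1``; ``haar`` gives the
    simplest filters for hand-checked tests.
    """
    arr = image.voxels if isinstance(image, Volume3D) else np.asarray(image, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D volume")
    bands = {name: np.empty_like(arr, dtype=float) for name in SUBBAND_NAMES}
    for k in range(arr.shape[2]):
        cA, cH, cV, cD = _swt2_slice(arr[:, :, k], wavelet)
        bands["LL"][:, :, k] = cA
        bands["LH"][:, :, k] = cH
        bands["HL"][:, :, k] = cV
        bands["HH"][:, :, k] = cD
    return WaveletSubbands(**bands)
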