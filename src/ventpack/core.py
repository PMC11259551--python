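"""Voxel-grid containers and NIfTI I/O.

All image stages of the pipeline operate on :class:`Volume3D` (scalar
intensities) and :class:`Mask3D` (binary masks) carrying their physical
voxel spacing in millimetres.  Grids are plain ``numpy`` arrays in the
image's native orientation; no resampling or reorientation is performed.
Voxel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "Mask3D", "load_volume", "load_mask", "save_volume", "save_mask"]


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels
        3-D array of signal intensities (arbitrary units).
    spacing_mm
        Per-axis voxel edge length in millimetres.  Default 5 mm isotropic,
        the resolution of coronal hyperpolarized-gas ventilation MRI this
        pipeline targets.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("voxels must be a 3-D grid with all dimensions >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("voxels must be finite")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three strictly positive lengths")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class Mask3D:
    """A 3-D binary mask aligned to a companion :class:`Volume3D` grid."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("mask must be a 3-D grid with all dimensions >= 1")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three strictly positive lengths")
        object.__setattr__(self, "voxels", arr.astype(bool))
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def __and__(self, other: "Mask3D") -> "Mask3D":
        return Mask3D(self.voxels & other.voxels, self.spacing_mm)

    def issubset(self, other: "Mask3D") -> bool:
        return bool(np.all(~self.voxels | other.voxels))


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(vol: Volume3D, path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.spacing_mm)), str(path))


def save_mask(mask: Mask3D, path) -> None:
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm)), str(path))


def _load(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), spacing


def load_volume(path) -> Volume3D:
    data, spacing = _load(path)
    return Volume3D(np.asarray(data, dtype=np.float64), spacing)


def load_mask(path) -> Mask3D:
    data, spacing = _load(path)
    return Mask3D(np.asarray(data) > 0, spacing)
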