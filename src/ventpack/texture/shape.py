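"""Voxel-based 3-D shape descriptors of a binary ROI."""

from __future__ import annotations

import numpy as np

from ..core import Mask3D

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = (
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "SphericalDisproportion",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of voxel faces exposed to background (voxel surface)."""
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1)
    for ax in range(3):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += np.abs(diff).sum() * face[ax]
    return float(area)


def _max_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    if len(pts) > 50:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def shape_features(roi: Mask3D, spacing_mm: tuple[float, float, float] | None = None) -> dict[str, float]:
    """14 shape descriptors from voxel counts, exposed faces and the
    principal axes of the voxel-centre point cloud.

    Axis lengths are 4 * sqrt(lambda) with lambda the eigenvalues of the
    population covariance (divide by N) of the ROI voxel physical
    coordinates; a single-voxel ROI has all axis lengths 0 and
    Elongation = Flatness = 1 by convention.
    """
    spacing = np.asarray(spacing_mm if spacing_mm is not None else roi.spacing_mm, dtype=float)
    mask = roi.voxels
    if not mask.any():
        raise ValueError("ROI is empty")
    coords = np.argwhere(mask).astype(float) * spacing
    n = len(coords)
    volume = float(n * spacing.prod())
    area = _surface_area(mask, spacing)

    cov = np.cov(coords, rowvar=False, bias=True) if n > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    sphericity = (np.pi ** (1 / 3)) * ((6.0 * volume) ** (2 / 3)) / area

    # in-plane diameters per slice along the third axis
    max2d = 0.0
    for k in range(mask.shape[2]):
        sl = np.argwhere(mask[:, :, k]).astype(float) * spacing[:2]
        if len(sl) >= 2:
            max2d = max(max2d, _max_pairwise(sl))

    out = {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": float(sphericity),
        "Compactness1": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "Compactness2": float(36.0 * np.pi * volume**2 / area**3),
        "SphericalDisproportion": float(1.0 / sphericity),
        "Maximum3DDiameter": _max_pairwise(coords),
        "Maximum2DDiameterSlice": max2d,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
    }
    return out
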