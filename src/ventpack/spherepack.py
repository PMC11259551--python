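"""Greedy maximal-sphere packing of ventilation-defect masks.

The unventilated region ``R`` of a ventilation image is decomposed into a
set ``S`` of pairwise-disjoint discrete spheres that exactly tile it: at
each round the largest sphere(s) that fit inside the remaining region are
identified from the Euclidean distance transform, carved out, and the
process repeats until only single voxels remain.  Every leftover voxel is
counted as a diameter-1 sphere, so the packed volume always equals the
region volume exactly.

From a packing three ventilation-heterogeneity summaries are derived:

* **VDCP** — ventilation defect cluster percent, the packed defect volume
  as a percentage of the lung volume;
* **CDD1** — the number of diameter-1 spheres (scattered single-voxel
  defects);
* **cluster slope** — the slope of log10(cumulative sphere count >= d)
  against log10(d), a power-law summary of the defect size distribution.

Discrete sphere convention: a sphere of odd diameter ``d`` centred on
voxel ``c`` contains every voxel ``u`` with ``||u - c||_2 <= (d - 1) / 2``
in voxel units.  ``d = 1`` is a single voxel.  Packing is performed in
voxel space; physical spacing enters only through reported volumes, so
strongly anisotropic grids should be resampled before packing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Mask3D

__all__ = [
    "Sphere",
    "SpherePacking",
    "ClusterMetrics",
    "discrete_ball_offsets",
    "maximal_sphere_candidates",
    "pack_spheres",
    "cluster_metrics",
    "packing_label_volume",
]

logger = logging.getLogger(__name__)

_BALL_CACHE: dict[int, np.ndarray] = {}


def discrete_ball_offsets(diameter_vox: int) -> np.ndarray:
    """Integer offsets of the discrete ball of odd diameter ``diameter_vox``.

    Membership rule: ``||u||_2 <= (d - 1) / 2`` on voxel centres, so
    ``d = 1`` is one voxel and ``d = 3`` is the 7-voxel face-neighbour ball.
    """
    d = int(diameter_vox)
    if d < 1 or d % 2 == 0:
        raise ValueError(f"sphere diameter must be an odd positive integer, got {diameter_vox}")
    if d not in _BALL_CACHE:
        r = (d - 1) // 2
        ax = np.arange(-r, r + 1)
        ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
        keep = ii**2 + jj**2 + kk**2 <= r**2
        _BALL_CACHE[d] = np.stack([ii[keep], jj[keep], kk[keep]], axis=1)
    return _BALL_CACHE[d]


@dataclass(frozen=True)
class Sphere:
    """A discrete sphere: centre voxel index and odd diameter in voxels."""

    center: tuple[int, int, int]
    diameter_vox: int

    def __post_init__(self) -> None:
        if self.diameter_vox < 1 or self.diameter_vox % 2 == 0:
            raise ValueError("diameter_vox must be an odd positive integer")

    @property
    def radius_vox(self) -> float:
        return (self.diameter_vox - 1) / 2

    def member_voxels(self) -> np.ndarray:
        return discrete_ball_offsets(self.diameter_vox) + np.asarray(self.center)


@dataclass(frozen=True)
class SpherePacking:
    """Result of greedily packing a defect region with disjoint spheres.

    ``spheres`` lists every accepted sphere of diameter >= 3 in
    non-increasing diameter order; the ``residual_unit_count`` voxels left
    over are each a diameter-1 sphere.  The volume constraint
    ``covered + residual == region`` holds exactly by construction.
    """

    spheres: tuple[Sphere, ...]
    region_voxel_count: int
    covered_voxel_count: int
    residual_unit_count: int

    @property
    def size_histogram(self) -> dict[int, int]:
        """Sphere count per diameter, diameter-1 spheres included."""
        hist: dict[int, int] = {}
        for s in self.spheres:
            hist[s.diameter_vox] = hist.get(s.diameter_vox, 0) + 1
        if self.residual_unit_count:
            hist[1] = hist.get(1, 0) + self.residual_unit_count
        return hist

    @property
    def total_sphere_count(self) -> int:
        return len(self.spheres) + self.residual_unit_count


@dataclass(frozen=True)
class ClusterMetrics:
    """Defect-cluster summaries derived from a sphere packing."""

    vdcp_percent: float
    cdd1: int
    cluster_slope: float
    size_histogram: dict[int, int] = field(default_factory=dict)


def _edt_voxels(mask_arr: np.ndarray) -> np.ndarray:
    # grid is padded with background, so boundary foreground voxels get EDT 1
    padded = np.pad(mask_arr, 1)
    edt = ndimage.distance_transform_edt(padded)
    return edt[1:-1, 1:-1, 1:-1]


def _candidates_from_array(mask_arr: np.ndarray) -> tuple[list[tuple[tuple[int, int, int], int]], int]:
    if not mask_arr.any():
        return [], 0
    edt = _edt_voxels(mask_arr)
    # d(v) = 2*ceil(EDT)-1: the inscribed radius ceil(EDT)-1 is strictly
    # below the distance to background, so containment is guaranteed, and
    # an isolated planted ball is recovered at its exact diameter
    dia = 2 * np.ceil(edt).astype(int) - 1
    dia[~mask_arr] = 0
    dmax = int(dia.max())
    idx = np.argwhere(dia == dmax)  # argwhere is already lexicographic scan order
    return [((int(i), int(j), int(k)), dmax) for i, j, k in idx], dmax


def maximal_sphere_candidates(mask: Mask3D) -> list[tuple[tuple[int, int, int], int]]:
    """All centres attaining the current maximum inscribed-sphere diameter.

    The candidate diameter at a foreground voxel ``v`` is
    ``d(v) = 2 * ceil(EDT(v)) - 1`` where EDT is the Euclidean distance (in
    voxel units) to the nearest background voxel centre, the grid being
    padded with background.  The inscribed radius ``ceil(EDT) - 1`` is
    strictly smaller than the distance to background, so the sphere of
    diameter ``d(v)`` centred on ``v`` lies entirely inside the mask, and a
    planted isolated discrete ball is recovered at its exact diameter.
    Centres are returned in lexicographic scan order; an empty mask yields
    an empty list.
    """
    cands, _ = _candidates_from_array(np.asarray(mask.voxels, dtype=bool))
    return cands


def pack_spheres(defect_mask: Mask3D) -> SpherePacking:
    """Greedily tile ``defect_mask`` with disjoint maximal spheres.

    Each round takes the candidates at the current global maximum diameter,
    accepts them in lexicographic order (skipping any that would overlap a
    sphere already accepted this round), removes the accepted spheres from
    the region, and recurses on the remainder.  When the maximum diameter
    falls to 1 every remaining voxel becomes a diameter-1 sphere.
    """
    remaining = np.asarray(defect_mask.voxels, dtype=bool).copy()
    region_count = int(remaining.sum())
    shape = remaining.shape
    accepted: list[Sphere] = []
    covered = 0

    while True:
        cands, dmax = _candidates_from_array(remaining)
        if dmax <= 1:
            break
        offsets = discrete_ball_offsets(dmax)
        for center, _ in cands:
            vox = offsets + np.asarray(center)
            sl = tuple(vox.T)
            # containment is guaranteed by the EDT bound; overlap with a
            # sphere accepted earlier this round defers the candidate
            if not remaining[sl].all():
                continue
            remaining[sl] = False
            accepted.append(Sphere(center, dmax))
            covered += len(offsets)

    residual = int(remaining.sum())
    accepted.sort(key=lambda s: (-s.diameter_vox, s.center))
    packing = SpherePacking(
        spheres=tuple(accepted),
        region_voxel_count=region_count,
        covered_voxel_count=covered,
        residual_unit_count=residual,
    )
    assert packing.covered_voxel_count + packing.residual_unit_count == region_count
    return packing


def cluster_metrics(
    packing: SpherePacking,
    lung_voxel_count: int,
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0),
) -> ClusterMetrics:
    """VDCP, CDD1 and the log-log cluster-size slope for a packing.

    VDCP normalises the packed defect volume by ``lung_voxel_count`` (the
    thoracic cavity by default).  The slope is the least-squares slope of
    log10(cumulative number of spheres of diameter >= d) versus log10(d)
    over the diameters with nonzero counts; with fewer than two distinct
    diameters it is undefined and returned as NaN.
    """
    if lung_voxel_count < packing.region_voxel_count:
        raise ValueError("lung_voxel_count must be at least the packed region size")
    hist = packing.size_histogram
    vdcp = 100.0 * packing.region_voxel_count / lung_voxel_count if lung_voxel_count else 0.0
    cdd1 = hist.get(1, 0)

    diameters = np.array(sorted(hist), dtype=float)
    if len(diameters) < 2:
        warnings.warn("fewer than two distinct sphere diameters; cluster slope undefined")
        slope = float("nan")
    else:
        counts = np.array([hist[int(d)] for d in diameters], dtype=float)
        cumulative = counts[::-1].cumsum()[::-1]  # number of spheres with diameter >= d
        x = np.log10(diameters)
        y = np.log10(cumulative)
        slope = float(np.polyfit(x, y, 1)[0])

    return ClusterMetrics(
        vdcp_percent=float(vdcp), cdd1=int(cdd1), cluster_slope=slope, size_histogram=hist
    )


def packing_label_volume(packing: SpherePacking, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel grid with each packed sphere painted with its diameter.

    Residual diameter-1 voxels are not recorded in the packing's sphere
    list with their positions, so only spheres of diameter >= 3 appear;
    useful for size-coded renderings of the defect clusters.
    """
    out = np.zeros(shape, dtype=np.int16)
    for s in packing.spheres:
        vox = s.member_voxels()
        out[tuple(vox.T)] = s.diameter_vox
    return out
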