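"""Thoracic and ventilation segmentation.

Preprocessing chain for paired proton / hyperpolarized-gas volumes:

1. seeded region growing on the proton image isolates the thoracic cavity;
2. 1-D k-means clustering of gas-image intensities inside the cavity
   partitions ventilation into ``k`` intensity classes (lowest = defect)
   and yields the ventilation defect percent (VDP);
3. Kapur maximum-entropy thresholding of the in-cavity histogram defines
   the ventilated region-of-interest used for texture extraction.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import Mask3D, Volume3D

__all__ = [
    "SegmentationResult",
    "region_grow_thoracic",
    "kmeans_ventilation",
    "max_entropy_roi",
]

logger = logging.getLogger(__name__)

_FACE_NEIGHBORS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass(frozen=True)
class SegmentationResult:
    """Thoracic mask, ventilation intensity clusters and VDP.

    ``ventilation_labels`` holds 0 outside the thoracic cavity and 1..k
    inside, clusters ordered by ascending mean intensity (1 = defect).
    """

    thoracic: Mask3D
    ventilation_labels: np.ndarray
    ventilated_roi: Mask3D
    vdp_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vdp_percent <= 100.0):
            raise ValueError("vdp_percent must lie in [0, 100]")


def region_grow_thoracic(
    proton: Volume3D,
    seeds: list[tuple[int, int, int]],
    tolerance: float,
    closing_radius: int = 1,
) -> Mask3D:
    """Seeded region growing of the thoracic cavity on the proton image.

    Starting from the seed voxels, 6-connected neighbours are accepted
    whenever their intensity differs from the running region mean by at
    most ``tolerance``; the mean is updated after each acceptance and the
    frontier is processed in deterministic first-in-first-out order from
    sorted seeds, so permuting the seed list does not change the result.
    A morphological closing (ball radius ``closing_radius``) fills small
    gaps afterwards.  If no neighbour of any seed is growable the
    seed-only mask is returned with a warning.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    arr = proton.voxels
    shape = arr.shape
    for s in seeds:
        if not all(0 <= c < n for c, n in zip(s, shape)):
            raise ValueError(f"seed {s} outside grid {shape}")

    mask = np.zeros(shape, dtype=bool)
    queue: deque = deque()
    total = 0.0
    count = 0
    for s in sorted(set(tuple(map(int, s)) for s in seeds)):
        mask[s] = True
        total += arr[s]
        count += 1
        queue.append(s)

    while queue:
        v = queue.popleft()
        mean = total / count
        for off in _FACE_NEIGHBORS:
            u = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if not all(0 <= c < n for c, n in zip(u, shape)):
                continue
            if mask[u]:
                continue
            if abs(arr[u] - mean) <= tolerance:
                mask[u] = True
                total += arr[u]
                count += 1
                queue.append(u)

    if count == len(set(map(tuple, seeds))):
        logger.warning("region growing accepted no voxels beyond the seeds")
        warnings.warn("region growing accepted no voxels beyond the seeds")
        return Mask3D(mask, proton.spacing_mm)

    if closing_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        closed = ndimage.binary_closing(
            mask, structure=structure, iterations=closing_radius
        )
        mask = mask | closed
    return Mask3D(mask, proton.spacing_mm)


def kmeans_ventilation(
    he3: Volume3D, thoracic: Mask3D, k: int = 5, seed: int = 0
) -> SegmentationResult:
    """1-D k-means ventilation clustering and VDP inside the thoracic mask.

    Intensities of thoracic voxels are clustered with k-means++ (fixed
    seed, reproducible bit-for-bit), clusters relabelled 1..k in ascending
    mean intensity, and VDP computed as the percentage of thoracic voxels
    in the lowest-intensity cluster.  If fewer distinct intensities than
    ``k`` exist, ``k`` is reduced to that count with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tmask = thoracic.voxels
    if not tmask.any():
        raise ValueError("thoracic mask is empty")
    values = he3.voxels[tmask]
    distinct = np.unique(values)
    k_eff = int(min(k, len(distinct)))
    if k_eff < k:
        msg = f"only {len(distinct)} distinct intensities; reducing k from {k} to {k_eff}"
        logger.warning(msg)
        warnings.warn(msg)

    if k_eff == 1:
        labels_in = np.zeros(len(values), dtype=int)
        order_means = distinct
    else:
        km = KMeans(n_clusters=k_eff, init="k-means++", n_init=10, random_state=seed)
        raw = km.fit_predict(values.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
        relabel = np.empty(k_eff, dtype=int)
        relabel[order] = np.arange(k_eff)
        labels_in = relabel[raw]
        order_means = km.cluster_centers_.ravel()[order]

    labels = np.zeros(he3.shape, dtype=np.int32)
    labels[tmask] = labels_in + 1
    vdp = 100.0 * float(np.sum(labels_in == 0)) / float(len(values))
    roi = Mask3D(labels >= 2, he3.spacing_mm)
    return SegmentationResult(
        thoracic=thoracic, ventilation_labels=labels, ventilated_roi=roi, vdp_percent=vdp
    )


def _kapur_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Kapur maximum-entropy threshold on a ``bins``-bin histogram.

    Returns the intensity (bin upper edge) maximizing the sum of the
    below- and above-threshold Shannon entropies.
    """
    hist, edges = np.histogram(values, bins=bins)
    p = hist.astype(float) / hist.sum()
    cum = np.cumsum(p)
    best_entropy, best_t = -np.inf, 0
    for t in range(bins - 1):
        w0 = cum[t]
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        p0 = p[: t + 1] / w0
        p1 = p[t + 1 :] / w1
        h0 = -np.sum(p0[p0 > 0] * np.log(p0[p0 > 0]))
        h1 = -np.sum(p1[p1 > 0] * np.log(p1[p1 > 0]))
        if h0 + h1 > best_entropy:
            best_entropy = h0 + h1
            best_t = t
    return float(edges[best_t + 1])


def max_entropy_roi(he3: Volume3D, thoracic: Mask3D) -> Mask3D:
    """Ventilated region-of-interest by Kapur maximum-entropy thresholding.

    The threshold is computed on the 256-bin histogram of gas intensities
    inside the thoracic cavity; the ROI keeps the thoracic voxels at or
    above it (the inhaled-gas distribution).  A single-valued histogram
    degenerates to ROI = thoracic with a warning.
    """
    tmask = thoracic.voxels
    if not tmask.any():
        raise ValueError("thoracic mask is empty")
    values = he3.voxels[tmask]
    if np.ptp(values) == 0:
        warnings.warn("constant intensity inside thoracic mask; ROI = thoracic")
        return Mask3D(tmask.copy(), he3.spacing_mm)
    thr = _kapur_threshold(values)
    return Mask3D(tmask & (he3.voxels >= thr), he3.spacing_mm)
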