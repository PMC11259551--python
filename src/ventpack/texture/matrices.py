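"""Gray-level matrix texture features (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All families operate on a :class:`~ventpack.texture.discretize.DiscretizedROI`
with levels 1..Ng.  Directional families (GLCM, GLRLM) enumerate the 13
unique 3-D directions at distance 1, compute features per direction on the
normalized matrix, and average over directions.  GLSZM zones and GLDM
dependences use 26-connectivity.  Feature definitions follow the standard
radiomics conventions; undefined features on degenerate input (e.g. a
single-voxel ROI with no co-occurring pairs) are returned as NaN sentinels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "OFFSETS_13",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

#: the 13 unique direction vectors (distance 1, 26-connectivity, one per
#: antipodal pair), lexicographic order with positive leading component
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EPS = np.finfo(float).eps


def _nan_dict(names) -> dict[str, float]:
    return {n: float("nan") for n in names}


def _shift_pairs(shape, off):
    """Slice pairs (src, dst) with dst = src + off, both in bounds."""
    src, dst = [], []
    for n, d in zip(shape, off):
        if d == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif d > 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(levels: np.ndarray, Ng: int, off) -> np.ndarray:
    src, dst = _shift_pairs(levels.shape, off)
    a = levels[src].ravel()
    b = levels[dst].ravel()
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return np.zeros((Ng, Ng))
    idx = (a[valid] - 1) * Ng + (b[valid] - 1)
    counts = np.bincount(idx, minlength=Ng * Ng).reshape(Ng, Ng).astype(float)
    return counts + counts.T  # symmetric co-occurrences


def _glcm_features_single(P: np.ndarray, Ng: int) -> dict[str, float]:
    p = P / P.sum()
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * i).sum())
    uy = float((py * i).sum())
    sx = float(np.sqrt((px * (i - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (i - uy) ** 2).sum()))

    k_diff = np.arange(0, Ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * ii * jj).sum())
    out["ClusterProminence"] = float((p * (ii + jj - ux - uy) ** 4).sum())
    out["ClusterShade"] = float((p * (ii + jj - ux - uy) ** 3).sum())
    out["ClusterTendency"] = float((p * (ii + jj - ux - uy) ** 2).sum())
    out["Contrast"] = float((p * (ii - jj) ** 2).sum())
    if sx > 0 and sy > 0:
        out["Correlation"] = float(((p * ii * jj).sum() - ux * uy) / (sx * sy))
    else:
        out["Correlation"] = 1.0  # fully dependent degenerate marginals
    da = float((p_diff * k_diff).sum())
    out["DifferenceAverage"] = da
    nz = p_diff > 0
    out["DifferenceEntropy"] = float(-(p_diff[nz] * np.log2(p_diff[nz])).sum())
    out["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    out["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + ((ii - jj) ** 2) / Ng**2)).sum())
    out["Idn"] = float((p / (1.0 + np.abs(ii - jj) / Ng)).sum())

    pxy = np.outer(px, py)
    nzp = p > 0
    hxy = float(-(p[nzp] * np.log2(p[nzp])).sum())
    nz1 = nzp & (pxy > 0)
    hxy1 = float(-(p[nz1] * np.log2(pxy[nz1])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    off_diag = ii != jj
    iv = p[off_diag] / ((ii - jj)[off_diag] ** 2)
    out["InverseVariance"] = float(iv.sum())
    out["JointAverage"] = ux
    out["JointEnergy"] = float((p**2).sum())
    out["JointEntropy"] = hxy
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((p_sum * k_sum).sum())
    nzs = p_sum > 0
    out["SumEntropy"] = float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum())
    out["SumSquares"] = float((p * (ii - ux) ** 2).sum())

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    if Ng == 1:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = (p / px[:, None]) @ (p / py[None, :]).T
        Q = np.nan_to_num(Q, nan=0.0, posinf=0.0, neginf=0.0)
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        out["MCC"] = float(np.sqrt(max(eig[-2], 0.0))) if len(eig) >= 2 else 1.0
    return out


def glcm_features(d: DiscretizedROI) -> dict[str, float]:
    """24 gray-level co-occurrence features, averaged over 13 directions.

    Includes the two normalized local-homogeneity measures Idn and Idmn,
    Idn = sum p(i,j) / (1 + |i-j|/Ng) and
    Idmn = sum p(i,j) / (1 + (i-j)^2/Ng^2), both in (0, 1].
    """
    per_dir = []
    for off in OFFSETS_13:
        P = _glcm_matrix(d.levels, d.Ng, off)
        if P.sum() > 0:
            per_dir.append(_glcm_features_single(P, d.Ng))
    if not per_dir:
        warnings.warn("no co-occurring voxel pairs in ROI; GLCM features undefined")
        return _nan_dict(GLCM_NAMES)
    return {n: float(np.mean([f[n] for f in per_dir])) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def _run_matrix(levels: np.ndarray, Ng: int, off) -> np.ndarray:
    """Run-length matrix P(level, run length) for one direction.

    Dynamic programming along the direction's leading axis: the run length
    at a voxel is one more than at its successor when levels match, and
    runs are counted at their start voxels.  Runs truncate at the ROI
    boundary (level 0).
    """
    shape = levels.shape
    run = (levels > 0).astype(np.int32)
    a = next(ax for ax in range(3) if off[ax] != 0)
    s = off[a]
    other_src = [slice(None)] * 3
    other_nb = [slice(None)] * 3
    for ax in range(3):
        if ax == a:
            continue
        dd = off[ax]
        if dd == 1:
            other_src[ax] = slice(0, shape[ax] - 1)
            other_nb[ax] = slice(1, shape[ax])
        elif dd == -1:
            other_src[ax] = slice(1, shape[ax])
            other_nb[ax] = slice(0, shape[ax] - 1)

    order = range(shape[a] - 2, -1, -1) if s > 0 else range(1, shape[a])
    for idx in order:
        ssl = list(other_src)
        nsl = list(other_nb)
        ssl[a] = idx
        nsl[a] = idx + s
        ssl, nsl = tuple(ssl), tuple(nsl)
        cur = levels[ssl]
        nxt = levels[nsl]
        same = (cur > 0) & (cur == nxt)
        run[ssl] = np.where(same, run[nsl] + 1, run[ssl])

    # a run starts where the predecessor (v - off) is absent or differs
    start = levels > 0
    src, dst = _shift_pairs(shape, off)
    cont = np.zeros(shape, dtype=bool)
    cont[dst] = (levels[dst] > 0) & (levels[dst] == levels[src])
    start &= ~cont

    lev_s = levels[start]
    run_s = run[start]
    if lev_s.size == 0:
        return np.zeros((Ng, 1))
    max_run = int(run_s.max())
    mat = np.bincount(
        (lev_s.astype(np.int64) - 1) * max_run + (run_s - 1), minlength=Ng * max_run
    ).reshape(Ng, max_run)
    return mat.astype(float)


def _glrlm_features_single(P: np.ndarray, Np: int) -> dict[str, float]:
    Nr = P.sum()
    p = P / Nr
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ii = i[:, None]
    jj = j[None, :]

    out: dict[str, float] = {}
    out["ShortRunEmphasis"] = float((p / jj**2).sum())
    out["LongRunEmphasis"] = float((p * jj**2).sum())
    out["GrayLevelNonUniformity"] = float((P.sum(axis=1) ** 2).sum() / Nr)
    out["GrayLevelNonUniformityNormalized"] = float((pi**2).sum())
    out["RunLengthNonUniformity"] = float((P.sum(axis=0) ** 2).sum() / Nr)
    out["RunLengthNonUniformityNormalized"] = float((pj**2).sum())
    out["RunPercentage"] = float(Nr / Np)
    mu_i = float((pi * i).sum())
    mu_j = float((pj * j).sum())
    out["GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    out["RunVariance"] = float((p * (jj - mu_j) ** 2).sum())
    nz = p > 0
    out["RunEntropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["LowGrayLevelRunEmphasis"] = float((p / ii**2).sum())
    out["HighGrayLevelRunEmphasis"] = float((p * ii**2).sum())
    out["ShortRunLowGrayLevelEmphasis"] = float((p / (ii**2 * jj**2)).sum())
    out["ShortRunHighGrayLevelEmphasis"] = float((p * ii**2 / jj**2).sum())
    out["LongRunLowGrayLevelEmphasis"] = float((p * jj**2 / ii**2).sum())
    out["LongRunHighGrayLevelEmphasis"] = float((p * ii**2 * jj**2).sum())
    return out


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 gray-level run-length features, averaged over 13 directions.

    Includes short-run low-gray-level emphasis
    SRLGLE = sum P(i,j) / (i^2 j^2) normalized by the run count.
    """
    Np = d.voxel_count
    if Np == 0:
        warnings.warn("empty ROI; GLRLM features undefined")
        return _nan_dict(GLRLM_NAMES)
    per_dir = []
    for off in OFFSETS_13:
        P = _run_matrix(d.levels, d.Ng, off)
        if P.sum() > 0:
            per_dir.append(_glrlm_features_single(P, Np))
    if not per_dir:
        return _nan_dict(GLRLM_NAMES)
    return {n: float(np.mean([f[n] for f in per_dir])) for n in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _zone_list(levels: np.ndarray, Ng: int) -> list[tuple[int, int]]:
    """(level, zone size) pairs over 26-connected equal-level components."""
    zones: list[tuple[int, int]] = []
    for g in range(1, Ng + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    return zones


def _szm_features_single(P: np.ndarray, Np: int) -> dict[str, float]:
    Nz = P.sum()
    p = P / Nz
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ii = i[:, None]
    jj = j[None, :]

    out: dict[str, float] = {}
    out["SmallAreaEmphasis"] = float((p / jj**2).sum())
    out["LargeAreaEmphasis"] = float((p * jj**2).sum())
    out["GrayLevelNonUniformity"] = float((P.sum(axis=1) ** 2).sum() / Nz)
    out["GrayLevelNonUniformityNormalized"] = float((pi**2).sum())
    out["SizeZoneNonUniformity"] = float((P.sum(axis=0) ** 2).sum() / Nz)
    out["SizeZoneNonUniformityNormalized"] = float((pj**2).sum())
    out["ZonePercentage"] = float(Nz / Np)
    mu_i = float((pi * i).sum())
    mu_j = float((pj * j).sum())
    out["GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    out["ZoneVariance"] = float((p * (jj - mu_j) ** 2).sum())
    nz = p > 0
    out["ZoneEntropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["LowGrayLevelZoneEmphasis"] = float((p / ii**2).sum())
    out["HighGrayLevelZoneEmphasis"] = float((p * ii**2).sum())
    out["SmallAreaLowGrayLevelEmphasis"] = float((p / (ii**2 * jj**2)).sum())
    out["SmallAreaHighGrayLevelEmphasis"] = float((p * ii**2 / jj**2).sum())
    out["LargeAreaLowGrayLevelEmphasis"] = float((p * jj**2 / ii**2).sum())
    out["LargeAreaHighGrayLevelEmphasis"] = float((p * ii**2 * jj**2).sum())
    return out


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 gray-level size-zone features over 26-connected zones.

    Includes low-gray-level zone emphasis LGLZE = sum P(i,j) / i^2 over
    the normalized size-zone matrix.
    """
    Np = d.voxel_count
    if Np == 0:
        warnings.warn("empty ROI; GLSZM features undefined")
        return _nan_dict(GLSZM_NAMES)
    zones = _zone_list(d.levels, d.Ng)
    max_size = max(s for _, s in zones)
    P = np.zeros((d.Ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return _szm_features_single(P, Np)


# ---------------------------------------------------------------------------
# GLDM


def _dependence_counts(levels: np.ndarray, alpha: float) -> np.ndarray:
    """dependence j = 1 + number of 26-neighbours with |level diff| <= alpha."""
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in OFFSETS_13:
        src, dst = _shift_pairs(levels.shape, off)
        a = levels[src]
        b = levels[dst]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[src] += ok
        dep[dst] += ok
    dep[levels > 0] += 1
    dep[levels == 0] = 0
    return dep


def _gldm_features_single(P: np.ndarray) -> dict[str, float]:
    Nz = P.sum()
    p = P / Nz
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ii = i[:, None]
    jj = j[None, :]

    out: dict[str, float] = {}
    out["SmallDependenceEmphasis"] = float((p / jj**2).sum())
    out["LargeDependenceEmphasis"] = float((p * jj**2).sum())
    out["GrayLevelNonUniformity"] = float((P.sum(axis=1) ** 2).sum() / Nz)
    out["DependenceNonUniformity"] = float((P.sum(axis=0) ** 2).sum() / Nz)
    out["DependenceNonUniformityNormalized"] = float((pj**2).sum())
    mu_i = float((pi * i).sum())
    mu_j = float((pj * j).sum())
    out["GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    out["DependenceVariance"] = float((p * (jj - mu_j) ** 2).sum())
    nz = p > 0
    out["DependenceEntropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["LowGrayLevelEmphasis"] = float((p / ii**2).sum())
    out["HighGrayLevelEmphasis"] = float((p * ii**2).sum())
    out["SmallDependenceLowGrayLevelEmphasis"] = float((p / (ii**2 * jj**2)).sum())
    out["SmallDependenceHighGrayLevelEmphasis"] = float((p * ii**2 / jj**2).sum())
    out["LargeDependenceLowGrayLevelEmphasis"] = float((p * jj**2 / ii**2).sum())
    out["LargeDependenceHighGrayLevelEmphasis"] = float((p * ii**2 * jj**2).sum())
    return out


def gldm_features(d: DiscretizedROI, alpha: float = 0.0) -> dict[str, float]:
    """14 gray-level dependence features (26-connectivity, threshold alpha).

    Includes small-dependence low-gray-level emphasis
    SDLGLE = sum P(i,j) / (i^2 j^2) over the normalized dependence matrix.
    """
    if d.voxel_count == 0:
        warnings.warn("empty ROI; GLDM features undefined")
        return _nan_dict(GLDM_NAMES)
    dep = _dependence_counts(d.levels, alpha)
    inside = d.levels > 0
    lev = d.levels[inside]
    dj = dep[inside]
    max_dep = int(dj.max())
    P = np.bincount(
        (lev.astype(np.int64) - 1) * max_dep + (dj - 1), minlength=d.Ng * max_dep
    ).reshape(d.Ng, max_dep).astype(float)
    return _gldm_features_single(P)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features.

    For each gray level i: n_i voxels, p_i = n_i / Nvp, and
    s_i = sum over those voxels of |i - A_v| where A_v is the mean level of
    the voxel's in-ROI 26-neighbours.  Voxels with no in-ROI neighbour are
    excluded.  A constant ROI yields Contrast = Busyness = 0 by convention.
    """
    if d.voxel_count == 0:
        warnings.warn("empty ROI; NGTDM features undefined")
        return _nan_dict(NGTDM_NAMES)
    levels = d.levels
    inside = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.correlate(levels.astype(float) * inside, kernel, mode="constant")
    nbr_cnt = ndimage.correlate(inside.astype(float), kernel, mode="constant")
    valid = inside & (nbr_cnt > 0)
    if not valid.any():
        warnings.warn("no voxel has an in-ROI neighbour; NGTDM features undefined")
        return _nan_dict(NGTDM_NAMES)

    A = nbr_sum[valid] / nbr_cnt[valid]
    lev = levels[valid].astype(float)
    Nvp = int(valid.sum())
    Ng = d.Ng
    n_i = np.bincount(levels[valid] - 1, minlength=Ng).astype(float)
    s_i = np.zeros(Ng)
    np.add.at(s_i, levels[valid] - 1, np.abs(lev - A))
    p_i = n_i / Nvp

    present = p_i > 0
    Ngp = int(present.sum())
    i = np.arange(1, Ng + 1, dtype=float)

    out: dict[str, float] = {}
    denom = float((p_i * s_i).sum())
    out["Coarseness"] = float(1.0 / denom) if denom > 0 else 1e6

    if Ngp <= 1:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
    else:
        pp = np.outer(p_i, p_i)
        dd2 = (i[:, None] - i[None, :]) ** 2
        out["Contrast"] = float(
            (pp * dd2).sum() / (Ngp * (Ngp - 1)) * (s_i.sum() / Nvp)
        )
        ipi = i * p_i
        bden = float(
            np.abs(ipi[present][:, None] - ipi[present][None, :]).sum()
        )
        out["Busyness"] = float(denom / bden) if bden > 0 else 0.0

    comp = 0.0
    stren = 0.0
    idx = np.where(present)[0]
    for ai in idx:
        for bi in idx:
            comp += (
                abs(i[ai] - i[bi])
                * (p_i[ai] * s_i[ai] + p_i[bi] * s_i[bi])
                / (p_i[ai] + p_i[bi])
            )
            stren += (p_i[ai] + p_i[bi]) * (i[ai] - i[bi]) ** 2
    out["Complexity"] = float(comp / Nvp)
    s_tot = float(s_i.sum())
    out["Strength"] = float(stren / s_tot) if s_tot > 0 else 0.0
    return out
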