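"""Independent brute-force oracles for texture matrices, EDT and region
growing.  Everything here is written as plain nested loops over voxels,
pairs, runs and zones, deliberately avoiding the vectorized code paths of
the package under test."""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def _in_bounds(v, shape):
    return all(0 <= c < n for c, n in zip(v, shape))


def _iter_voxels(shape):
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                yield (i, j, k)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix_oracle(levels, Ng, off):
    shape = levels.shape
    P = np.zeros((Ng, Ng))
    for v in _iter_voxels(shape):
        a = levels[v]
        if a == 0:
            continue
        u = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        if not _in_bounds(u, shape):
            continue
        b = levels[u]
        if b == 0:
            continue
        P[a - 1, b - 1] += 1
        P[b - 1, a - 1] += 1
    return P


def _glcm_feats_oracle(P, Ng):
    p = P / P.sum()
    i_idx = list(range(1, Ng + 1))
    px = [sum(p[i - 1, j - 1] for j in i_idx) for i in i_idx]
    py = [sum(p[i - 1, j - 1] for i in i_idx) for j in i_idx]
    ux = sum(px[i - 1] * i for i in i_idx)
    uy = sum(py[j - 1] * j for j in i_idx)
    sx = math.sqrt(sum(px[i - 1] * (i - ux) ** 2 for i in i_idx))
    sy = math.sqrt(sum(py[j - 1] * (j - uy) ** 2 for j in i_idx))

    pdiff = [0.0] * Ng
    psum = [0.0] * (2 * Ng - 1)
    for i in i_idx:
        for j in i_idx:
            pdiff[abs(i - j)] += p[i - 1, j - 1]
            psum[i + j - 2] += p[i - 1, j - 1]

    f = {}
    f["Autocorrelation"] = sum(p[i - 1, j - 1] * i * j for i in i_idx for j in i_idx)
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum(p[i - 1, j - 1] * (i + j - ux - uy) ** power for i in i_idx for j in i_idx)
    f["Contrast"] = sum(p[i - 1, j - 1] * (i - j) ** 2 for i in i_idx for j in i_idx)
    if sx > 0 and sy > 0:
        f["Correlation"] = (f["Autocorrelation"] - ux * uy) / (sx * sy)
    else:
        f["Correlation"] = 1.0
    da = sum(pdiff[k] * k for k in range(Ng))
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(q * math.log2(q) for q in pdiff if q > 0)
    f["DifferenceVariance"] = sum(pdiff[k] * (k - da) ** 2 for k in range(Ng))
    f["Id"] = sum(p[i - 1, j - 1] / (1 + abs(i - j)) for i in i_idx for j in i_idx)
    f["Idm"] = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in i_idx for j in i_idx)
    f["Idmn"] = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2 / Ng**2) for i in i_idx for j in i_idx)
    f["Idn"] = sum(p[i - 1, j - 1] / (1 + abs(i - j) / Ng) for i in i_idx for j in i_idx)
    hxy = -sum(p[i - 1, j - 1] * math.log2(p[i - 1, j - 1])
               for i in i_idx for j in i_idx if p[i - 1, j - 1] > 0)
    hxy1 = -sum(p[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
                for i in i_idx for j in i_idx
                if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = -sum(px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
                for i in i_idx for j in i_idx if px[i - 1] * py[j - 1] > 0)
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hy = -sum(q * math.log2(q) for q in py if q > 0)
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0))
    f["InverseVariance"] = sum(p[i - 1, j - 1] / (i - j) ** 2
                               for i in i_idx for j in i_idx if i != j)
    f["JointAverage"] = ux
    f["JointEnergy"] = sum(p[i - 1, j - 1] ** 2 for i in i_idx for j in i_idx)
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = max(p[i - 1, j - 1] for i in i_idx for j in i_idx)
    f["SumAverage"] = sum(psum[s - 2] * s for s in range(2, 2 * Ng + 1))
    f["SumEntropy"] = -sum(q * math.log2(q) for q in psum if q > 0)
    f["SumSquares"] = sum(p[i - 1, j - 1] * (i - ux) ** 2 for i in i_idx for j in i_idx)
    if Ng == 1:
        f["MCC"] = 1.0
    else:
        Q = np.zeros((Ng, Ng))
        for i in i_idx:
            for j in i_idx:
                s = 0.0
                for k in i_idx:
                    den = px[i - 1] * py[k - 1]
                    if den > 0:
                        s += p[i - 1, k - 1] * p[j - 1, k - 1] / den
                Q[i - 1, j - 1] = s
        eig = sorted(abs(np.linalg.eigvals(Q)))
        f["MCC"] = math.sqrt(max(eig[-2], 0.0)) if len(eig) >= 2 else 1.0
    return f


def glcm_oracle(levels, Ng):
    per_dir = []
    for off in OFFSETS_13:
        P = _glcm_matrix_oracle(levels, Ng, off)
        if P.sum() > 0:
            per_dir.append(_glcm_feats_oracle(P, Ng))
    if not per_dir:
        return None
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_oracle(levels, off):
    """(level, length) of every maximal run along direction off."""
    shape = levels.shape
    runs = []
    for v in _iter_voxels(shape):
        lev = levels[v]
        if lev == 0:
            continue
        prev = (v[0] - off[0], v[1] - off[1], v[2] - off[2])
        if _in_bounds(prev, shape) and levels[prev] == lev:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if _in_bounds(nxt, shape) and levels[nxt] == lev:
                length += 1
                cur = nxt
            else:
                break
        runs.append((lev, length))
    return runs


def _rlm_style_feats(pairs, Np, prefix):
    """Shared run/zone feature formulas from (level, size) pairs."""
    N = len(pairs)
    total = float(N)
    lev_counts = {}
    size_counts = {}
    for g, s in pairs:
        lev_counts[g] = lev_counts.get(g, 0) + 1
        size_counts[s] = size_counts.get(s, 0) + 1
    mu_i = sum(g for g, _ in pairs) / total
    mu_j = sum(s for _, s in pairs) / total
    f = {}
    f[f"Short{prefix}Emphasis"] = sum(1.0 / s**2 for _, s in pairs) / total
    f[f"Long{prefix}Emphasis"] = sum(float(s**2) for _, s in pairs) / total
    f["GrayLevelNonUniformity"] = sum(c**2 for c in lev_counts.values()) / total
    f["GrayLevelNonUniformityNormalized"] = sum(c**2 for c in lev_counts.values()) / total**2
    f[f"{prefix}NonUniformity"] = sum(c**2 for c in size_counts.values()) / total
    f[f"{prefix}NonUniformityNormalized"] = sum(c**2 for c in size_counts.values()) / total**2
    f["Percentage"] = total / Np
    f["GrayLevelVariance"] = sum((g - mu_i) ** 2 for g, _ in pairs) / total
    f[f"{prefix}Variance"] = sum((s - mu_j) ** 2 for _, s in pairs) / total
    cell_counts = {}
    for pair in pairs:
        cell_counts[pair] = cell_counts.get(pair, 0) + 1
    f["Entropy"] = -sum((c / total) * math.log2(c / total) for c in cell_counts.values())
    f["LowGrayLevelEmphasis"] = sum(1.0 / g**2 for g, _ in pairs) / total
    f["HighGrayLevelEmphasis"] = sum(float(g**2) for g, _ in pairs) / total
    f["ShortLow"] = sum(1.0 / (g**2 * s**2) for g, s in pairs) / total
    f["ShortHigh"] = sum(g**2 / s**2 for g, s in pairs) / total
    f["LongLow"] = sum(s**2 / g**2 for g, s in pairs) / total
    f["LongHigh"] = sum(float(g**2 * s**2) for g, s in pairs) / total
    return f


def glrlm_oracle(levels):
    Np = int((levels > 0).sum())
    per_dir = []
    for off in OFFSETS_13:
        runs = _runs_oracle(levels, off)
        if runs:
            g = _rlm_style_feats(runs, Np, "Run")
            per_dir.append({
                "ShortRunEmphasis": g["ShortRunEmphasis"],
                "LongRunEmphasis": g["LongRunEmphasis"],
                "GrayLevelNonUniformity": g["GrayLevelNonUniformity"],
                "GrayLevelNonUniformityNormalized": g["GrayLevelNonUniformityNormalized"],
                "RunLengthNonUniformity": g["RunNonUniformity"],
                "RunLengthNonUniformityNormalized": g["RunNonUniformityNormalized"],
                "RunPercentage": g["Percentage"],
                "GrayLevelVariance": g["GrayLevelVariance"],
                "RunVariance": g["RunVariance"],
                "RunEntropy": g["Entropy"],
                "LowGrayLevelRunEmphasis": g["LowGrayLevelEmphasis"],
                "HighGrayLevelRunEmphasis": g["HighGrayLevelEmphasis"],
                "ShortRunLowGrayLevelEmphasis": g["ShortLow"],
                "ShortRunHighGrayLevelEmphasis": g["ShortHigh"],
                "LongRunLowGrayLevelEmphasis": g["LongLow"],
                "LongRunHighGrayLevelEmphasis": g["LongHigh"],
            })
    if not per_dir:
        return None
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def _zones_oracle(levels):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in _iter_voxels(shape):
        if levels[v] == 0 or seen[v]:
            continue
        lev = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        u = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                        if _in_bounds(u, shape) and not seen[u] and levels[u] == lev:
                            seen[u] = True
                            stack.append(u)
        zones.append((lev, size))
    return zones


def glszm_oracle(levels):
    Np = int((levels > 0).sum())
    zones = _zones_oracle(levels)
    if not zones:
        return None
    g = _rlm_style_feats(zones, Np, "Zone")
    return {
        "SmallAreaEmphasis": g["ShortZoneEmphasis"],
        "LargeAreaEmphasis": g["LongZoneEmphasis"],
        "GrayLevelNonUniformity": g["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": g["GrayLevelNonUniformityNormalized"],
        "SizeZoneNonUniformity": g["ZoneNonUniformity"],
        "SizeZoneNonUniformityNormalized": g["ZoneNonUniformityNormalized"],
        "ZonePercentage": g["Percentage"],
        "GrayLevelVariance": g["GrayLevelVariance"],
        "ZoneVariance": g["ZoneVariance"],
        "ZoneEntropy": g["Entropy"],
        "LowGrayLevelZoneEmphasis": g["LowGrayLevelEmphasis"],
        "HighGrayLevelZoneEmphasis": g["HighGrayLevelEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": g["ShortLow"],
        "SmallAreaHighGrayLevelEmphasis": g["ShortHigh"],
        "LargeAreaLowGrayLevelEmphasis": g["LongLow"],
        "LargeAreaHighGrayLevelEmphasis": g["LongHigh"],
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_pairs_oracle(levels, alpha=0.0):
    shape = levels.shape
    pairs = []
    for v in _iter_voxels(shape):
        lev = levels[v]
        if lev == 0:
            continue
        dep = 1
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    u = (v[0] + di, v[1] + dj, v[2] + dk)
                    if _in_bounds(u, shape) and levels[u] > 0 and abs(int(levels[u]) - int(lev)) <= alpha:
                        dep += 1
        pairs.append((lev, dep))
    return pairs


def gldm_oracle(levels, alpha=0.0):
    pairs = gldm_pairs_oracle(levels, alpha)
    if not pairs:
        return None
    g = _rlm_style_feats(pairs, len(pairs), "Dependence")
    return {
        "SmallDependenceEmphasis": g["ShortDependenceEmphasis"],
        "LargeDependenceEmphasis": g["LongDependenceEmphasis"],
        "GrayLevelNonUniformity": g["GrayLevelNonUniformity"],
        "DependenceNonUniformity": g["DependenceNonUniformity"],
        "DependenceNonUniformityNormalized": g["DependenceNonUniformityNormalized"],
        "GrayLevelVariance": g["GrayLevelVariance"],
        "DependenceVariance": g["DependenceVariance"],
        "DependenceEntropy": g["Entropy"],
        "LowGrayLevelEmphasis": g["LowGrayLevelEmphasis"],
        "HighGrayLevelEmphasis": g["HighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": g["ShortLow"],
        "SmallDependenceHighGrayLevelEmphasis": g["ShortHigh"],
        "LargeDependenceLowGrayLevelEmphasis": g["LongLow"],
        "LargeDependenceHighGrayLevelEmphasis": g["LongHigh"],
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_oracle(levels, Ng):
    shape = levels.shape
    n_i = [0.0] * Ng
    s_i = [0.0] * Ng
    Nvp = 0
    for v in _iter_voxels(shape):
        lev = levels[v]
        if lev == 0:
            continue
        nbr = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    u = (v[0] + di, v[1] + dj, v[2] + dk)
                    if _in_bounds(u, shape) and levels[u] > 0:
                        nbr.append(int(levels[u]))
        if not nbr:
            continue
        Nvp += 1
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - sum(nbr) / len(nbr))
    if Nvp == 0:
        return None
    p_i = [n / Nvp for n in n_i]
    present = [i for i in range(Ng) if p_i[i] > 0]
    Ngp = len(present)
    f = {}
    denom = sum(p_i[i] * s_i[i] for i in range(Ng))
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if Ngp <= 1:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
    else:
        c = sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in range(Ng) for j in range(Ng))
        f["Contrast"] = c / (Ngp * (Ngp - 1)) * (sum(s_i) / Nvp)
        b = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in present for j in present)
        f["Busyness"] = denom / b if b > 0 else 0.0
    comp = 0.0
    stren = 0.0
    for i in present:
        for j in present:
            comp += abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
            stren += (p_i[i] + p_i[j]) * (i - j) ** 2
    f["Complexity"] = comp / Nvp
    f["Strength"] = stren / sum(s_i) if sum(s_i) > 0 else 0.0
    return f


# ---------------------------------------------------------------------------
# EDT and flood fill


def brute_edt(mask):
    """EDT by scanning every background voxel (grid padded with background)."""
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    bg = np.argwhere(~padded)
    out = np.zeros(mask.shape)
    for v in np.argwhere(padded):
        d2 = ((bg - v) ** 2).sum(axis=1).min()
        out[tuple(v - 1)] = math.sqrt(d2)
    return out


def flood_fill_equal(arr, seed):
    """Connected component of voxels equal to the seed's value (6-conn)."""
    arr = np.asarray(arr)
    target = arr[seed]
    seen = np.zeros(arr.shape, dtype=bool)
    stack = [tuple(seed)]
    seen[tuple(seed)] = True
    while stack:
        v = stack.pop()
        for off in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]:
            u = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(u, arr.shape) and not seen[u] and arr[u] == target:
                seen[u] = True
                stack.append(u)
    return seen
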