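"""Independent brute-force oracles for the texture-matrix families.

Everything here is written as plain nested loops over pixels and matrix
cells, deliberately sharing no code with the package implementation:
pair enumeration for co-occurrence, a linear run scanner for run
lengths, flood fill for size zones, per-pixel neighbourhood means for
NGTDM and a direct dependence counter for GLDM.
"""

import math

import numpy as np

EPS = np.spacing(1.0)

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def glcm_matrix_oracle(levels, mask, n_bins, direction):
    h, w = levels.shape
    di, dj = direction
    counts = np.zeros((n_bins, n_bins))
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for s in (1, -1):
                ni, nj = i + s * di, j + s * dj
                if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                    counts[levels[i, j] - 1, levels[ni, nj] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_features_oracle(P):
    n = P.shape[0]
    feats = {}
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum(((i + 1) - mu) ** 2 * px[i] for i in range(n))
    sigma = math.sqrt(var)

    p_diff = [0.0] * n
    p_sum = [0.0] * (2 * n - 1)
    for i in range(n):
        for j in range(n):
            p_diff[abs(i - j)] += P[i][j]
            p_sum[i + j] += P[i][j]
    da = sum(k * p_diff[k] for k in range(n))

    feats["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(n) for j in range(n)
    )
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)):
        feats[name] = sum(
            ((i + 1) + (j + 1) - 2 * mu) ** power * P[i][j]
            for i in range(n)
            for j in range(n)
        )
    feats["Contrast"] = sum(
        (i - j) ** 2 * P[i][j] for i in range(n) for j in range(n)
    )
    if sigma > 1e-12:
        feats["Correlation"] = (feats["Autocorrelation"] - mu * mu) / (sigma * sigma)
    else:
        feats["Correlation"] = 1.0
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = -sum(
        p * math.log2(p + EPS) for p in p_diff if p > 0
    )
    feats["DifferenceVariance"] = sum(
        (k - da) ** 2 * p_diff[k] for k in range(n)
    )
    feats["Id"] = sum(P[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    feats["Idm"] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    feats["Idmn"] = sum(
        P[i][j] / (1 + ((i - j) / n) ** 2) for i in range(n) for j in range(n)
    )
    feats["Idn"] = sum(
        P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
    )
    hxy = -sum(P[i][j] * math.log2(P[i][j] + EPS) for i in range(n) for j in range(n) if P[i][j] > 0)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * px[j] + EPS) for i in range(n) for j in range(n)
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j] + EPS) for i in range(n) for j in range(n)
    )
    hx = -sum(p * math.log2(p + EPS) for p in px if p > 0)
    feats["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1 - math.exp(-2 * (hxy2 - hxy))
    feats["Imc2"] = math.sqrt(arg) if arg > 0 else 0.0
    feats["InverseVariance"] = sum(
        P[i][j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
    )
    feats["JointAverage"] = mu
    feats["JointEnergy"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    feats["JointEntropy"] = hxy
    present = [i for i in range(n) if px[i] > 0]
    if len(present) > 1:
        m = len(present)
        Q = np.zeros((m, m))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a][b] = sum(
                    P[i][k] * P[j][k] / (px[i] * px[k]) for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        feats["MCC"] = math.sqrt(max(eig[-2], 0.0))
    else:
        feats["MCC"] = 1.0
    feats["MaximumProbability"] = max(P[i][j] for i in range(n) for j in range(n))
    feats["SumEntropy"] = -sum(p * math.log2(p + EPS) for p in p_sum if p > 0)
    feats["SumSquares"] = sum(
        ((i + 1) - mu) ** 2 * P[i][j] for i in range(n) for j in range(n)
    )
    return feats


def _lines_for_direction(levels, direction):
    h, w = levels.shape
    di, dj = direction
    lines = []
    if direction == (0, 1):
        starts = [(i, 0) for i in range(h)]
    elif direction == (1, 0):
        starts = [(0, j) for j in range(w)]
    elif direction == (1, 1):
        starts = [(i, 0) for i in range(h)] + [(0, j) for j in range(1, w)]
    elif direction == (1, -1):
        starts = [(0, j) for j in range(w)] + [(i, w - 1) for i in range(1, h)]
    else:
        raise ValueError(direction)
    for i0, j0 in starts:
        line = []
        i, j = i0, j0
        while 0 <= i < h and 0 <= j < w:
            line.append(levels[i, j])
            i, j = i + di, j + dj
        lines.append(line)
    return lines


def glrlm_matrix_oracle(levels, mask, n_bins, direction):
    lm = np.where(mask, levels, 0)
    h, w = lm.shape
    R = np.zeros((n_bins, max(h, w)))
    for line in _lines_for_direction(lm, direction):
        k = 0
        while k < len(line):
            if line[k] == 0:
                k += 1
                continue
            length = 1
            while k + length < len(line) and line[k + length] == line[k]:
                length += 1
            R[line[k] - 1, length - 1] += 1
            k += length
    return R


def glszm_matrix_oracle(levels, mask, n_bins):
    lm = np.where(mask, levels, 0)
    h, w = lm.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for i in range(h):
        for j in range(w):
            if lm[i, j] == 0 or seen[i, j]:
                continue
            # flood fill, 8-connected
            stack, size, lv = [(i, j)], 0, lm[i, j]
            seen[i, j] = True
            while stack:
                ci, cj = stack.pop()
                size += 1
                for di, dj in NEIGHBOURS_8:
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < h and 0 <= nj < w and not seen[ni, nj] and lm[ni, nj] == lv:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            zones.append((lv, size))
    max_size = max(s for _, s in zones)
    Z = np.zeros((n_bins, max_size))
    for lv, s in zones:
        Z[lv - 1, s - 1] += 1
    return Z


def size_matrix_features_oracle(M, n_pix):
    """Loop-based run-length/size-zone/dependence feature formulas."""
    ng, ns = M.shape
    Nz = M.sum()
    feats = {}
    pg = [sum(M[i][j] for j in range(ns)) for i in range(ng)]
    ps = [sum(M[i][j] for i in range(ng)) for j in range(ns)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / Nz
    mu_j = sum((j + 1) * ps[j] for j in range(ns)) / Nz
    feats["SmallEmphasis"] = sum(
        M[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["LargeEmphasis"] = sum(
        M[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["GrayLevelNonUniformity"] = sum(g**2 for g in pg) / Nz
    feats["GrayLevelNonUniformityNormalized"] = sum(g**2 for g in pg) / Nz**2
    feats["SizeNonUniformity"] = sum(s**2 for s in ps) / Nz
    feats["SizeNonUniformityNormalized"] = sum(s**2 for s in ps) / Nz**2
    feats["Percentage"] = Nz / n_pix
    feats["GrayLevelVariance"] = sum(
        ((i + 1) - mu_i) ** 2 * M[i][j] / Nz for i in range(ng) for j in range(ns)
    )
    feats["SizeVariance"] = sum(
        ((j + 1) - mu_j) ** 2 * M[i][j] / Nz for i in range(ng) for j in range(ns)
    )
    feats["Entropy"] = -sum(
        (M[i][j] / Nz) * math.log2(M[i][j] / Nz + EPS)
        for i in range(ng)
        for j in range(ns)
        if M[i][j] > 0
    )
    feats["LowGrayLevelEmphasis"] = sum(
        M[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["HighGrayLevelEmphasis"] = sum(
        M[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["SmallLowGrayLevelEmphasis"] = sum(
        M[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)
    ) / Nz
    feats["SmallHighGrayLevelEmphasis"] = sum(
        M[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["LargeLowGrayLevelEmphasis"] = sum(
        M[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    feats["LargeHighGrayLevelEmphasis"] = sum(
        M[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / Nz
    return feats


def ngtdm_oracle(levels, mask, n_bins):
    h, w = levels.shape
    s = np.zeros(n_bins)
    n = np.zeros(n_bins)
    nvp = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            nb = [
                levels[i + di, j + dj]
                for di, dj in NEIGHBOURS_8
                if 0 <= i + di < h and 0 <= j + dj < w and mask[i + di, j + dj]
            ]
            if not nb:
                continue
            nvp += 1
            lv = levels[i, j]
            s[lv - 1] += abs(lv - sum(nb) / len(nb))
            n[lv - 1] += 1
    return s, n, nvp


def ngtdm_features_oracle(s, n, nvp, n_bins):
    p = n / nvp
    present = [i for i in range(n_bins) if p[i] > 0]
    ngp = len(present)
    sum_ps = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * ((i + 1) - (j + 1)) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
        ) * (sum(s[i] for i in present) / nvp)
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs((i + 1) - (j + 1))
                * (p[i] * s[i] + p[j] * s[j])
                / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nvp
        )
        s_sum = sum(s[i] for i in present)
        strength = (
            sum((p[i] + p[j]) * ((i + 1) - (j + 1)) ** 2 for i in present for j in present)
            / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def gldm_matrix_oracle(levels, mask, n_bins, alpha=0):
    h, w = levels.shape
    D = np.zeros((n_bins, 9))
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            dep = 0
            for di, dj in NEIGHBOURS_8:
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < h
                    and 0 <= nj < w
                    and mask[ni, nj]
                    and abs(int(levels[i, j]) - int(levels[ni, nj])) <= alpha
                ):
                    dep += 1
            D[levels[i, j] - 1, dep] += 1  # dependence size = dep + 1 (center)
    return D


_GLRLM_KEYS = {
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_KEYS = {
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_KEYS = {
    "SmallEmphasis": "SmallDependenceEmphasis",
    "LargeEmphasis": "LargeDependenceEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "SizeNonUniformity": "DependenceNonUniformity",
    "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "DependenceVariance",
    "Entropy": "DependenceEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
}
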