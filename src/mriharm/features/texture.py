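"""Gray-level texture-matrix features on 2D discretized ROIs.

Five matrix families: co-occurrence (GLCM), run length (GLRLM), size
zone (GLSZM), neighbouring gray tone difference (NGTDM) and dependence
(GLDM).  Matrices are built in-plane at pixel distance 1; GLCM and GLRLM
are computed per direction over the four 2D directions and the features
averaged with equal weights.  Zones and dependences use 8-connectivity.

Degenerate-ROI conventions (flat region, single gray level) follow the
reference extractor: GLCM Correlation -> 1, MCC -> 1, Imc1/Imc2 -> 0,
NGTDM Contrast -> 0, Coarseness -> 1e6 sentinel, Busyness/Strength -> 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_2D",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_matrix",
    "gldm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

_EPS = np.spacing(1.0)
DIRECTIONS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))
COARSENESS_SENTINEL = 1e6

_NEIGHBOUR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)


def _shifted_pairs(levels: np.ndarray, di: int, dj: int):
    """Aligned (center, neighbour) level views for one offset; 0 = outside."""
    h, w = levels.shape
    i0, i1 = max(0, -di), min(h, h - di)
    j0, j1 = max(0, -dj), min(w, w - dj)
    a = levels[i0:i1, j0:j1]
    b = levels[i0 + di : i1 + di, j0 + dj : j1 + dj]
    return a, b


# ---------------------------------------------------------------------------
# matrix builders


def glcm_matrix(disc: DiscretizedROI, direction: tuple[int, int], distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction."""
    n = disc.n_bins
    di, dj = direction[0] * distance, direction[1] * distance
    a, b = _shifted_pairs(disc.levels, di, dj)
    valid = (a > 0) & (b > 0)
    counts = np.zeros((n, n))
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pair for GLCM")
    return counts / total


def glrlm_matrix(disc: DiscretizedROI, direction: tuple[int, int]) -> np.ndarray:
    """Run-length matrix R(level, run length) for one direction."""
    levels = disc.levels
    h, w = levels.shape
    if direction == (0, 1):
        lines = [levels[i, :] for i in range(h)]
    elif direction == (1, 0):
        lines = [levels[:, j] for j in range(w)]
    elif direction == (1, 1):
        lines = [np.diagonal(levels, offset=o) for o in range(-h + 1, w)]
    elif direction == (1, -1):
        flipped = levels[:, ::-1]
        lines = [np.diagonal(flipped, offset=o) for o in range(-h + 1, w)]
    else:
        raise ValueError(f"unsupported direction {direction}")

    max_len = max(h, w)
    R = np.zeros((disc.n_bins, max_len))
    for line in lines:
        run_level, run_len = 0, 0
        for lv in line:
            if lv == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = int(lv), 1
        if run_level > 0:
            R[run_level - 1, run_len - 1] += 1
    return R


def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix Z(level, zone size); zones are 8-connected."""
    structure = np.ones((3, 3), dtype=int)
    n_pix = int(disc.mask.sum())
    sizes: list[tuple[int, int]] = []
    for lv in np.unique(disc.levels[disc.mask]):
        labelled, n_zones = ndimage.label(disc.levels == lv, structure=structure)
        for z in range(1, n_zones + 1):
            sizes.append((int(lv), int((labelled == z).sum())))
    max_size = max(s for _, s in sizes)
    Z = np.zeros((disc.n_bins, max(max_size, 1)))
    for lv, s in sizes:
        Z[lv - 1, s - 1] += 1
    assert sum(s for _, s in sizes) == n_pix
    return Z


def ngtdm_matrix(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (s_i, n_i) of the neighbourhood gray-tone difference.

    s_i sums |i - A(x)| over in-ROI pixels of level i, where A(x) is the
    mean level of the pixel's in-ROI 8-neighbours; n_i counts those
    pixels.  Returns (s, n, Nvp) with Nvp the number of valid pixels.
    """
    levels = disc.levels.astype(np.float64)
    mask = disc.mask
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(levels * mask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    s = np.zeros(disc.n_bins)
    n = np.zeros(disc.n_bins)
    lv = disc.levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(s, lv - 1, diff)
    np.add.at(n, lv - 1, 1.0)
    return s, n, int(valid.sum())


def gldm_matrix(disc: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix D(level, dependence size).

    A neighbour is *dependent* when |level - center level| <= alpha; the
    dependence size is 1 + the number of dependent in-ROI 8-neighbours
    (the center always depends on itself), so sizes run 1..9.
    """
    levels = disc.levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for di, dj in _NEIGHBOUR_OFFSETS:
        a, b = _shifted_pairs(levels, di, dj)
        contrib = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        h, w = levels.shape
        i0, i1 = max(0, -di), min(h, h - di)
        j0, j1 = max(0, -dj), min(w, w - dj)
        dep[i0:i1, j0:j1] += contrib
    D = np.zeros((disc.n_bins, 9))
    lv = levels[disc.mask]
    np.add.at(D, (lv - 1, dep[disc.mask]), 1.0)
    return D


# ---------------------------------------------------------------------------
# feature computations


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    # symmetric matrix: px == py, mu_x == mu_y
    mu = float((i * px).sum())
    sigma = float(np.sqrt((((i - mu) ** 2) * px).sum()))

    diff_k = np.arange(n, dtype=np.float64)  # |i-j| = 0..n-1
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), P.ravel())
    sum_k = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, P.ravel())

    da = float((diff_k * p_diff).sum())

    nzP = P[P > 0]
    hxy = float(-(nzP * np.log2(nzP + _EPS)).sum())
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-(P * np.log2(pxpy + _EPS)).sum())
        hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    nz_px = px[px > 0]
    hx = float(-(nz_px * np.log2(nz_px + _EPS)).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0

    if sigma > 1e-12:
        correlation = float(((I * J * P).sum() - mu * mu) / (sigma * sigma))
    else:
        correlation = 1.0

    # MCC: second largest eigenvalue of Q over the present gray levels
    # MCC: Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)), restricted to
    # present gray levels; sqrt of the second largest eigenvalue of Q.
    present = px > 0
    if present.sum() > 1:
        Pp = P[np.ix_(present, present)]
        pxp = px[present]
        Q = (Pp / pxp[:, None]) @ (Pp / pxp[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    idx_ne = I != J
    inv_var = float((P[idx_ne] / (I - J)[idx_ne] ** 2).sum())

    nz_sum = p_sum[p_sum > 0]
    nz_diff = p_diff[p_diff > 0]
    return {
        "Autocorrelation": float((I * J * P).sum()),
        "ClusterProminence": float((((I + J - 2 * mu) ** 4) * P).sum()),
        "ClusterShade": float((((I + J - 2 * mu) ** 3) * P).sum()),
        "ClusterTendency": float((((I + J - 2 * mu) ** 2) * P).sum()),
        "Contrast": float((((I - J) ** 2) * P).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(nz_diff * np.log2(nz_diff + _EPS)).sum()),
        "DifferenceVariance": float((((diff_k - da) ** 2) * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((I - J) / n) ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / n)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-(nz_sum * np.log2(nz_sum + _EPS)).sum()),
        "SumSquares": float((((I - mu) ** 2) * P).sum()),
    }


def glcm_features(disc: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """23 co-occurrence features, averaged over the four 2D directions."""
    per_dir = []
    for d in DIRECTIONS_2D:
        try:
            P = glcm_matrix(disc, d, distance)
        except ValueError:
            continue
        per_dir.append(_glcm_features_single(P))
    if not per_dir:
        raise ValueError("no valid pixel pair in any direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _size_weighted_features(M: np.ndarray, n_pix: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM feature form over a (level, size) matrix.

    ``prefix`` maps the generic keys to family-specific feature names.
    """
    Ns = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, M.shape[1] + 1, dtype=np.float64)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = M / Ns
    pg = M.sum(axis=1)  # per gray level
    ps = M.sum(axis=0)  # per size
    mu_i = float((i * pg / Ns).sum())
    mu_j = float((j * ps / Ns).sum())
    nz = p[p > 0]

    generic = {
        "SmallEmphasis": float((M / J**2).sum() / Ns),
        "LargeEmphasis": float((M * J**2).sum() / Ns),
        "GrayLevelNonUniformity": float((pg**2).sum() / Ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / Ns**2),
        "SizeNonUniformity": float((ps**2).sum() / Ns),
        "SizeNonUniformityNormalized": float((ps**2).sum() / Ns**2),
        "Percentage": float(Ns / n_pix),
        "GrayLevelVariance": float((((I - mu_i) ** 2) * p).sum()),
        "SizeVariance": float((((J - mu_j) ** 2) * p).sum()),
        "Entropy": float(-(nz * np.log2(nz + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((M / I**2).sum() / Ns),
        "HighGrayLevelEmphasis": float((M * I**2).sum() / Ns),
        "SmallLowGrayLevelEmphasis": float((M / (I**2 * J**2)).sum() / Ns),
        "SmallHighGrayLevelEmphasis": float((M * I**2 / J**2).sum() / Ns),
        "LargeLowGrayLevelEmphasis": float((M * J**2 / I**2).sum() / Ns),
        "LargeHighGrayLevelEmphasis": float((M * I**2 * J**2).sum() / Ns),
    }
    return {out_name: generic[key] for key, out_name in prefix.items()}


_GLRLM_NAMES = {
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

_GLSZM_NAMES = {
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

_GLDM_NAMES = {
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


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the four 2D directions."""
    n_pix = int(disc.mask.sum())
    per_dir = [
        _size_weighted_features(glrlm_matrix(disc, d), n_pix, _GLRLM_NAMES)
        for d in DIRECTIONS_2D
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (8-connected zones; single matrix)."""
    n_pix = int(disc.mask.sum())
    return _size_weighted_features(glszm_matrix(disc), n_pix, _GLSZM_NAMES)


def gldm_features(disc: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 dependence features (8-neighbourhood, level tolerance ``alpha``)."""
    n_pix = int(disc.mask.sum())
    return _size_weighted_features(gldm_matrix(disc, alpha), n_pix, _GLDM_NAMES)


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    """The 5 neighbourhood gray-tone difference features."""
    s, n, nvp = ngtdm_matrix(disc)
    if nvp == 0:
        raise ValueError("no ROI pixel has an in-ROI neighbour")
    p = n / nvp
    i = np.arange(1, disc.n_bins + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())

    pi, ii, si = p[present], i[present], s[present]

    sum_ps = float((pi * si).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_SENTINEL

    if ngp > 1:
        Ipi, Ipj = np.meshgrid(ii, ii, indexing="ij")
        Ppi, Ppj = np.meshgrid(pi, pi, indexing="ij")
        contrast = (
            float((Ppi * Ppj * (Ipi - Ipj) ** 2).sum()) / (ngp * (ngp - 1))
        ) * (float(si.sum()) / nvp)
        busy_den = float(np.abs(Ipi * Ppi - Ipj * Ppj).sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        Spi, Spj = np.meshgrid(si, si, indexing="ij")
        complexity = float(
            (np.abs(Ipi - Ipj) * (Ppi * Spi + Ppj * Spj) / (Ppi + Ppj)).sum()
        ) / nvp
        s_sum = float(si.sum())
        strength = (
            float(((Ppi + Ppj) * (Ipi - Ipj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
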