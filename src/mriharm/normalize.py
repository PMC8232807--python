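"""Image-level intensity harmonization for brain MRI.

Six methods in three families, all estimating their parameters inside a
brain (or foreground) mask and transforming the whole volume:

1. *Z-Score* and *WhiteStripe*: ``Inorm = (I - mu) / sigma``, with mu and
   sigma taken over the whole mask (Z-Score) or over a narrow quantile
   window around the white-matter mode (WhiteStripe).
2. *FCM-*, *GMM-* and *KDE-based*: ``Inorm = c * I / mu`` where mu is
   the white-matter mean (fuzzy c-means or Gaussian mixture) or the
   white-matter peak (kernel density), WM being the brightest class on
   T1-weighted images.
3. *Nyul* piecewise-linear histogram matching: landmark percentiles are
   mapped onto a standard scale learned from a training set.

All methods either are invariant to a global positive affine intensity
change (z-score, whitestripe, nyul) or pin the output's WM level to the
constant ``c`` (fcm, gmm, kde) — either way, a pure scanner gain/offset
difference between paired volumes is neutralized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .core import ImageVolume

__all__ = [
    "NormalizationParams",
    "StandardScale",
    "zscore_normalize",
    "whitestripe_normalize",
    "estimate_wm_mean_fcm",
    "estimate_wm_mean_gmm",
    "find_wm_peak_kde",
    "wm_ratio_normalize",
    "fcm_normalize",
    "gmm_normalize",
    "kde_normalize",
    "nyul_learn_standard_histogram",
    "nyul_apply",
    "otsu_mask",
    "normalize_volume",
    "NORMALIZATION_METHODS",
]

DEFAULT_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)


@dataclass(frozen=True)
class NormalizationParams:
    method: str
    mu: float
    sigma: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive")


@dataclass
class StandardScale:
    """Learned Nyul standard scale: landmark percentiles -> intensities."""

    percentiles: tuple[float, ...]
    landmarks: tuple[float, ...]
    scale_bounds: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles)
        s = np.asarray(self.landmarks)
        if not (np.all(np.diff(p) > 0) and p[0] > 0 and p[-1] < 100):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if not np.all(np.diff(s) > 0):
            raise ValueError("standard landmarks must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "percentiles": list(self.percentiles),
            "landmarks": list(self.landmarks),
            "scale_bounds": list(self.scale_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardScale":
        return cls(
            percentiles=tuple(d["percentiles"]),
            landmarks=tuple(d["landmarks"]),
            scale_bounds=tuple(d["scale_bounds"]),
        )


def _masked(volume: ImageVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return volume.values[mask]


# ---------------------------------------------------------------------------
# family 1: (I - mu) / sigma


def zscore_normalize(
    volume: ImageVolume, mask: np.ndarray
) -> tuple[ImageVolume, NormalizationParams]:
    """Z-score the volume with mask statistics (population sigma)."""
    vals = _masked(volume, mask)
    if np.unique(vals).size < 2:
        raise ValueError("constant masked region: sigma = 0")
    mu = float(vals.mean())
    sigma = float(vals.std())
    out = (volume.values - mu) / sigma
    return volume.copy_with(out), NormalizationParams("zscore", mu=mu, sigma=sigma)


def whitestripe_normalize(
    volume: ImageVolume,
    mask: np.ndarray,
    stripe_halfwidth: float = 0.05,
) -> tuple[ImageVolume, NormalizationParams]:
    """Standardize against the white stripe around the WM mode.

    The stripe collects masked voxels whose intensity lies between the
    (q - tau) and (q + tau) quantiles, where q is the quantile of the WM
    mode and tau the half-width.  Because the stripe is defined through
    quantiles, the method is equivariant under global positive affine
    intensity changes.
    """
    vals = _masked(volume, mask)
    peak = find_wm_peak_kde(volume, mask)
    q = float((vals < peak).mean())
    # keep the full 2*tau quantile width even when the window hits a
    # boundary (tau = 0.5 then degenerates to the whole mask)
    width = min(2.0 * stripe_halfwidth, 1.0)
    lo_q = float(np.clip(q - stripe_halfwidth, 0.0, 1.0 - width))
    lo = np.quantile(vals, lo_q)
    hi = np.quantile(vals, lo_q + width)
    stripe = vals[(vals >= lo) & (vals <= hi)]
    if stripe.size == 0:
        raise ValueError("white stripe is empty")
    mu = float(stripe.mean())
    sigma = float(stripe.std())
    if sigma <= 0:
        raise ValueError("white stripe has zero variance")
    out = (volume.values - mu) / sigma
    return volume.copy_with(out), NormalizationParams("whitestripe", mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# family 2: c * I / mu  (WM-referenced)


def estimate_wm_mean_fcm(
    volume: ImageVolume,
    mask: np.ndarray,
    n_classes: int = 3,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> float:
    """WM mean via fuzzy c-means on masked intensities.

    WM is taken as the class with the highest centroid (T1 convention:
    white matter is the brightest compartment).
    """
    x = np.asarray(_masked(volume, mask), dtype=np.float64)
    if np.unique(x).size < n_classes:
        raise ValueError(f"need at least {n_classes} distinct intensities")
    # deterministic init: spread centroids over the intensity range
    centroids = np.quantile(x, np.linspace(0.1, 0.9, n_classes))
    m = fuzzifier
    power = 2.0 / (m - 1.0)
    for iteration in range(max_iter):
        d = np.abs(x[:, None] - centroids[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.abs(new - centroids).max()
        centroids = new
        if shift < tol:
            break
    else:
        raise RuntimeError(f"FCM did not converge in {max_iter} iterations")
    return float(centroids.max())


def estimate_wm_mean_gmm(
    volume: ImageVolume,
    mask: np.ndarray,
    n_components: int = 3,
    n_init: int = 5,
    max_voxels: int = 50000,
    random_state: int = 0,
) -> float:
    """WM mean as the highest-mean component of a univariate GMM."""
    x = _masked(volume, mask)
    if x.size > max_voxels:
        rng = np.random.default_rng(random_state)
        x = rng.choice(x, size=max_voxels, replace=False)
    gm = GaussianMixture(
        n_components=n_components, n_init=n_init, random_state=random_state
    ).fit(x.reshape(-1, 1))
    if np.any(gm.covariances_.ravel() < 1e-12):
        raise ValueError("singular GMM component (variance < 1e-12)")
    return float(gm.means_.max())


def find_wm_peak_kde(
    volume: ImageVolume,
    mask: np.ndarray,
    bandwidth: str | float = "scott",
    grid_size: int = 1024,
) -> float:
    """Location of the highest-intensity local maximum of the masked KDE.

    Gaussian kernel, Scott's rule by default; the highest-intensity mode
    is the WM peak on T1-weighted images.
    """
    x = _masked(volume, mask)
    if x.size < 100:
        raise ValueError("need at least 100 masked voxels for KDE")
    kde = gaussian_kde(x, bw_method=bandwidth)
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.nonzero(interior)[0] + 1
    # a mode must carry real mass: discard numerical wiggles in the tails
    peaks = peaks[dens[peaks] >= 0.1 * dens.max()]
    if peaks.size == 0:
        raise ValueError("density has no local maximum")
    return float(grid[peaks[-1]])


def wm_ratio_normalize(volume: ImageVolume, mu: float, c: float = 1.0) -> ImageVolume:
    """``Inorm = c * I / mu``: pin the WM reference level to ``c``."""
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return volume.copy_with(c * volume.values / mu)


def fcm_normalize(volume, mask, c: float = 1.0):
    mu = estimate_wm_mean_fcm(volume, mask)
    return wm_ratio_normalize(volume, mu, c), NormalizationParams("fcm", mu=mu, c=c)


def gmm_normalize(volume, mask, c: float = 1.0):
    mu = estimate_wm_mean_gmm(volume, mask)
    return wm_ratio_normalize(volume, mu, c), NormalizationParams("gmm", mu=mu, c=c)


def kde_normalize(volume, mask, c: float = 1.0):
    mu = find_wm_peak_kde(volume, mask)
    return wm_ratio_normalize(volume, mu, c), NormalizationParams("kde", mu=mu, c=c)


# ---------------------------------------------------------------------------
# family 3: Nyul piecewise-linear histogram matching


def _image_landmarks(vals: np.ndarray, percentiles) -> np.ndarray:
    lm = np.percentile(vals, percentiles)
    if not np.all(np.diff(lm) > 0):
        raise ValueError("non-increasing landmarks (too many tied intensities)")
    return lm


def nyul_learn_standard_histogram(
    volumes: list[ImageVolume],
    masks: list[np.ndarray],
    percentiles=DEFAULT_PERCENTILES,
    scale_bounds: tuple[float, float] = (1.0, 100.0),
) -> StandardScale:
    """Learn the standard scale from a training set.

    Each image's landmarks are mapped affinely so its outermost
    landmarks hit the scale bounds, then averaged across images — this
    makes the learned scale invariant to per-image affine intensity
    transforms.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 training volumes")
    s_min, s_max = scale_bounds
    mapped = []
    for vol, mask in zip(volumes, masks):
        lm = _image_landmarks(_masked(vol, mask), percentiles)
        mapped.append(s_min + (lm - lm[0]) * (s_max - s_min) / (lm[-1] - lm[0]))
    landmarks = np.mean(mapped, axis=0)
    return StandardScale(
        percentiles=tuple(float(p) for p in percentiles),
        landmarks=tuple(float(v) for v in landmarks),
        scale_bounds=(float(s_min), float(s_max)),
    )


def nyul_apply(
    volume: ImageVolume, mask: np.ndarray, scale: StandardScale
) -> tuple[ImageVolume, NormalizationParams]:
    """Piecewise-linearly map the image onto the standard scale.

    The image's own landmark intensities map exactly onto the standard
    landmarks; between landmarks the map is linear, beyond the outermost
    landmarks it extends linearly with the end-segment slopes.  The map
    is monotone non-decreasing everywhere.
    """
    lm = _image_landmarks(_masked(volume, mask), scale.percentiles)
    std = np.asarray(scale.landmarks)
    x = volume.values
    out = np.interp(x, lm, std)
    # linear extension beyond the outermost landmarks
    lo_slope = (std[1] - std[0]) / (lm[1] - lm[0])
    hi_slope = (std[-1] - std[-2]) / (lm[-1] - lm[-2])
    below = x < lm[0]
    above = x > lm[-1]
    out[below] = std[0] + (x[below] - lm[0]) * lo_slope
    out[above] = std[-1] + (x[above] - lm[-1]) * hi_slope
    params = NormalizationParams("nyul", mu=float(lm[len(lm) // 2]))
    return volume.copy_with(out), params


# ---------------------------------------------------------------------------
# utilities


def otsu_mask(volume: ImageVolume) -> np.ndarray:
    """Fallback foreground mask by Otsu thresholding."""
    from skimage.filters import threshold_otsu

    t = threshold_otsu(volume.values)
    return volume.values > t


NORMALIZATION_METHODS = ("zscore", "whitestripe", "fcm", "gmm", "kde", "nyul")


def normalize_volume(
    volume: ImageVolume,
    mask: np.ndarray,
    method: str,
    scale: StandardScale | None = None,
    c: float = 1.0,
) -> tuple[ImageVolume, NormalizationParams]:
    """Dispatch to one of the six methods by name."""
    if method == "zscore":
        return zscore_normalize(volume, mask)
    if method == "whitestripe":
        return whitestripe_normalize(volume, mask)
    if method == "fcm":
        return fcm_normalize(volume, mask, c)
    if method == "gmm":
        return gmm_normalize(volume, mask, c)
    if method == "kde":
        return kde_normalize(volume, mask, c)
    if method == "nyul":
        if scale is None:
            raise ValueError("nyul requires a learned StandardScale")
        return nyul_apply(volume, mask, scale)
    raise ValueError(f"unknown normalization method {method!r}")
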