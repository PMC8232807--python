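"""Reproducibility statistics: paired tests, Bonferroni, DiffFeatureRatio.

Feature distributions from the same ROIs under different acquisition
settings should be indistinguishable if no scanner effect remains.  Per
(tissue class, feature) a paired nonparametric test compares settings —
Wilcoxon signed-rank for two settings, Friedman for three or more —
followed by Bonferroni correction over the 92 features within a class.
The headline summary is the *DiffFeatureRatio*: the fraction of tests
significant at alpha = 0.05; 0 marks perfect harmonization, 1 the worst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ImageVolume
from .features.registry import FEATURE_NAMES

__all__ = [
    "wilcoxon_signed_rank",
    "friedman_test",
    "bonferroni_adjust",
    "diff_feature_ratio",
    "evaluate_feature_table",
    "image_histogram",
    "pca_components",
]


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded (if all are zero, p = 1 by
    convention).  The null distribution is exact for n <= 25 without
    ties in |d|, otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 5:
        raise ValueError("need >= 5 nonzero differences for the signed-rank test")
    absd = np.abs(d)
    has_ties = np.unique(absd).size < absd.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return float(res.pvalue)


def friedman_test(groups) -> float:
    """Friedman chi-square p-value for k >= 3 paired samples.

    Within-block midranks with tie correction; chi-square approximation
    with k - 1 degrees of freedom.  Identical blocks give statistic 0
    and p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 3:
        raise ValueError("Friedman needs k >= 3 groups; use Wilcoxon for two")
    n = groups[0].size
    if any(g.size != n for g in groups):
        raise ValueError("all groups must have equal length")
    if n < 5:
        raise ValueError("need >= 5 blocks")
    data = np.column_stack(groups)
    if np.all(np.ptp(data, axis=1) == 0):
        return 1.0
    return float(stats.friedmanchisquare(*groups).pvalue)


def bonferroni_adjust(pvals, family_size: int) -> np.ndarray:
    """adjusted = min(1, p * family_size), order preserved."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * float(family_size))


def diff_feature_ratio(report: pd.DataFrame, alpha: float = 0.05, use_raw: bool = False) -> float:
    """Fraction of (tissue class, feature) tests significant at ``alpha``.

    Adjusted p-values by default; ``use_raw`` probes sensitivity to the
    correction.
    """
    if len(report) == 0:
        raise ValueError("empty report")
    col = "p_raw" if use_raw else "p_adjusted"
    return float((report[col] < alpha).mean())


def evaluate_feature_table(
    features: pd.DataFrame,
    batch_col: str = "setting_id",
    class_col: str = "tissue_class",
    pair_cols: tuple[str, ...] = ("subject_id", "roi_id"),
    feature_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(tissue class, feature) paired tests across settings.

    Rows are paired on ``pair_cols``; the Bonferroni family is the
    feature count within one tissue class.  Returns a report with raw
    and adjusted p-values and a significance flag.
    """
    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in features.columns]
    settings = [str(s) for s in pd.unique(features[batch_col])]
    if len(settings) < 2:
        raise ValueError("need >= 2 settings to compare")
    test_name = "wilcoxon" if len(settings) == 2 else "friedman"

    rows = []
    for cls, grp in features.groupby(class_col, sort=False):
        wide = grp.pivot_table(
            index=list(pair_cols), columns=batch_col, values=feature_names,
            sort=False,
        )
        for feat in feature_names:
            cols = [wide[(feat, s)].to_numpy() for s in settings]
            if any(np.isnan(c).any() for c in cols):
                raise ValueError(f"unpaired rows for feature {feat} in class {cls}")
            if test_name == "wilcoxon":
                try:
                    p = wilcoxon_signed_rank(cols[0], cols[1])
                except ValueError:
                    # fewer than 5 informative pairs: no detectable difference
                    p = 1.0
            else:
                p = friedman_test(cols)
            rows.append(
                {
                    "tissue_class": cls,
                    "feature": feat,
                    "test": test_name,
                    "comparison": " vs ".join(settings),
                    "p_raw": p,
                }
            )
    report = pd.DataFrame(rows)
    family = len(feature_names)
    report["p_adjusted"] = np.concatenate(
        [
            bonferroni_adjust(sub["p_raw"].to_numpy(), family)
            for _, sub in report.groupby("tissue_class", sort=False)
        ]
    )
    report["significant"] = report["p_adjusted"] < alpha
    return report


def image_histogram(
    volume: ImageVolume, mask: np.ndarray, n_bins: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Counts over ``n_bins`` equal-width bins spanning the masked range."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = volume.values[mask]
    counts, edges = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
    return counts, edges


def pca_components(
    features: pd.DataFrame,
    k: int = 3,
    feature_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized PCA scores and explained-variance ratios.

    Features are z-scored column-wise first; constant columns are
    dropped with a warning.
    """
    import warnings

    from sklearn.decomposition import PCA

    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in features.columns]
    X = features[feature_names].to_numpy(dtype=np.float64)
    if X.shape[0] <= k:
        raise ValueError(f"need more than {k} rows for {k} components")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, ok in zip(feature_names, keep) if not ok]
        warnings.warn(f"dropping constant feature columns: {dropped}")
        X = X[:, keep]
        sd = sd[keep]
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, random_state=0)
    scores = pca.fit_transform(Xs)
    return scores, pca.explained_variance_ratio_
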