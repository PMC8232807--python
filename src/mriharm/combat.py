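"""Location/scale batch harmonization of radiomic feature tables (ComBat).

Model, per feature v and batch i:

    y_ijv = alpha_v + gamma_iv + delta_iv * eps_ijv,   eps ~ N(0, sigma_v^2)

with no covariates (all samples are paired across batches, so there is
no biological design to preserve).  After standardizing
``z = (y - alpha_v) / sigma_v``, the per-batch location gamma and scale
delta are estimated in one of three ways:

* ``standard``   — per-batch sample mean / sd of z, no shrinkage;
* ``parametric`` — empirical-Bayes shrinkage with a normal prior on
  gamma and an inverse-gamma prior on delta^2, method-of-moments
  hyperparameters and iterative conditional updates;
* ``nonparametric`` — posterior expectations by likelihood-weighted
  averaging over the other features' raw estimates.

The adjusted data are ``y* = sigma_v * (z - gamma*_iv) / delta*_iv + alpha_v``.
Harmonization is applied per tissue class: each class gets its own fit,
because the same feature can carry a different scanner effect in
different tissues and pooled fitting leaves residual effects behind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_transform", "harmonize_by_class"]

VARIANTS = ("standard", "parametric", "nonparametric")


@dataclass
class CombatModel:
    variant: str
    batches: list[str]
    n_per_batch: dict[str, int]
    feature_names: list[str]
    alpha: np.ndarray  # (V,) grand effects
    sigma: np.ndarray  # (V,) pooled residual sd
    gamma_hat: dict[str, np.ndarray]  # raw per-batch location (V,)
    delta2_hat: dict[str, np.ndarray]  # raw per-batch variance (V,)
    gamma_star: dict[str, np.ndarray]  # EB-adjusted
    delta2_star: dict[str, np.ndarray]
    hyper: dict[str, dict[str, float]] = field(default_factory=dict)
    n_iterations: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "variant": self.variant,
            "batches": self.batches,
            "n_per_batch": self.n_per_batch,
            "feature_names": self.feature_names,
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": {b: g.tolist() for b, g in self.gamma_star.items()},
            "delta2_star": {b: d.tolist() for b, d in self.delta2_star.items()},
            "hyper": self.hyper,
            "n_iterations": self.n_iterations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_matrix(features: pd.DataFrame, feature_names: list[str] | None):
    if feature_names is None:
        feature_names = [c for c in features.columns if features[c].dtype.kind == "f"]
    X = features[feature_names].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X, list(feature_names)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(d2):
    m, s2 = d2.mean(), d2.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 100.0


def _bprior(d2):
    m, s2 = d2.mean(), d2.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else m


def _it_solve(z_batch, g_hat, d2_hat, g_bar, t2, a, b, tol=1e-4, max_iter=1000):
    """Iterative conditional EB updates for one batch (parametric variant)."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d2_hat.copy()
    count = 0
    while count < max_iter:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)).max(),
        )
        g_old, d_old = g_new, d_new
        count += 1
        if change < tol:
            break
    return g_old, d_old, count


def _int_eprior(z_batch, g_hat, d2_hat):
    """Non-parametric EB: likelihood-weighted average over other features."""
    n, V = z_batch.shape
    g_star = np.empty(V)
    d2_star = np.empty(V)
    for v in range(V):
        others = np.arange(V) != v
        g, d2 = g_hat[others], d2_hat[others]
        x = z_batch[:, v]
        # log-likelihood of column v under each other feature's (g, d2)
        resid2 = ((x[:, None] - g[None, :]) ** 2).sum(axis=0)
        ll = -0.5 * n * np.log(2 * np.pi * d2) - resid2 / (2 * d2)
        w = np.exp(ll - ll.max())
        wsum = w.sum()
        if wsum <= 0 or not np.isfinite(wsum):
            g_star[v], d2_star[v] = g_hat[v], d2_hat[v]
        else:
            g_star[v] = float((w * g).sum() / wsum)
            d2_star[v] = float((w * d2).sum() / wsum)
    return g_star, d2_star


def combat_fit(
    features: pd.DataFrame,
    batch_labels,
    variant: str = "parametric",
    feature_names: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> CombatModel:
    """Fit the location/scale model on one tissue class' feature table."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    batch_labels = np.asarray(batch_labels)
    X, feature_names = _as_matrix(features, feature_names)
    batches = [str(b) for b in pd.unique(batch_labels)]
    if len(batches) < 2:
        raise ValueError(
            "ComBat needs at least 2 batches: with a single batch there is "
            "nothing to harmonize"
        )
    idx = {b: np.nonzero(batch_labels.astype(str) == b)[0] for b in batches}
    n_per = {b: len(ix) for b, ix in idx.items()}
    for b, n in n_per.items():
        if n < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    N = X.shape[0]

    # zero-variance guard, named so the user can find the offending cell
    for b, ix in idx.items():
        v = X[ix].var(axis=0)
        if np.any(v <= 0):
            bad = [feature_names[k] for k in np.nonzero(v <= 0)[0]]
            raise ValueError(f"zero variance in batch {b!r} for feature(s) {bad}")

    batch_means = {b: X[ix].mean(axis=0) for b, ix in idx.items()}
    alpha = np.zeros(X.shape[1])
    for b in batches:
        alpha += n_per[b] * batch_means[b]
    alpha /= N
    resid = X.copy()
    for b, ix in idx.items():
        resid[ix] -= batch_means[b][None, :]
    sigma2 = (resid**2).sum(axis=0) / N
    sigma = np.sqrt(sigma2)

    Z = (X - alpha[None, :]) / sigma[None, :]
    gamma_hat = {b: Z[ix].mean(axis=0) for b, ix in idx.items()}
    delta2_hat = {b: Z[ix].var(axis=0, ddof=1) for b, ix in idx.items()}

    gamma_star: dict[str, np.ndarray] = {}
    delta2_star: dict[str, np.ndarray] = {}
    hyper: dict[str, dict[str, float]] = {}
    n_iterations: dict[str, int] = {}

    for b in batches:
        g_hat, d2_hat = gamma_hat[b], delta2_hat[b]
        if variant == "standard":
            gamma_star[b], delta2_star[b] = g_hat.copy(), d2_hat.copy()
        elif variant == "parametric":
            g_bar = float(g_hat.mean())
            t2 = float(g_hat.var())
            a = float(_aprior(d2_hat))
            bb = float(_bprior(d2_hat))
            g_s, d2_s, iters = _it_solve(
                Z[idx[b]], g_hat, d2_hat, g_bar, t2, a, bb, tol=tol, max_iter=max_iter
            )
            if iters >= max_iter:
                raise RuntimeError(f"parametric EB did not converge for batch {b!r}")
            gamma_star[b], delta2_star[b] = g_s, d2_s
            hyper[b] = {"gamma_bar": g_bar, "tau2": t2, "lambda": a, "theta": bb}
            n_iterations[b] = iters
        else:  # nonparametric
            gamma_star[b], delta2_star[b] = _int_eprior(Z[idx[b]], g_hat, d2_hat)

    return CombatModel(
        variant=variant,
        batches=batches,
        n_per_batch=n_per,
        feature_names=feature_names,
        alpha=alpha,
        sigma=sigma,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        hyper=hyper,
        n_iterations=n_iterations,
    )


def combat_transform(
    features: pd.DataFrame, model: CombatModel, batch_labels
) -> pd.DataFrame:
    """Apply a fitted model: remove per-batch location/scale, restore grand scale."""
    batch_labels = np.asarray(batch_labels).astype(str)
    unseen = set(batch_labels) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch label(s): {sorted(unseen)}")
    X, _ = _as_matrix(features, model.feature_names)
    Z = (X - model.alpha[None, :]) / model.sigma[None, :]
    out = np.empty_like(Z)
    for b in model.batches:
        ix = np.nonzero(batch_labels == b)[0]
        if len(ix) == 0:
            continue
        d_star = np.sqrt(model.delta2_star[b])
        out[ix] = (Z[ix] - model.gamma_star[b][None, :]) / d_star[None, :]
    Y = out * model.sigma[None, :] + model.alpha[None, :]
    result = features.copy()
    result[model.feature_names] = Y
    return result


def harmonize_by_class(
    features: pd.DataFrame,
    batch_col: str = "setting_id",
    class_col: str = "tissue_class",
    variant: str = "parametric",
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Fit and apply ComBat independently within each tissue class.

    Row order and id columns are preserved.  Raises if any
    (class x batch) cell has fewer than 2 rows.
    """
    all_batches = pd.unique(features[batch_col])
    for cls, grp in features.groupby(class_col):
        counts = grp[batch_col].value_counts().reindex(all_batches, fill_value=0)
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(
                f"tissue class {cls!r} has fewer than 2 ROIs in batch(es) {bad}"
            )
    pieces = []
    for cls, grp in features.groupby(class_col, sort=False):
        model = combat_fit(grp, grp[batch_col], variant, feature_names)
        pieces.append(combat_transform(grp, model, grp[batch_col]))
    out = pd.concat(pieces).loc[features.index]
    return out
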