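"""GBLUP fitting, hold-out prediction, replicated five-fold cross-validation,
weight-grid enumeration, and grid search over joined weighted kernels.

The model is y = 1 mu + Z u + e with u ~ N(0, G s2_u) and e ~ N(0, I s2_e);
the variance ratio lambda = s2_e / s2_u is estimated by REML through the
eigendecomposition of the training kernel (single-kernel spectral method),
so every restricted-likelihood evaluation is O(n).  Hold-out samples are
predicted by the BLUP conditional expectation

    u_test = G_test,train (G_train,train + lambda I)^(-1) (y_train - mu 1).

Prediction ability is the Pearson correlation between observed and
predicted adjusted entry means in the validation set of each fold; the
median across the five folds is taken per replicate, and the median of
those medians across replicates is the headline figure.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import CVResult, GBLUPFit, GridSearchResult, Kernel

__all__ = [
    "fit_gblup",
    "predict_holdout",
    "prediction_ability",
    "cross_validate",
    "fold_partitions",
    "enumerate_weight_grid",
    "combine_kernels",
    "grid_search",
]

#: Natural-log search window for the variance ratio lambda.  The strictly
#: positive lower bound regularizes the rank-deficient centered kernels at
#: small n, so no diagonal jitter is needed in the spectral formulation.
_LOG_LAMBDA_RANGE = (-12.0, 12.0)


def _align_y(y, sample_ids: Sequence[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [s for s in sample_ids if s not in y.index]
        if missing:
            raise KeyError(f"phenotype missing for samples {missing[:5]}")
        return y.loc[list(sample_ids)].to_numpy(float)
    y = np.asarray(y, float)
    if y.shape[0] != len(sample_ids):
        raise ValueError("y length does not match kernel samples")
    return y


def fit_gblup(kernel: Kernel, y) -> GBLUPFit:
    """REML fit of the single-kernel GBLUP model on the training samples."""
    ids = kernel.sample_ids
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 training samples")
    yv = _align_y(y, ids)
    K = kernel.matrix
    min_eig_tol = -1e-6 * max(1.0, np.abs(kernel.matrix).max())
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s[0] < min_eig_tol:
        raise ValueError(f"kernel not PSD (min eigenvalue {s[0]:.3g})")
    s = np.clip(s, 0.0, None)

    if np.ptp(yv) == 0.0:
        # zero phenotypic variance: all shrinkage, predictions are the mean
        return GBLUPFit(
            mu_hat=float(yv.mean()), lambda_hat=np.inf,
            u_hat=pd.Series(np.zeros(n), index=ids),
            training_ids=list(ids), alpha=np.zeros(n),
            sigma2_u=0.0, sigma2_e=0.0,
        )

    yt = U.T @ yv
    xt = U.T @ np.ones(n)

    def neg_reml(log_lam: float) -> float:
        d = s + np.exp(log_lam)
        xtd = xt / d
        xx = xtd @ xt
        mu = (xtd @ yt) / xx
        r = yt - mu * xt
        rss = (r * r / d).sum()
        s2u = rss / (n - 1)
        return (n - 1) * np.log(s2u) + np.log(d).sum() + np.log(xx)

    grid = np.linspace(*_LOG_LAMBDA_RANGE, 61)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    log_lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    lam = float(np.exp(log_lam))

    d = s + lam
    xtd = xt / d
    xx = xtd @ xt
    mu = float((xtd @ yt) / xx)
    alpha = U @ ((yt - mu * xt) / d)          # (K + lam I)^-1 (y - mu)
    u_hat = K @ alpha
    s2u = float(((yt - mu * xt) ** 2 / d).sum() / (n - 1))
    return GBLUPFit(
        mu_hat=mu, lambda_hat=lam,
        u_hat=pd.Series(u_hat, index=ids),
        training_ids=list(ids), alpha=alpha,
        sigma2_u=s2u, sigma2_e=lam * s2u,
    )


def predict_holdout(fit: GBLUPFit, kernel: Kernel, test_ids: Sequence[str]) -> pd.Series:
    """BLUP prediction mu + G_test,train (G_train,train + lambda I)^-1 (y - mu)."""
    known = set(kernel.sample_ids)
    missing = [t for t in test_ids if t not in known]
    if missing:
        raise KeyError(f"test samples not in kernel: {missing[:5]}")
    if not np.isfinite(fit.lambda_hat):
        return pd.Series(np.full(len(test_ids), fit.mu_hat), index=list(test_ids))
    G_tt = kernel.cross(test_ids, fit.training_ids)
    pred = fit.mu_hat + G_tt @ fit.alpha
    return pd.Series(pred, index=list(test_ids))


def prediction_ability(observed, predicted) -> float:
    """Pearson correlation of observed vs predicted; 0 (with a warning) when
    the predictions are constant."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted differ in length")
    if obs.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        warnings.warn("constant vector in prediction ability; returning 0", stacklevel=2)
        return 0.0
    return float(stats.pearsonr(obs, pred)[0])


def fold_partitions(
    n_samples: int, n_folds: int, n_replicates: int, base_seed: int
) -> np.ndarray:
    """Random fold labels, shape (n_replicates, n_samples); fold sizes differ
    by at most one.  Replicate r draws from seed (base_seed + r) mod 2^31, so
    partitions are shared across any predictors evaluated with the same
    settings (paired comparisons)."""
    labels = np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n_samples, n_folds + 1).astype(int)))
    out = np.empty((n_replicates, n_samples), dtype=int)
    for r in range(n_replicates):
        rng = np.random.default_rng((base_seed + r) % 2**31)
        out[r] = rng.permutation(labels)
    return out


def cross_validate(
    kernel: Kernel,
    y,
    n_folds: int = 5,
    n_replicates: int = 200,
    base_seed: int = 0,
    partitions: Optional[np.ndarray] = None,
    keep_predictions: bool = False,
) -> CVResult:
    """Replicated k-fold cross-validation of single-kernel GBLUP.

    Variance components are re-estimated inside every training fold, so no
    information leaks from the hold-out samples.
    """
    ids = kernel.sample_ids
    n = len(ids)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples, got {n}")
    yv = _align_y(y, ids)
    if partitions is None:
        partitions = fold_partitions(n, n_folds, n_replicates, base_seed)
    abilities = np.empty((n_replicates, n_folds))
    preds = np.empty((n_replicates, n)) if keep_predictions else None
    id_arr = np.asarray(ids, dtype=object)
    for r in range(n_replicates):
        fold = partitions[r]
        for f in range(n_folds):
            test = fold == f
            train_ids = list(id_arr[~test])
            fit = fit_gblup(kernel.restrict(train_ids), yv[~test])
            p = predict_holdout(fit, kernel, list(id_arr[test])).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                abilities[r, f] = prediction_ability(yv[test], p)
            if preds is not None:
                preds[r, test] = p
    return CVResult(
        abilities=abilities,
        fold_assignments=partitions,
        replicate_seeds=[(base_seed + r) % 2**31 for r in range(n_replicates)],
        sample_ids=list(ids),
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# Weight grid and joined weighted kernels
# ---------------------------------------------------------------------------

def enumerate_weight_grid(n_kernels: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All compositions of 1 into ``n_kernels`` weights on the ``step``
    lattice, each exactly once, in lexicographic order.

    Enumeration is exact in rational arithmetic; ``step`` must divide 1.
    With four kernels and step 0.1 there are C(13,3) = 286 combinations.
    """
    if n_kernels < 1:
        raise ValueError("need at least one kernel")
    frac = Fraction(step).limit_denominator(10**6)
    if frac <= 0 or (1 / frac).denominator != 1:
        raise ValueError(f"step {step} does not divide 1 exactly")
    L = int(1 / frac)
    out = []
    for parts in product(range(L + 1), repeat=n_kernels - 1):
        rest = L - sum(parts)
        if rest >= 0:
            out.append(tuple(float(p * frac) for p in (*parts, rest)))
    return out


def combine_kernels(kernels: Sequence[Kernel], weights: Sequence[float]) -> Kernel:
    """Joined weighted relationship matrix sum_k w_k G_k (convex combination)."""
    if len(kernels) != len(weights):
        raise ValueError("one weight per kernel required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    ids = kernels[0].sample_ids
    for k in kernels[1:]:
        if k.sample_ids != ids:
            raise ValueError("kernels cover different samples or orderings")
    G = np.zeros_like(kernels[0].matrix)
    for w, k in zip(weights, kernels):
        if w != 0.0:
            G = G + w * k.matrix
    layer = "+".join(
        f"{w:g}*{k.layer}" for w, k in zip(weights, kernels) if w != 0.0
    )
    m = sum(k.m for w, k in zip(weights, kernels) if w != 0.0)
    return Kernel(sample_ids=list(ids), matrix=G, m=m, layer=layer)


def grid_search(
    kernels: Sequence[Kernel],
    y,
    grid: Optional[Sequence[tuple[float, ...]]] = None,
    step: float = 0.1,
    n_folds: int = 5,
    n_replicates: int = 200,
    base_seed: int = 0,
) -> GridSearchResult:
    """Evaluate every weight vector on the simplex lattice by replicated CV.

    Fold partitions are shared across all weight vectors within a replicate,
    making comparisons between weight vectors paired; vertex vectors
    therefore reproduce single-kernel CV exactly under the same seed.  Ties
    on the maximal ability are broken toward the fewest nonzero weights,
    then the lexicographically smallest vector.
    """
    if grid is None:
        grid = enumerate_weight_grid(len(kernels), step)
    ids = kernels[0].sample_ids
    partitions = fold_partitions(len(ids), n_folds, n_replicates, base_seed)
    rows = []
    for w in grid:
        joint = combine_kernels(kernels, w)
        cv = cross_validate(
            joint, y, n_folds=n_folds, n_replicates=n_replicates,
            base_seed=base_seed, partitions=partitions,
        )
        rows.append((*w, cv.median_of_medians))
    layers = [k.layer for k in kernels]
    table = pd.DataFrame(rows, columns=[f"w_{l}" for l in layers] + ["ability"])
    best_ability = table["ability"].max()
    tied = [grid[i] for i in np.flatnonzero(table["ability"].to_numpy() == best_ability)]
    best = min(tied, key=lambda w: (sum(1 for x in w if x != 0), w))
    return GridSearchResult(
        table=table,
        best_weights=tuple(best),
        best_ability=float(best_ability),
        kernel_layers=layers,
    )
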