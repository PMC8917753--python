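"""Adjusted entry means, variance components, entry-mean heritability,
trait-metabolite correlations, and metabolite filtering.

Replicated observations come in long format with columns
``genotype, environment, replicate, value`` (environment optional for
single-environment designs such as greenhouse metabolite profiling).

The multi-environment model is

    y_ijk = mu + E_j + G_i + (GxE)_ij + e_ijk

with genotype fixed (adjusted entry means) or random (genetic variance),
and environment / interaction always random.  The single-environment model
reduces to ``y_ik = mu + G_i + e_ik``.  Entry-mean heritability is

    H^2 = s2_G / (s2_G + nu_bar / 2)

where ``nu_bar`` is the mean variance of a difference between two adjusted
entry means, averaged over all unordered genotype pairs.

REML is maximised by bounded numerical optimisation of the restricted
log-likelihood assembled from explicit design matrices, profiling out the
residual variance and optimising over variance ratios.  The panel sizes in
scope (tens of genotypes, a few thousand observations) make this direct
approach both exact and fast: every likelihood evaluation reduces to a
q x q Cholesky factorisation, q being the total number of random-effect
levels, via the Woodbury identity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import EntryMeans, VarianceComponents

__all__ = [
    "fit_entry_means",
    "estimate_genetic_variance",
    "heritability_entry_mean",
    "correlate",
    "filter_metabolites",
    "reml",
]


# ---------------------------------------------------------------------------
# Generic REML via profiled variance ratios
# ---------------------------------------------------------------------------

@dataclass
class REMLFit:
    beta: np.ndarray
    sigma2_e: float
    sigma2: list[float]              # per random term, same order as Z_list
    varcov_beta: np.ndarray          # sigma2_e * (X' H^-1 X)^-1
    loglik: float
    converged: bool


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _gls_quantities(gamma, blocks, ZtZ, ZtX, Zty, XtX, Xty, yty):
    """GLS pieces under H = I + Z diag(gamma per block) Z'.

    All crossproducts are precomputed; each call costs one q x q Cholesky.
    Safe at gamma = 0 through the symmetric square-root formulation.
    Returns (logdetH, logdetXtHX, beta, rss, XtHX) or None on breakdown.
    """
    if len(blocks):
        g = np.concatenate([np.full(b, gi) for gi, b in zip(gamma, blocks)])
    else:
        g = np.zeros(0)
    sg = np.sqrt(g)
    q = g.size
    S = np.eye(q) + (sg[:, None] * ZtZ * sg[None, :])
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return None
    logdetH = 2.0 * np.log(np.diag(L)).sum()

    # A' H^-1 B = A'B - (sg*Z'A)' S^-1 (sg*Z'B)
    sZtX = sg[:, None] * ZtX
    sZty = sg * Zty
    W = np.linalg.solve(L, np.hstack([sZtX, sZty[:, None]]))
    WX, Wy = W[:, :-1], W[:, -1]
    XtHX = XtX - WX.T @ WX
    XtHy = Xty - WX.T @ Wy
    ytHy = yty - Wy @ Wy
    try:
        Lx = np.linalg.cholesky(XtHX)
    except np.linalg.LinAlgError:
        return None
    beta = np.linalg.solve(XtHX, XtHy)
    rss = max(float(ytHy - XtHy @ beta), 0.0)
    logdetXtHX = 2.0 * np.log(np.diag(Lx)).sum()
    return logdetH, logdetXtHX, beta, rss, XtHX


def reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: Sequence[np.ndarray],
) -> REMLFit:
    """REML fit of ``y = X beta + sum_k Z_k u_k + e`` with u_k ~ N(0, s2_k I).

    Optimises the residual variance on a log scale and each component
    variance on ``[0, inf)`` (constrained REML: negative estimates are
    truncated at the boundary).  The explicit residual parameter keeps the
    degenerate noiseless limit well behaved: s2_e runs to its tiny lower
    bound while the component variances stay finite and correct.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for REML (n={n}, p={p})")
    Z = np.hstack(Z_list) if Z_list else np.zeros((n, 0))
    blocks = [Zk.shape[1] for Zk in Z_list]
    ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ X, Z.T @ y
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    cross = (blocks, ZtZ, ZtX, Zty, XtX, Xty, yty)

    vary = float(np.var(y)) or 1.0

    # Degenerate exact-fit data (noiseless simulations): the restricted
    # likelihood is unbounded in s2_e, so attribute variances by sequential
    # least squares in the given term order — the noiseless-limit estimates.
    if Z_list:
        design = np.hstack([X, Z])
        coef_sat = np.linalg.lstsq(design, y, rcond=None)[0]
        rss_sat = float(((y - design @ coef_sat) ** 2).sum())
        if rss_sat <= 1e-12 * n * vary:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            sigma2 = []
            for Zk in Z_list:
                uk = np.linalg.lstsq(Zk, resid, rcond=None)[0]
                uk_c = uk - uk.mean()
                sigma2.append(float(uk_c @ uk_c / max(uk.size - 1, 1)))
                resid = resid - Zk @ uk
            out = _gls_quantities(np.zeros(len(Z_list)), *cross)
            XtHX = out[4]
            return REMLFit(
                beta=beta, sigma2_e=0.0, sigma2=sigma2,
                varcov_beta=np.zeros_like(XtHX), loglik=np.nan, converged=True,
            )

    if not Z_list:
        out = _gls_quantities(np.array([]), *cross)
        _, _, beta, rss, XtHX = out
        s2e = rss / (n - p)
        return REMLFit(beta, s2e, [], s2e * np.linalg.inv(XtHX), np.nan, True)

    K = len(Z_list)
    s2e_floor = 1e-10 * vary
    cap = 1e4 * vary

    def obj(theta):
        s2e = float(np.exp(theta[0]))
        s2k = np.maximum(theta[1:], 0.0)
        out = _gls_quantities(s2k / s2e, *cross)
        if out is None:
            return np.inf
        logdetH, logdetXtHX, _, rss, _ = out
        return (n - p) * np.log(s2e) + logdetH + logdetXtHX + rss / s2e

    starts = []
    for fe in (0.5, 0.05):
        for combo in itertools.product((0.0, 0.3, 3.0), repeat=K):
            starts.append(np.array([np.log(fe * vary), *(c * vary for c in combo)]))
    best_t, best_v = None, np.inf
    for t in starts:
        v = obj(t)
        if v < best_v:
            best_v, best_t = v, t
    bounds = [(np.log(s2e_floor), np.log(cap))] + [(0.0, cap)] * K
    res = optimize.minimize(
        obj, best_t, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13},
    )
    t_hat = res.x if res.fun <= best_v else best_t
    s2e = float(np.exp(np.clip(t_hat[0], *bounds[0])))
    s2k = np.maximum(t_hat[1:], 0.0)
    out = _gls_quantities(s2k / s2e, *cross)
    logdetH, logdetXtHX, beta, rss, XtHX = out
    nll = (n - p) * np.log(s2e) + logdetH + logdetXtHX + rss / s2e
    return REMLFit(
        beta=beta,
        sigma2_e=s2e,
        sigma2=[float(v) for v in s2k],
        varcov_beta=s2e * np.linalg.inv(XtHX),
        loglik=-0.5 * nll,
        converged=bool(res.success) or res.fun > best_v,
    )


# ---------------------------------------------------------------------------
# Observation-table handling
# ---------------------------------------------------------------------------

def _prepare(observations: pd.DataFrame, trait: Optional[str]):
    obs = observations
    if trait is not None and "trait" in obs.columns:
        obs = obs[obs["trait"] == trait]
        if obs.empty:
            raise ValueError(f"no observations for trait {trait!r}")
    required = {"genotype", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    obs = obs.dropna(subset=["value"])
    has_env = "environment" in obs.columns and obs["environment"].nunique() > 1
    geno = pd.Categorical(obs["genotype"].astype(str))
    y = obs["value"].to_numpy(float)
    return obs, y, geno, has_env


# ---------------------------------------------------------------------------
# Entry means and variance components
# ---------------------------------------------------------------------------

def fit_entry_means(observations: pd.DataFrame, trait: Optional[str] = None) -> EntryMeans:
    """Adjusted entry means with genotype fixed.

    Multi-environment data use environment and genotype-by-environment as
    random terms; single-environment data reduce to genotype means with a
    residual-only model.  Returns the GLS means and their variance-covariance
    matrix at the REML variance estimates.
    """
    obs, y, geno, has_env = _prepare(observations, trait)
    levels = list(geno.categories)
    X = _incidence(geno.codes, len(levels))
    if has_env:
        env = pd.Categorical(obs["environment"].astype(str))
        Ze = _incidence(env.codes, len(env.categories))
        cell = geno.codes.astype(np.int64) * len(env.categories) + env.codes
        cell_levels, cell_codes = np.unique(cell, return_inverse=True)
        Zge = _incidence(cell_codes, cell_levels.size)
        fit = reml(y, X, [Ze, Zge])
        model_used = "multi_env"
        cells_per_geno = (
            pd.DataFrame({"g": geno.codes, "c": cell}).groupby("g")["c"].nunique()
        )
        low_rep = [levels[g] for g, k in cells_per_geno.items() if k < 2]
    else:
        fit = reml(y, X, [])
        model_used = "single_env"
        counts = pd.Series(geno.codes).value_counts()
        low_rep = [levels[g] for g, k in counts.items() if k < 2]

    means = pd.Series(fit.beta, index=levels, name=trait)
    varcov = pd.DataFrame(fit.varcov_beta, index=levels, columns=levels)
    return EntryMeans(
        trait=trait or "trait",
        means=means,
        varcov=varcov,
        model_used=model_used,
        low_replication=low_rep,
    )


def estimate_genetic_variance(
    observations: pd.DataFrame, trait: Optional[str] = None
) -> VarianceComponents:
    """REML variance components with genotype random (intercept-only fixed part)."""
    obs, y, geno, has_env = _prepare(observations, trait)
    if np.ptp(y) == 0:
        return VarianceComponents(
            sigma2_G=0.0, sigma2_e=0.0,
            sigma2_E=0.0 if has_env else None,
            sigma2_GxE=0.0 if has_env else None,
            degenerate=True,
        )
    X = np.ones((y.size, 1))
    Zg = _incidence(geno.codes, len(geno.categories))
    if has_env:
        env = pd.Categorical(obs["environment"].astype(str))
        Ze = _incidence(env.codes, len(env.categories))
        cell = geno.codes.astype(np.int64) * len(env.categories) + env.codes
        _, cell_codes = np.unique(cell, return_inverse=True)
        Zge = _incidence(cell_codes, cell_codes.max() + 1)
        fit = reml(y, X, [Zg, Ze, Zge])
        s2g, s2env, s2ge = fit.sigma2
        return VarianceComponents(
            sigma2_G=s2g, sigma2_e=fit.sigma2_e, sigma2_E=s2env, sigma2_GxE=s2ge
        )
    fit = reml(y, X, [Zg])
    return VarianceComponents(sigma2_G=fit.sigma2[0], sigma2_e=fit.sigma2_e)


def heritability_entry_mean(vc: VarianceComponents, nu_bar: Optional[float] = None) -> float:
    """H^2 = s2_G / (s2_G + nu_bar/2), in [0, 1].

    ``nu_bar`` may be given explicitly or carried on ``vc``; the degenerate
    all-zero case is defined as 0 (with a warning).
    """
    if nu_bar is None:
        nu_bar = vc.nu_bar
    if nu_bar is None:
        raise ValueError("nu_bar required (pass explicitly or set on vc)")
    if nu_bar < 0:
        raise ValueError("nu_bar must be >= 0")
    denom = vc.sigma2_G + nu_bar / 2.0
    if denom == 0:
        warnings.warn("sigma2_G and nu_bar both zero; H2 defined as 0", stacklevel=2)
        return 0.0
    return float(min(1.0, max(0.0, vc.sigma2_G / denom)))


def heritability_from_observations(
    observations: pd.DataFrame, trait: Optional[str] = None
) -> tuple[float, VarianceComponents, EntryMeans]:
    """Convenience: entry means + genetic variance + entry-mean H^2 in one call."""
    em = fit_entry_means(observations, trait)
    vc = estimate_genetic_variance(observations, trait)
    nb = em.nu_bar()
    vc = VarianceComponents(
        sigma2_G=vc.sigma2_G, sigma2_e=vc.sigma2_e,
        sigma2_E=vc.sigma2_E, sigma2_GxE=vc.sigma2_GxE,
        nu_bar=nb, degenerate=vc.degenerate,
    )
    return heritability_entry_mean(vc), vc, em


# ---------------------------------------------------------------------------
# Correlations with significance stars
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*" if p < 0.05 else ""


def correlate(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between columns of an entry-means table.

    Returns (r, p, stars) DataFrames.  Significance is a two-sided t test at
    the conventional 0.05 / 0.01 / 0.001 thresholds, uncorrected for
    multiplicity.  Zero-variance columns yield NaN correlations.
    """
    cols = list(means.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = means[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for {cols[i]!r} vs {cols[j]!r}"
                )
            x, z = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(z) == 0:
                continue  # undefined, stays NaN
            rr, pp = stats.pearsonr(x, z)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(lambda v: "" if np.isnan(v) else _stars(v))
    np.fill_diagonal(sdf.values, "")
    return rdf, pdf, sdf


# ---------------------------------------------------------------------------
# Metabolite filtering and heritability groups
# ---------------------------------------------------------------------------

def filter_metabolites(
    means: pd.DataFrame,
    h2: pd.Series,
    identity: Optional[pd.Series] = None,
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
) -> dict[str, pd.DataFrame]:
    """Collapse duplicate-identity metabolites and build heritability groups.

    Metabolites annotated as the same compound keep only the member with the
    greatest entry-mean heritability.  The returned dict maps ``"M"`` (all
    retained metabolites) and ``"M_<t>"`` (those with H^2 strictly greater
    than t) to sample x metabolite mean tables with strictly nested columns.
    """
    h2 = h2.reindex(means.columns)
    if h2.isna().any():
        bad = h2.index[h2.isna()].tolist()
        raise ValueError(f"missing H2 for metabolites: {bad[:5]}")
    keep = list(means.columns)
    if identity is not None:
        keep = []
        ident = identity.reindex(means.columns)
        for _, group in ident.dropna().groupby(ident.dropna()):
            members = list(group.index)
            keep.append(max(members, key=lambda m: (h2[m], m)))
        unannotated = ident.index[ident.isna()]
        keep = sorted(set(keep) | set(unannotated), key=list(means.columns).index)
    out = {"M": means[keep]}
    for t in thresholds:
        sel = [m for m in keep if h2[m] > t]
        out[f"M_{t:g}"] = means[sel]
    return out
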