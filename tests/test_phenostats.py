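"""Entry means, variance components, heritability and correlations,
checked against direct GLS / expected-mean-squares oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicpred import (
    correlate,
    estimate_genetic_variance,
    filter_metabolites,
    fit_entry_means,
    heritability_entry_mean,
    heritability_from_observations,
)
from omicpred.datatypes import VarianceComponents
from omicpred.phenostats import reml


def long_table(values, genotypes, envs=None, reps=None, trait="T"):
    n = len(values)
    envs = envs if envs is not None else ["e1"] * n
    reps = reps if reps is not None else list(range(n))
    return pd.DataFrame({
        "genotype": genotypes, "environment": envs,
        "replicate": reps, "trait": trait, "value": values,
    })


# ---------------------------------------------------------------------------
# Entry means
# ---------------------------------------------------------------------------

def test_single_env_entry_mean_is_raw_mean():
    obs = long_table([2.0, 4.0, 10.0], ["A", "A", "B"], reps=[1, 2, 1])
    em = fit_entry_means(obs)
    assert em.means["A"] == pytest.approx(3.0)
    assert em.means["B"] == pytest.approx(10.0)
    assert em.model_used == "single_env"
    assert "B" in em.low_replication


def test_balanced_multi_env_entry_means_equal_raw_genotype_means(rng):
    genos, envs = [f"g{i}" for i in range(6)], [f"e{j}" for j in range(3)]
    rows = []
    for g in genos:
        for e in envs:
            for r in (1, 2):
                rows.append((g, e, r, "T", rng.normal()))
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    em = fit_entry_means(obs, "T")
    raw = obs.groupby("genotype")["value"].mean()
    np.testing.assert_allclose(em.means[raw.index], raw, atol=1e-8)
    assert em.model_used == "multi_env"


def test_unbalanced_entry_means_match_explicit_gls_oracle(rng):
    """On unbalanced data the adjusted means must equal a from-scratch GLS
    solve assembled with dense V = s2_e I + s2_E Z_E Z_E' + s2_GxE Z Z'."""
    genos, envs = ["g0", "g1", "g2", "g3"], ["e0", "e1", "e2"]
    rows = []
    for gi, g in enumerate(genos):
        for ej, e in enumerate(envs):
            n_rep = 1 + (gi + ej) % 3  # unbalanced replication
            for r in range(n_rep):
                rows.append((g, e, r, "T", rng.normal(loc=gi)))
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    em = fit_entry_means(obs, "T")

    # oracle: rebuild V at the fitted variance components and GLS directly
    from omicpred.phenostats import _incidence, _prepare
    o, y, geno, _ = _prepare(obs, "T")
    env = pd.Categorical(o["environment"])
    X = _incidence(geno.codes, len(geno.categories))
    Ze = _incidence(env.codes, len(env.categories))
    cell = geno.codes.astype(int) * 3 + env.codes
    _, cc = np.unique(cell, return_inverse=True)
    Zge = _incidence(cc, cc.max() + 1)
    fit = reml(y, X, [Ze, Zge])
    V = (fit.sigma2_e * np.eye(len(y))
         + fit.sigma2[0] * Ze @ Ze.T + fit.sigma2[1] * Zge @ Zge.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    np.testing.assert_allclose(em.means[list(geno.categories)], beta, atol=1e-6)
    np.testing.assert_allclose(
        em.varcov.to_numpy(), np.linalg.inv(X.T @ Vi @ X), atol=1e-6
    )


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def test_noiseless_variance_components():
    g = {"A": 1.0, "B": 3.0, "C": 7.0}
    rows = [(k, e, r, "T", v + {"e1": 0.5, "e2": -0.5}[e])
            for k, v in g.items() for e in ("e1", "e2") for r in (1, 2)]
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    vc = estimate_genetic_variance(obs, "T")
    assert vc.sigma2_e == pytest.approx(0.0, abs=1e-3)
    assert vc.sigma2_GxE == pytest.approx(0.0, abs=1e-3)
    assert vc.sigma2_G == pytest.approx(np.var([1, 3, 7], ddof=1), rel=0.05)


def test_degenerate_constant_observations_flagged():
    obs = long_table([5.0] * 6, ["A", "A", "B", "B", "C", "C"], reps=[1, 2] * 3)
    vc = estimate_genetic_variance(obs)
    assert vc.degenerate and vc.sigma2_G == 0.0 and vc.sigma2_e == 0.0


def test_balanced_single_env_reml_matches_ems_anova(rng):
    """For a balanced one-way design REML must equal the expected-mean-squares
    closed form sigma2_G = (MS_G - MS_e)/r when the estimate is interior."""
    n_g, r = 15, 4
    g_eff = rng.normal(0, 2.0, n_g)
    rows = [(f"g{i}", "e1", k, "T", g_eff[i] + rng.normal(0, 1.0))
            for i in range(n_g) for k in range(r)]
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    vc = estimate_genetic_variance(obs, "T")
    y = obs["value"].to_numpy().reshape(n_g, r)
    ms_g = r * np.var(y.mean(axis=1), ddof=1)
    ms_e = np.mean(np.var(y, axis=1, ddof=1))
    assert vc.sigma2_G == pytest.approx(max(0.0, (ms_g - ms_e) / r), rel=1e-4, abs=1e-8)
    assert vc.sigma2_e == pytest.approx(ms_e, rel=1e-4)


def test_variance_component_recovery_multi_env(rng):
    """Estimates stay within 10% of truth on average over replicated draws."""
    true = {"G": 4.0, "E": 1.0, "GxE": 0.5, "e": 1.0}
    n_g, n_e, r, n_sim = 20, 5, 4, 40
    ests = []
    for s in range(n_sim):
        rs = np.random.default_rng(1000 + s)
        g = rs.normal(0, np.sqrt(true["G"]), n_g)
        e = rs.normal(0, np.sqrt(true["E"]), n_e)
        ge = rs.normal(0, np.sqrt(true["GxE"]), (n_g, n_e))
        rows = [(f"g{i}", f"e{j}", k, "T",
                 g[i] + e[j] + ge[i, j] + rs.normal(0, 1.0))
                for i in range(n_g) for j in range(n_e) for k in range(r)]
        obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
        vc = estimate_genetic_variance(obs, "T")
        ests.append([vc.sigma2_G, vc.sigma2_GxE, vc.sigma2_e])
    mean = np.mean(ests, axis=0)
    np.testing.assert_allclose(mean, [true["G"], true["GxE"], true["e"]], rtol=0.10)


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

def test_heritability_formula_cases():
    assert heritability_entry_mean(VarianceComponents(3.0, 1.0), nu_bar=2.0) == pytest.approx(0.75)
    assert heritability_entry_mean(VarianceComponents(0.0, 1.0), nu_bar=2.0) == 0.0
    with pytest.warns(UserWarning):
        assert heritability_entry_mean(VarianceComponents(0.0, 0.0), nu_bar=0.0) == 0.0


def test_heritability_monotone_in_genetic_variance():
    h = [heritability_entry_mean(VarianceComponents(s, 1.0), nu_bar=1.0)
         for s in (0.1, 0.5, 1.0, 5.0)]
    assert all(a < b for a, b in zip(h, h[1:]))


def test_balanced_single_env_closed_form(rng):
    """With r reps, nu_bar = 2 s2_e / r, so s2_G=1, s2_e=1, r=2 gives H2=2/3."""
    n_g, r = 40, 2
    g = rng.normal(0, 1.0, n_g)
    g = (g - g.mean()) / g.std(ddof=1)          # realized s2_G = 1 exactly
    eps = rng.normal(0, 1.0, (n_g, r))
    eps = (eps - eps.mean()) / eps.std(ddof=0)  # pooled s2_e close to 1
    rows = [(f"g{i}", "e1", k, "T", g[i] + eps[i, k])
            for i in range(n_g) for k in range(r)]
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])
    h2, vc, em = heritability_from_observations(obs, "T")
    assert em.nu_bar() == pytest.approx(2 * vc.sigma2_e / r, rel=1e-6)
    assert h2 == pytest.approx(2.0 / 3.0, abs=0.08)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def test_correlate_identical_orthogonal_and_stars(rng):
    x = rng.normal(size=23)
    y = x - x.mean()
    z = rng.normal(size=23)
    z = z - z.mean()
    z -= (z @ y) / (y @ y) * y                   # orthogonal to y
    df = pd.DataFrame({"a": y, "same": y, "orth": z})
    r, p, s = correlate(df)
    assert r.loc["a", "same"] == pytest.approx(1.0)
    assert r.loc["a", "orth"] == pytest.approx(0.0, abs=1e-12)
    # r = 0.685 at n = 23 is significant beyond the 0.001 threshold
    t = 0.685 * np.sqrt(21 / (1 - 0.685**2))
    p_oracle = 2 * stats.t.sf(t, 21)
    assert p_oracle < 0.001
    b = 0.685 * y + np.sqrt(1 - 0.685**2) * z / z.std() * y.std()
    df2 = pd.DataFrame({"a": y, "b": b})
    r2, p2, s2 = correlate(df2)
    if r2.loc["a", "b"] >= 0.685:
        assert s2.loc["a", "b"] == "***"


def test_correlate_zero_variance_reported_missing():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "flat": [5.0] * 4})
    r, p, s = correlate(df)
    assert np.isnan(r.loc["a", "flat"])
    assert s.loc["a", "flat"] == ""


# ---------------------------------------------------------------------------
# Metabolite filtering
# ---------------------------------------------------------------------------

def test_filter_metabolites_duplicates_and_groups(rng):
    means = pd.DataFrame(rng.normal(size=(10, 3)), columns=["m1", "m2", "m3"])
    h2 = pd.Series({"m1": 0.3, "m2": 0.7, "m3": 0.65})
    identity = pd.Series({"m1": "glucose", "m2": "glucose", "m3": np.nan})
    groups = filter_metabolites(means, h2, identity=identity)
    assert list(groups["M"].columns) == ["m2", "m3"]  # keep max-H2 duplicate
    assert list(groups["M_0.6"].columns) == ["m2", "m3"]
    assert list(groups["M_0.7"].columns) == []         # strict threshold


def test_filter_metabolites_groups_are_nested(rng):
    means = pd.DataFrame(rng.normal(size=(8, 20)),
                         columns=[f"m{i}" for i in range(20)])
    h2 = pd.Series(np.linspace(0, 0.95, 20), index=means.columns)
    groups = filter_metabolites(means, h2)
    names = ["M"] + [f"M_0.{k}" for k in range(1, 9)]
    for a, b in zip(names, names[1:]):
        assert set(groups[b].columns) <= set(groups[a].columns)
    # threshold counts: H2 {0.05, 0.15, 0.65} -> M_0.1 has 2, M_0.6 has 1
    sub = filter_metabolites(means[["m0", "m1", "m2"]],
                             pd.Series({"m0": 0.05, "m1": 0.15, "m2": 0.65}))
    assert sub["M_0.1"].shape[1] == 2 and sub["M_0.6"].shape[1] == 1
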