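"""GBLUP, hold-out prediction, cross-validation and the weight grid,
checked against ridge-regression and joint mixed-model oracles."""

import numpy as np
import pandas as pd
import pytest

from omicpred import (
    build_kernel,
    combine_kernels,
    cross_validate,
    enumerate_weight_grid,
    fit_gblup,
    fold_partitions,
    grid_search,
    predict_holdout,
    prediction_ability,
)
from omicpred.datatypes import Kernel

from conftest import make_fm


def ridge_oracle(W, y_train, train_idx, test_idx, lam):
    """Hold-out predictions of GBLUP expressed as ridge regression on the
    standardized features with penalty m * lambda (kernel-trick identity)."""
    n, m = W.shape
    Ws = (W - W.mean(0)) / W.std(0, ddof=0)
    Wtr, Wte = Ws[train_idx], Ws[test_idx]
    K_tr = Wtr @ Wtr.T / m
    ones = np.ones(len(train_idx))
    A = np.linalg.inv(K_tr + lam * np.eye(len(train_idx)))
    mu = (ones @ A @ y_train) / (ones @ A @ ones)
    beta = np.linalg.solve(Wtr.T @ Wtr + m * lam * np.eye(m), Wtr.T @ (y_train - mu))
    return mu + Wte @ beta


def random_instance(rng, n=12, m=50):
    W = rng.normal(size=(n, m))
    fm = make_fm(W, samples=[f"s{i}" for i in range(n)])
    kernel = build_kernel(fm)
    y = rng.normal(size=n)
    return W, kernel, y


# ---------------------------------------------------------------------------
# GBLUP fit + prediction
# ---------------------------------------------------------------------------

def test_pure_noise_limit_predicts_mean(rng):
    """With phenotype unrelated to the kernel the fitted ratio is large and
    hold-out predictions collapse toward the general mean."""
    _, kernel, _ = random_instance(rng, n=14, m=30)
    y = rng.normal(size=11)
    train = kernel.sample_ids[:11]
    test = kernel.sample_ids[11:]
    # make y pure noise independent of kernel: already random
    fit = fit_gblup(kernel.restrict(train), y)
    pred = predict_holdout(fit, kernel, test)
    assert np.abs(pred - fit.mu_hat).max() <= np.abs(y - fit.mu_hat).max()


def test_zero_variance_phenotype_lambda_infinite(rng):
    _, kernel, _ = random_instance(rng, n=8, m=20)
    fit = fit_gblup(kernel, np.full(8, 3.0))
    assert np.isinf(fit.lambda_hat)
    assert (fit.u_hat == 0).all()
    pred = predict_holdout(fit, kernel, kernel.sample_ids[:2])
    assert (pred == 3.0).all()


def test_noiseless_kernel_trait_interpolates(rng):
    """A trait lying in the kernel's column space is recovered in-sample as
    the ratio goes to zero."""
    W = rng.normal(size=(15, 60))
    fm = make_fm(W, samples=[f"s{i}" for i in range(15)])
    kernel = build_kernel(fm)
    alpha = rng.normal(size=15)
    y = kernel.matrix @ alpha
    fit = fit_gblup(kernel, y)
    r = np.corrcoef(fit.mu_hat + fit.u_hat.to_numpy(), y)[0, 1]
    assert r > 0.999


def test_gblup_equals_ridge_oracle_on_random_instances():
    """Hold-out GBLUP predictions coincide with explicit ridge regression on
    the standardized feature matrix with penalty m*lambda (max diff < 1e-8)."""
    rng = np.random.default_rng(77)
    worst = 0.0
    for _ in range(20):
        n = int(rng.integers(12, 23))
        m = int(rng.integers(30, 101))
        W = rng.normal(size=(n, m))
        fm = make_fm(W, samples=[f"s{i}" for i in range(n)])
        kernel = build_kernel(fm)
        y = rng.normal(size=n)
        n_te = 3
        train = kernel.sample_ids[:-n_te]
        test = kernel.sample_ids[-n_te:]
        fit = fit_gblup(kernel.restrict(train), y[:-n_te])
        pred = predict_holdout(fit, kernel, test).to_numpy()
        oracle = ridge_oracle(
            W, y[:-n_te], np.arange(n - n_te), np.arange(n - n_te, n), fit.lambda_hat
        )
        worst = max(worst, np.abs(pred - oracle).max())
    assert worst < 1e-8


def test_holdout_equals_masked_joint_mixed_model(rng):
    """Predicting a hold-out sample equals solving the joint mixed model with
    that sample's phenotype masked (conditional-expectation identity)."""
    W = rng.normal(size=(14, 40))
    fm = make_fm(W, samples=[f"s{i}" for i in range(14)])
    kernel = build_kernel(fm)
    y = rng.normal(size=14)
    train, test = kernel.sample_ids[:11], kernel.sample_ids[11:]
    fit = fit_gblup(kernel.restrict(train), y[:11])
    pred = predict_holdout(fit, kernel, test).to_numpy()

    # oracle: Henderson equations on training samples, then conditional mean
    lam = fit.lambda_hat
    K = kernel.matrix
    K_tr = K[:11][:, :11]
    V = K_tr + lam * np.eye(11)
    Vi = np.linalg.inv(V)
    ones = np.ones(11)
    mu = (ones @ Vi @ y[:11]) / (ones @ Vi @ ones)
    u_all = K[:, :11] @ Vi @ (y[:11] - mu)     # BLUP of all 14 effects
    np.testing.assert_allclose(pred, mu + u_all[11:], atol=1e-8)


def test_zero_covariance_test_sample_predicts_mean(rng):
    n = 8
    G = np.eye(n)
    kernel = Kernel([f"s{i}" for i in range(n)], G, m=1, layer="X")
    y = rng.normal(size=n - 1)
    fit = fit_gblup(kernel.restrict(kernel.sample_ids[:-1]), y)
    pred = predict_holdout(fit, kernel, [kernel.sample_ids[-1]])
    assert pred.iloc[0] == pytest.approx(fit.mu_hat)


# ---------------------------------------------------------------------------
# Prediction ability
# ---------------------------------------------------------------------------

def test_prediction_ability_limits():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert prediction_ability(obs, obs) == pytest.approx(1.0)
    assert prediction_ability(obs, -obs) == pytest.approx(-1.0)
    with pytest.warns(UserWarning):
        assert prediction_ability(obs, np.ones(4)) == 0.0
    with pytest.raises(ValueError):
        prediction_ability(obs[:2], obs[:2])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def test_fold_sizes_balanced():
    parts = fold_partitions(22, 5, 3, base_seed=0)
    for r in range(3):
        sizes = sorted(np.bincount(parts[r]).tolist())
        assert sizes == [4, 4, 4, 5, 5]
    # partitions differ across replicates but are seed-deterministic
    again = fold_partitions(22, 5, 3, base_seed=0)
    np.testing.assert_array_equal(parts, again)
    assert not np.array_equal(parts[0], parts[1])


def test_replicate_median_and_median_of_medians():
    from omicpred.datatypes import CVResult
    ab = np.array([[0.2, 0.4, 0.6, 0.1, 0.9], [0.5, 0.5, 0.5, 0.5, 0.5]])
    cv = CVResult(ab, np.zeros((2, 10), int), [0, 1], [f"s{i}" for i in range(10)])
    assert cv.median_per_replicate.tolist() == [0.4, 0.5]
    assert cv.median_of_medians == pytest.approx(0.45)


def test_cv_near_perfect_for_noiseless_kernel_trait(rng):
    W = rng.normal(size=(22, 200))
    fm = make_fm(W, samples=[f"s{i}" for i in range(22)])
    kernel = build_kernel(fm)
    y = kernel.matrix @ rng.normal(size=22)  # heritable signal, no noise
    cv = cross_validate(kernel, y, n_replicates=10, base_seed=4)
    assert cv.median_of_medians > 0.6


# ---------------------------------------------------------------------------
# Weight grid + joined kernels
# ---------------------------------------------------------------------------

def test_weight_grid_cardinalities():
    assert len(enumerate_weight_grid(4, 0.1)) == 286
    assert len(enumerate_weight_grid(3, 0.1)) == 66    # C(12,2)
    assert enumerate_weight_grid(2, 0.5) == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]
    with pytest.raises(ValueError):
        enumerate_weight_grid(4, 0.3)


def test_weight_grid_no_duplicates_and_sums_to_one():
    grid = enumerate_weight_grid(4, 0.1)
    assert len(set(grid)) == len(grid)
    assert all(abs(sum(w) - 1.0) < 1e-9 for w in grid)


def test_combine_kernels_vertex_and_uniform(rng):
    kernels = [build_kernel(make_fm(rng.normal(size=(6, 15)))) for _ in range(4)]
    vertex = combine_kernels(kernels, (1.0, 0.0, 0.0, 0.0))
    np.testing.assert_array_equal(vertex.matrix, kernels[0].matrix)
    same = combine_kernels([kernels[0]] * 4, (0.25, 0.25, 0.25, 0.25))
    np.testing.assert_allclose(same.matrix, kernels[0].matrix, atol=1e-12)
    for w in [(0.3, 0.3, 0.2, 0.2), (0.0, 0.5, 0.5, 0.0)]:
        joint = combine_kernels(kernels, w)
        assert np.trace(joint.matrix) == pytest.approx(6.0, abs=1e-9)


def test_combine_kernels_validates_inputs(rng):
    k1 = build_kernel(make_fm(rng.normal(size=(5, 8))))
    k2 = build_kernel(make_fm(rng.normal(size=(5, 8)), samples=[f"x{i}" for i in range(5)]))
    with pytest.raises(ValueError, match="sum to 1"):
        combine_kernels([k1, k1], (0.5, 0.6))
    with pytest.raises(ValueError, match="different samples"):
        combine_kernels([k1, k2], (0.5, 0.5))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def test_grid_vertex_reproduces_single_kernel_cv(rng):
    kernels = [build_kernel(make_fm(rng.normal(size=(15, 40)))) for _ in range(3)]
    y = kernels[1].matrix @ rng.normal(size=15)
    gs = grid_search(kernels, y, grid=[(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)],
                     n_replicates=5, base_seed=9)
    for row, kern in zip(gs.table.itertuples(index=False), kernels[:2]):
        cv = cross_validate(kern, y, n_replicates=5, base_seed=9)
        assert row.ability == cv.median_of_medians


def test_grid_search_recovers_causal_kernel(rng):
    """Phenotype generated from kernel 2's feature space: the best weight
    vector should load at least half its weight on that kernel."""
    mats = [rng.normal(size=(20, 8)) for _ in range(3)]  # low rank: distinct kernels
    kernels = [build_kernel(make_fm(m)) for m in mats]
    Ws = (mats[2] - mats[2].mean(0)) / mats[2].std(0, ddof=0)
    y = Ws @ rng.normal(size=8)
    gs = grid_search(kernels, y, step=0.25, n_replicates=10, base_seed=13)
    assert gs.best_weights[2] >= 0.5


def test_grid_search_identical_kernels_tie_break(rng):
    k = build_kernel(make_fm(rng.normal(size=(15, 30))))
    kernels = [Kernel(k.sample_ids, k.matrix.copy(), k.m, f"L{i}") for i in range(4)]
    y = k.matrix @ rng.normal(size=15)
    gs = grid_search(kernels, y, step=0.5, n_replicates=4, base_seed=2)
    # all joint kernels identical -> all abilities equal -> vertex tie-break
    assert np.ptp(gs.table["ability"].to_numpy()) < 1e-12
    assert sorted(gs.best_weights) == [0.0, 0.0, 0.0, 1.0]
    assert gs.best_weights == (0.0, 0.0, 0.0, 1.0)  # lexicographic smallest vertex


def test_heritable_trait_beats_noisy_trait_in_paired_cv(rng):
    """Shared-fold CV: a high-heritability trait attains at least the median
    ability of its low-heritability counterpart in most replicates."""
    W = rng.normal(size=(22, 120))
    fm = make_fm(W, samples=[f"s{i}" for i in range(22)])
    kernel = build_kernel(fm)
    g = kernel.matrix @ rng.normal(size=22)
    g = (g - g.mean()) / g.std()
    wins = 0
    n_rep = 20
    for r in range(n_rep):
        noise = np.random.default_rng(100 + r)
        y_hi = g + noise.normal(0, np.sqrt(1 / 0.9 - 1), 22)
        y_lo = g + noise.normal(0, np.sqrt(1 / 0.5 - 1), 22)
        parts = fold_partitions(22, 5, 1, base_seed=500 + r)
        cv_hi = cross_validate(kernel, y_hi, n_replicates=1, partitions=parts)
        cv_lo = cross_validate(kernel, y_lo, n_replicates=1, partitions=parts)
        if cv_hi.median_of_medians >= cv_lo.median_of_medians:
            wins += 1
    assert wins >= 0.7 * n_rep
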