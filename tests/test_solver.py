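"""Solver unit and property tests: analytic cases, oracles, KKT, paths, CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mismatchnet import (PenaltyWeights, compute_lambda_path,
                         cross_validate_lambda, fit_lambda_path,
                         fit_weighted_enet, kkt_max_violation, predict,
                         soft_threshold)
from mismatchnet.solver import make_folds, objective_sweep_trace

from conftest import random_instance
from oracles import prss, ridge_closed_form


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("z,gamma,expected", [
    (3.0, 1.0, 2.0),
    (-0.5, 1.0, 0.0),
    (-3.0, 1.0, -2.0),
    (1.0, 1.0, 0.0),    # tie resolves to 0
    (0.0, 0.0, 0.0),
])
def test_soft_threshold_values(z, gamma, expected):
    assert soft_threshold(z, gamma) == expected


def test_soft_threshold_rejects_negative_gamma():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


@settings(derandomize=True, max_examples=200)
@given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
def test_soft_threshold_shrinks_toward_zero(z, gamma):
    out = soft_threshold(z, gamma)
    assert abs(out) <= abs(z)
    assert out * z >= 0  # never flips sign
    assert abs(out) == max(abs(z) - gamma, 0)


# ---------------------------------------------------------------------------
# single-feature analytic fits and basic contracts
# ---------------------------------------------------------------------------

X1 = np.array([[1.0], [-1.0]])
Y1 = np.array([1.0, -1.0])


def test_one_feature_ridge_closed_form():
    fit = fit_weighted_enet(X1, Y1, lam=2.0, alpha=0.0, weights=np.ones(1))
    assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-10)


def test_one_feature_lasso_stationarity():
    fit = fit_weighted_enet(X1, Y1, lam=1.0, alpha=1.0, weights=np.ones(1))
    assert fit.coefficients[0] == pytest.approx(0.75, abs=1e-10)


def test_infinite_weight_excludes_marker(rng):
    X, y, _ = random_instance(rng, n=30, p=4)
    w = np.array([1.0, np.inf, 1.0, 1.0])
    for lam in (0.1, 1.0, 10.0, 100.0):
        fit = fit_weighted_enet(X, y, lam=lam, alpha=0.7, weights=w)
        assert fit.coefficients[1] == 0.0


def test_lambda_zero_matches_least_squares(rng):
    X = rng.normal(size=(50, 5))
    y = X @ rng.normal(size=5) + rng.normal(size=50)
    fit = fit_weighted_enet(X, y, lam=0.0, alpha=1.0)
    Xc, yc = X - X.mean(0), y - y.mean()
    beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-6)
    preds = predict(fit, X)
    np.testing.assert_allclose(preds, y.mean() + Xc @ beta, atol=1e-6)


def test_weighted_ridge_matches_closed_form(rng):
    X, y, w = random_instance(rng, n=30, p=8)
    lam = 4.2
    fit = fit_weighted_enet(X, y, lam=lam, alpha=0.0, weights=w,
                            standardize=False)
    np.testing.assert_allclose(fit.coefficients,
                               ridge_closed_form(X, y, lam, w), atol=1e-6)


def test_input_validation(rng):
    X, y, w = random_instance(rng, n=20, p=3)
    with pytest.raises(ValueError):
        fit_weighted_enet(X, y, lam=-1.0)
    with pytest.raises(ValueError):
        fit_weighted_enet(X, y[:-1], lam=1.0)
    with pytest.raises(ValueError):
        fit_weighted_enet(X, y, lam=1.0, weights=w[:-1])
    with pytest.raises(ValueError):
        fit_weighted_enet(X * np.nan, y, lam=1.0)


def test_unit_weights_bitwise_equivalent(rng):
    """Explicit unit weights and no weights share one code path exactly."""
    X, y, _ = random_instance(rng, n=35, p=7)
    f0 = fit_weighted_enet(X, y, lam=2.0, alpha=0.5)
    f1 = fit_weighted_enet(X, y, lam=2.0, alpha=0.5, weights=np.ones(7))
    f2 = fit_weighted_enet(X, y, lam=2.0, alpha=0.5,
                           weights=PenaltyWeights.unit(7))
    assert np.array_equal(f0.coefficients, f1.coefficients)
    assert np.array_equal(f0.coefficients, f2.coefficients)
    assert f0.intercept == f1.intercept == f2.intercept


def test_monomorphic_marker_gets_zero_coefficient(rng):
    X, y, _ = random_instance(rng, n=25, p=4)
    X[:, 2] = 1.7  # constant column
    fit = fit_weighted_enet(X, y, lam=1.0, alpha=0.5)
    assert fit.coefficients[2] == 0.0


# ---------------------------------------------------------------------------
# descent, KKT, permutation properties
# ---------------------------------------------------------------------------

def test_objective_non_increasing_per_sweep(rng):
    for _ in range(5):
        X, y, w = random_instance(rng)
        alpha = rng.choice([0.0, 0.5, 1.0])
        lam = rng.uniform(0.1, 5.0)
        trace = objective_sweep_trace(X, y, lam, alpha, weights=w,
                                      n_sweeps=15)
        assert np.all(np.diff(trace) <= 1e-10)


def test_kkt_certificate_on_random_fits(rng):
    for _ in range(10):
        X, y, w = random_instance(rng)
        alpha = float(rng.choice([0.0, 0.5, 1.0]))
        lam = float(rng.uniform(0.1, 2 * X.shape[0]))
        fit = fit_weighted_enet(X, y, lam=lam, alpha=alpha, weights=w)
        assert fit.converged
        assert kkt_max_violation(fit, X, y, weights=w) <= 1e-6


def test_column_permutation_equivariance(rng):
    X, y, w = random_instance(rng, n=30, p=8)
    perm = rng.permutation(8)
    f = fit_weighted_enet(X, y, lam=1.5, alpha=0.5, weights=w)
    fp = fit_weighted_enet(X[:, perm], y, lam=1.5, alpha=0.5,
                           weights=w[perm])
    np.testing.assert_allclose(fp.coefficients, f.coefficients[perm],
                               atol=1e-6)
    assert fp.intercept == pytest.approx(f.intercept, abs=1e-6)


def test_prox_gradient_oracle_agreement(rng):
    """Small cross-check; the 20-instance version lives in the acceptance
    suite."""
    from oracles import prox_gradient_enet
    X, y, w = random_instance(rng, n=25, p=6)
    Xc, yc = X - X.mean(0), y - y.mean()
    lam = 3.0
    for alpha in (0.0, 0.5, 1.0):
        fit = fit_weighted_enet(X, y, lam=lam, alpha=alpha, weights=w,
                                standardize=False)
        ref = prox_gradient_enet(Xc, yc, lam, alpha, w)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-4)
        assert prss(Xc, yc, fit.coefficients, lam, alpha, w) <= \
            prss(Xc, yc, ref, lam, alpha, w) + 1e-8


# ---------------------------------------------------------------------------
# lambda path
# ---------------------------------------------------------------------------

def test_lambda_max_kills_all_coefficients():
    grid = compute_lambda_path(X1, Y1, alpha=1.0, n_lambda=5)
    assert grid[0] == pytest.approx(4.0)  # 2|x'y| / (alpha w) = 4
    fit = fit_weighted_enet(X1, Y1, lam=grid[0], alpha=1.0)
    assert fit.coefficients[0] == 0.0


def test_lambda_max_scales_inversely_with_weight(rng):
    X, y, _ = random_instance(rng, n=40, p=1)
    g1 = compute_lambda_path(X, y, alpha=1.0, weights=np.array([1.0]),
                             n_lambda=3)
    g2 = compute_lambda_path(X, y, alpha=1.0, weights=np.array([2.0]),
                             n_lambda=3)
    assert g2[0] == pytest.approx(g1[0] / 2)


def test_ridge_path_uses_alpha_floor(rng):
    X, y, _ = random_instance(rng, n=30, p=5)
    g0 = compute_lambda_path(X, y, alpha=0.0, n_lambda=3)
    g1 = compute_lambda_path(X, y, alpha=1e-3, n_lambda=3)
    assert g0[0] == pytest.approx(g1[0])


def test_lambda_path_errors():
    X = np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]])
    with pytest.raises(ValueError):
        compute_lambda_path(X, np.ones(3), alpha=1.0)  # constant y
    with pytest.raises(ValueError):
        compute_lambda_path(X, np.array([1.0, 2.0, 0.5]), alpha=1.0,
                            weights=np.array([np.inf, np.inf]))


def test_path_sparsity_grows_as_lambda_decreases(rng):
    X, y, w = random_instance(rng, n=40, p=10)
    path = fit_lambda_path(X, y, alpha=1.0, weights=w, n_lambda=30)
    nnz = np.array([f.n_nonzero for f in path.fits])
    assert nnz[0] == 0
    running_max = np.maximum.accumulate(nnz)
    assert nnz[-1] >= running_max[-1] - 2  # trend, not strict monotonicity
    assert np.all(np.diff(path.grid) < 0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cv_noiseless_recovery(rng):
    X = rng.normal(size=(100, 10))
    y = 3.0 * X[:, 5]
    cv = cross_validate_lambda(X, y, alpha=1.0, k=10, seed=1, n_lambda=40)
    assert cv.lambda_min == pytest.approx(cv.grid[-1])
    assert cv.cv_mse_mean.min() < 1e-4
    assert cv.lambda_1se >= cv.lambda_min


def test_cv_seed_stability(rng):
    X = rng.normal(size=(100, 10))
    y = 3.0 * X[:, 5]
    a = cross_validate_lambda(X, y, alpha=1.0, k=10, seed=1, n_lambda=40)
    b = cross_validate_lambda(X, y, alpha=1.0, k=10, seed=99, n_lambda=40)
    ia = int(np.where(a.grid == a.lambda_min)[0][0])
    ib = int(np.where(b.grid == b.lambda_min)[0][0])
    assert abs(ia - ib) <= 1


def test_leave_one_out_partitions(rng):
    assign = make_folds(10, 10, seed=0)
    assert sorted(assign) == list(range(10))
    X, y, _ = random_instance(rng, n=10, p=3)
    cv = cross_validate_lambda(X, y, alpha=1.0, k=10, seed=0, n_lambda=10)
    assert len(np.unique(cv.fold_assignment)) == 10


def test_cv_rejects_too_many_folds(rng):
    X, y, _ = random_instance(rng, n=5, p=3)
    with pytest.raises(ValueError):
        cross_validate_lambda(X, y, alpha=1.0, k=6)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_contracts(rng):
    X, y, _ = random_instance(rng, n=30, p=5)
    fit = fit_weighted_enet(X, y, lam=1e6, alpha=1.0)  # everything shrunk
    assert fit.n_nonzero == 0
    np.testing.assert_array_equal(predict(fit, X), np.full(30, fit.intercept))
    fit2 = fit_weighted_enet(X, y, lam=1.0, alpha=0.5)
    perm = rng.permutation(30)
    np.testing.assert_array_equal(predict(fit2, X[perm]),
                                  predict(fit2, X)[perm])
    with pytest.raises(ValueError):
        predict(fit2, X[:, :-1])
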