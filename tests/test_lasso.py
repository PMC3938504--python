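"""L1-constrained logistic regression: budget fits, paths, ranking, nested CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ntcpx import (
    FACTOR_NAMES,
    LassoLogisticPath,
    build_design_matrix,
    compute_path,
    fit_lasso,
    nested_cv_select,
)
from ntcpx._fastfit import newton_logit
from conftest import endpoint_data


@pytest.fixture(scope="module")
def small_design(cohort_3m):
    data, y = cohort_3m
    X, cmap = build_design_matrix(data, list(FACTOR_NAMES))
    return X, cmap, y


def _deviance(intercept, coefs, X, y):
    eta = intercept + X.to_numpy(float) @ np.asarray(coefs)
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


# ---------------------------------------------------------------------------
# budget-form fits


def test_zero_budget_is_intercept_only(small_design):
    X, _, y = small_design
    fit = fit_lasso(X, y, t=0.0)
    assert fit.coefficients.abs().max() == 0.0
    assert fit.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-9)


def test_slack_budget_matches_unpenalized_mle(small_design):
    X, _, y = small_design
    Z = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
    beta_mle, _, ok = newton_logit(Z, np.asarray(y, float))
    assert ok
    fit = fit_lasso(X, y, t=1e6)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_mle[1:], atol=1e-4)
    assert fit.intercept == pytest.approx(beta_mle[0], abs=1e-4)


def test_budget_feasibility(small_design):
    X, _, y = small_design
    for t in [0.1, 0.5, 1.0, 2.0]:
        fit = fit_lasso(X, y, t=t)
        assert fit.coefficients_std.abs().sum() <= t + 1e-8


def test_strong_covariate_enters_before_null():
    """With one strong and one null covariate at a small budget, the active
    coefficient is the strong one; the solution matches a brute-force
    profile of the constrained likelihood over a 2-D grid."""
    rng = np.random.default_rng(4)
    n = 60
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = rng.binomial(1, expit(0.2 + 1.6 * x1)).astype(float)
    X = pd.DataFrame({"strong": x1, "null": x2})
    t = 0.4
    fit = fit_lasso(X, y, t=t)
    assert abs(fit.coefficients_std["strong"]) > 1e-6
    assert abs(fit.coefficients_std["null"]) <= 1e-6

    # brute-force oracle on the standardized scale
    Xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)

    def profile_ll(b1, b2):
        eta_x = Xs @ np.array([b1, b2])
        b0 = 0.0
        for _ in range(50):  # 1-D Newton in the intercept
            p = expit(b0 + eta_x)
            g = np.sum(y - p)
            h = np.sum(p * (1 - p))
            step = g / h
            b0 += step
            if abs(step) < 1e-10:
                break
        eta = b0 + eta_x
        return np.sum(y * eta - np.logaddexp(0, eta))

    best = -np.inf
    arg = None
    for b1 in np.linspace(-t, t, 81):
        rem = t - abs(b1)
        for b2 in np.linspace(-rem, rem, 21):
            ll = profile_ll(b1, b2)
            if ll > best:
                best, arg = ll, (b1, b2)
    ours = profile_ll(fit.coefficients_std["strong"], fit.coefficients_std["null"])
    assert ours >= best - 1e-3
    assert np.sign(arg[0]) == np.sign(fit.coefficients_std["strong"])


# ---------------------------------------------------------------------------
# paths


def test_singleton_grid(small_design):
    X, _, y = small_design
    path = compute_path(X, y, penalties=[0.05])
    assert len(path.penalties) == 1
    assert path.coefs.shape[0] == 1


def test_path_matches_cold_start_refits(small_design):
    X, cmap, y = small_design
    path = compute_path(X, y, n_penalties=40, column_map=cmap)
    for i in [5, 20, 35]:
        single = compute_path(X, y, penalties=[path.penalties[i]])
        np.testing.assert_allclose(single.coefs_std[0], path.coefs_std[i], atol=1e-5)


def test_path_traces_continuous(small_design):
    X, cmap, y = small_design
    path = compute_path(X, y, n_penalties=80, column_map=cmap)
    jumps = np.abs(np.diff(path.coefs_std, axis=0)).max(axis=1)
    assert jumps.max() < 0.35  # no discontinuities on a fine grid


def test_active_set_grows_along_path(small_design):
    X, cmap, y = small_design
    path = compute_path(X, y, n_penalties=60, column_map=cmap)
    nnz = (np.abs(path.coefs_std) > 1e-8).sum(axis=1)
    assert np.all(np.diff(nnz) >= -1)  # monotone up to numerical tolerance
    assert nnz[0] == 0 and nnz[-1] > 5


def test_training_deviance_monotone_in_budget(small_design):
    X, cmap, y = small_design
    path = compute_path(X, y, n_penalties=40, column_map=cmap)
    dev = [_deviance(path.intercepts[i], path.coefs[i], X, np.asarray(y, float))
           for i in range(len(path.penalties))]
    assert np.all(np.diff(dev) <= 1e-6)  # penalty decreasing => budget growing


def test_constant_columns_stay_zero():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 100).astype(float)
    X = pd.DataFrame({"z1": np.zeros(100), "z2": np.full(100, 3.0)})
    path = compute_path(X, y, penalties=[0.1, 0.01, 0.001])
    assert np.all(path.coefs == 0.0)
    assert np.all(path.coefs_std == 0.0)


# ---------------------------------------------------------------------------
# ranking


def test_ranking_covers_all_sixteen_factors(cohort_3m):
    data, y = cohort_3m
    est = LassoLogisticPath(n_penalties=50).fit(data, y)
    assert sorted(est.ranking_) == sorted(FACTOR_NAMES)
    assert len(est.ranking_) == 16


def test_true_factors_rank_top():
    data, y = endpoint_data(5000, seed=51, timepoint="3m")
    est = LassoLogisticPath(n_penalties=60).fit(data, y)
    assert set(est.ranking_[:3]) == {"dmean_c", "dmean_i", "age"}


def test_never_entered_factors_rank_last():
    rng = np.random.default_rng(2)
    n = 400
    frame = pd.DataFrame({
        "dmean_c_gy": rng.uniform(5, 65, n),
        "smoking": rng.integers(0, 2, n),
    })
    y = rng.binomial(1, expit(-3 + 0.1 * frame["dmean_c_gy"]))
    # a grid stopping early enough that weak factors never activate
    est = LassoLogisticPath(factors=["dmean_c", "smoking"],
                            n_penalties=5, min_ratio=0.5).fit(frame, y)
    assert est.ranking_[0] == "dmean_c"


# ---------------------------------------------------------------------------
# nested cross-validation


def test_single_candidate_penalty_is_chosen(small_design):
    X, cmap, y = small_design
    cv = nested_cv_select(X, y, folds=5, random_state=0, penalties=[0.02],
                          column_map=cmap)
    assert cv.chosen_penalty == 0.02


def test_nested_cv_deterministic(small_design):
    X, cmap, y = small_design
    a = nested_cv_select(X, y, folds=5, random_state=7, n_penalties=10,
                         min_ratio=0.02, column_map=cmap)
    b = nested_cv_select(X, y, folds=5, random_state=7, n_penalties=10,
                         min_ratio=0.02, column_map=cmap)
    assert a.chosen_penalty == b.chosen_penalty
    assert a.selected_factors == b.selected_factors
    assert a.outer_subsets == b.outer_subsets
    np.testing.assert_array_equal(a.mean_deviance, b.mean_deviance)


def test_nested_cv_rejects_too_few_events():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"x": rng.normal(size=30)})
    y = np.r_[np.ones(4), np.zeros(26)]
    with pytest.raises(ValueError, match="stratified"):
        nested_cv_select(X, y, folds=10)


def test_nested_cv_selects_true_factors():
    """Across seeds, the CV-chosen subset contains the generating factors."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        data, y = endpoint_data(1000, seed=900 + seed, timepoint="3m")
        X, cmap = build_design_matrix(data, list(FACTOR_NAMES))
        cv = nested_cv_select(X, y, folds=10, random_state=seed,
                              n_penalties=10, min_ratio=0.01, column_map=cmap)
        if {"dmean_c", "dmean_i", "age"} <= set(cv.selected_factors):
            hits += 1
    assert hits >= int(0.9 * n_seeds)
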