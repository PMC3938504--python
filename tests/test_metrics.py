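"""Performance metrics: AUC, bootstrap CI, Hosmer-Lemeshow, Brier, R2, omnibus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from ntcpx import (
    auc,
    auc_ci,
    evaluate_model,
    fit_mle,
    hosmer_lemeshow,
    nagelkerke_r2,
    omnibus_test,
    scaled_brier,
)
from ntcpx._fastfit import newton_logit
from ntcpx.metrics import brier


def _auc_brute(p, y):
    p, y = np.asarray(p, float), np.asarray(y, int)
    pos, neg = p[y == 1], p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# AUC


def test_auc_perfect_and_constant():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc([0.4] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_auc_pair_counting_example():
    p, y = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
    assert auc(p, y) == pytest.approx(_auc_brute(p, y))
    assert _auc_brute(p, y) == 0.75


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([0.2, 0.4], [1, 1])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(5, 200))
def test_auc_matches_brute_force_enumeration(seed, n):
    rng = np.random.default_rng(seed)
    p = rng.choice([0.1, 0.25, 0.25, 0.6, 0.9], size=n)  # include ties
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    assert auc(p, y) == pytest.approx(_auc_brute(p, y), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 150)
    y = rng.integers(0, 2, 150)
    y[:2] = [0, 1]
    assert auc(p, y) == pytest.approx(auc(np.exp(3 * p) - 0.5, y), abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap CI


def test_auc_ci_deterministic_and_contains_point():
    rng = np.random.default_rng(2)
    p = rng.uniform(0, 1, 300)
    y = rng.binomial(1, p)
    a = auc_ci(p, y, n_boot=200, seed=9)
    b = auc_ci(p, y, n_boot=200, seed=9)
    assert a == b
    assert a[0] <= auc(p, y) <= a[1]


def test_auc_ci_upper_hits_one_under_perfect_separation():
    p = np.r_[np.full(40, 0.1), np.full(40, 0.9)]
    y = np.r_[np.zeros(40), np.ones(40)]
    lo, hi = auc_ci(p, y, n_boot=200, seed=0)
    assert hi == 1.0


def test_auc_ci_narrow_on_large_well_separated_sample():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10_000)
    y = rng.binomial(1, expit(2.5 * x))
    p = expit(2.5 * x)
    lo, hi = auc_ci(p, y, n_boot=400, seed=1)
    assert hi - lo < 0.05


def test_auc_ci_requires_enough_resamples():
    with pytest.raises(ValueError):
        auc_ci([0.1, 0.9], [0, 1], n_boot=10)


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow


def test_hl_two_group_hand_computation():
    p = np.array([0.2, 0.2, 0.8, 0.8])
    y = np.array([0, 1, 1, 1])
    stat, pval = hosmer_lemeshow(p, y, groups=2)
    # group 1: O=1, E=0.4, n=2 ; group 2: O=2, E=1.6, n=2
    expected = (1 - 0.4) ** 2 / (0.4 * (1 - 0.2)) + (2 - 1.6) ** 2 / (1.6 * (1 - 0.8))
    assert stat == pytest.approx(expected)
    assert pval == pytest.approx(stats.chi2.sf(expected, 1))


def test_hl_constant_predictions_reduce_to_count_chi_square():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 200).astype(float)
    pbar = y.mean()
    p = np.full(200, pbar)
    stat, _ = hosmer_lemeshow(p, y, groups=10)
    order = np.argsort(p, kind="mergesort")
    groups = np.array_split(order, 10)
    expected = sum((y[g].sum() - len(g) * pbar) ** 2 / (len(g) * pbar * (1 - pbar))
                   for g in groups)
    assert stat == pytest.approx(expected)


def test_hl_uniform_under_correct_specification():
    """p-values of a correctly specified fitted model are ~uniform: the
    fraction below 0.05 over 200 replicates stays within 0.05 +/- 0.04."""
    rng = np.random.default_rng(11)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.normal(size=(1000, 2))
        y = rng.binomial(1, expit(-0.3 + x @ np.array([0.8, -0.5]))).astype(float)
        Z = np.column_stack([np.ones(1000), x])
        beta, _, ok = newton_logit(Z, y)
        assert ok
        _, pval = hosmer_lemeshow(expit(Z @ beta), y)
        rejections += pval < 0.05
    assert abs(rejections / n_rep - 0.05) <= 0.04


def test_hl_needs_enough_observations():
    with pytest.raises(ValueError):
        hosmer_lemeshow([0.5] * 5, [0, 1, 0, 1, 0], groups=10)


# ---------------------------------------------------------------------------
# Brier scores


def test_scaled_brier_perfect_and_reference():
    y = np.array([0, 1, 1, 0, 1])
    assert scaled_brier(y.astype(float), y) == 1.0
    assert scaled_brier(np.full(5, y.mean()), y) == pytest.approx(0.0, abs=1e-12)


def test_scaled_brier_hand_example():
    # Brier = ((0.2-0)^2 + (0.8-1)^2)/2 = 0.04 ; reference 0.25 ; skill 0.84
    assert scaled_brier([0.2, 0.8], [0, 1]) == pytest.approx(1 - 0.04 / 0.25)


def test_scaled_brier_of_prevalence_predictor_is_zero_always():
    rng = np.random.default_rng(6)
    for n in (10, 57, 400):
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert scaled_brier(np.full(n, y.mean()), y) == pytest.approx(0.0, abs=1e-12)


def test_brier_bounds_predictions():
    with pytest.raises(ValueError):
        scaled_brier([1.2, 0.5], [1, 0])


# ---------------------------------------------------------------------------
# likelihood-based summaries


def test_nagelkerke_null_is_zero_and_saturated_is_one():
    ll_null = -60.0
    assert nagelkerke_r2(ll_null, ll_null, 100) == 0.0
    assert nagelkerke_r2(0.0, ll_null, 100) == pytest.approx(1.0)


def test_nagelkerke_rejects_model_worse_than_null():
    with pytest.raises(ValueError):
        nagelkerke_r2(-70.0, -60.0, 100)


def test_nagelkerke_from_independent_likelihood_computation(cohort_3m):
    data, y = cohort_3m
    model = fit_mle(data, y, factors=["dmean_c", "age"])
    p = np.asarray(model.ntcp(data))
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    ybar = y.mean()
    ll0 = float(np.sum(y * np.log(ybar) + (1 - y) * np.log(1 - ybar)))
    direct = nagelkerke_r2(ll, ll0, len(y))
    via_meta = nagelkerke_r2(model.fit_metadata["log_likelihood"],
                             model.fit_metadata["ll_null"], len(y))
    assert direct == pytest.approx(via_meta, abs=1e-6)
    assert 0.0 < direct < 1.0


def test_omnibus_null_and_strong_signal(cohort_3m):
    assert omnibus_test(-50.0, -50.0, 3)[1] == 1.0
    data, y = cohort_3m
    model = fit_mle(data, y, factors=["dmean_c", "dmean_i", "age"])
    _, p = omnibus_test(model.fit_metadata["log_likelihood"],
                        model.fit_metadata["ll_null"], 3)
    assert p < 1e-3


def test_omnibus_df_counts_each_dummy_column(cohort_3m):
    data, y = cohort_3m
    model = fit_mle(data, y, factors=["education"])
    report = evaluate_model(model, data, y, n_boot=150, seed=0)
    # education has 4 levels -> 3 indicator columns -> df = 3
    stat = 2 * (model.fit_metadata["log_likelihood"] - model.fit_metadata["ll_null"])
    assert report.omnibus_p == pytest.approx(stats.chi2.sf(stat, 3))


def test_omnibus_rejects_negative_statistic():
    with pytest.raises(ValueError):
        omnibus_test(-61.0, -60.0, 2)


def test_evaluation_report_invariants(cohort_3m):
    data, y = cohort_3m
    model = fit_mle(data, y, factors=["dmean_c", "dmean_i", "age"])
    report = evaluate_model(model, data, y, n_boot=150, seed=2)
    assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
    assert report.scaled_brier <= 1.0
    assert 0.0 <= report.nagelkerke_r2 <= 1.0
    assert report.n == len(y) and report.n_events == int(np.sum(y))
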