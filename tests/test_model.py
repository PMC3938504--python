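"""Design-matrix coding, the logistic NTCP formula, MLE fitting, odds ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ntcpx import (
    NtcpLogisticRegression,
    SeparationError,
    build_design_matrix,
    decode_design_row,
    default_coding,
    fit_mle,
    odds_ratio,
    published_model,
)
from conftest import endpoint_data

# ---------------------------------------------------------------------------
# design matrices


def test_continuous_factors_pass_through(cohort_3m):
    data, _ = cohort_3m
    X, cmap = build_design_matrix(data, ["dmean_c", "dmean_i", "age"])
    assert X.shape == (len(data), 3)
    np.testing.assert_allclose(X["dmean_c"], data["dmean_c_gy"])
    np.testing.assert_allclose(X["age"], data["age"])
    assert cmap == {"dmean_c": ["dmean_c"], "dmean_i": ["dmean_i"], "age": ["age"]}


def test_binary_factor_single_column():
    frame = pd.DataFrame({"smoking": [0, 1]})
    X, _ = build_design_matrix(frame, ["smoking"])
    assert list(X["smoking"]) == [0.0, 1.0]


def test_categorical_reference_coding():
    coding = default_coding().with_reference(t_stage=4)
    frame = pd.DataFrame({"t_stage": [1, 2, 3, 4]})
    X, cmap = build_design_matrix(frame, ["t_stage"], coding)
    assert cmap["t_stage"] == ["t_stage[1]", "t_stage[2]", "t_stage[3]"]
    assert X.to_numpy().tolist() == [[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]]


def test_unseen_level_rejected():
    frame = pd.DataFrame({"education": [0, 5]})
    with pytest.raises(ValueError, match="education"):
        build_design_matrix(frame, ["education"])


def test_empty_dummy_column_dropped(caplog):
    frame = pd.DataFrame({"education": [1, 2, 2, 3]})  # nobody at level 0
    coding = default_coding().with_reference(education=1)
    with caplog.at_level("INFO"):
        X, cmap = build_design_matrix(frame, ["education"], coding)
    assert cmap["education"] == ["education[2]", "education[3]"]


def test_coding_round_trip(cohort_3m):
    data, _ = cohort_3m
    factors = ["dmean_c", "age", "smoking", "t_stage", "education", "financial"]
    X, _ = build_design_matrix(data.head(40), factors, drop_empty=False)
    for i in range(len(X)):
        decoded = decode_design_row(X.iloc[i], factors)
        row = data.iloc[i]
        assert decoded["dmean_c"] == pytest.approx(row["dmean_c_gy"])
        for f in ["age", "smoking", "t_stage", "education", "financial"]:
            assert decoded[f] == pytest.approx(row[f])


# ---------------------------------------------------------------------------
# linear predictor and NTCP


def test_linear_predictor_matches_term_by_term_sum():
    model = published_model("3m", "suboptimal")
    record = {"dmean_c": 30.6, "dmean_i": 36.3, "age": 52}
    expected = -21.298 + 30.6 * 0.097 + 36.3 * 0.101 + 52 * 0.285
    assert model.linear_predictor(record) == pytest.approx(expected, abs=1e-12)
    assert model.ntcp(record) == pytest.approx(expit(expected), abs=1e-12)


def test_linear_predictor_reference_record_keeps_only_constant():
    model = published_model("12m", "suboptimal")
    record = {"dmean_i": 0.0, "dmean_c": 0.0, "smoking": 0, "education": 0, "t_stage": 4}
    assert model.linear_predictor(record) == pytest.approx(-8.028)


def test_linear_predictor_missing_factor_named():
    model = published_model("3m", "suboptimal")
    with pytest.raises(KeyError, match="age"):
        model.linear_predictor({"dmean_c": 30.0, "dmean_i": 35.0})


def test_ntcp_symmetry_and_limits():
    model = published_model("3m", "suboptimal")
    zero = {"dmean_c": 0.0, "dmean_i": 0.0, "age": 21.298 / 0.285}
    assert model.ntcp(zero) == pytest.approx(0.5)
    huge = {"dmean_c": 500.0, "dmean_i": 500.0, "age": 500.0}
    assert 0.999 < model.ntcp(huge) < 1.0


def test_ntcp_monotone_in_positive_coefficient_factor():
    model = published_model("3m", "suboptimal")
    probs = [model.ntcp({"dmean_c": d, "dmean_i": 36.3, "age": 52}) for d in np.linspace(5, 68, 15)]
    assert np.all(np.diff(probs) > 0)


# ---------------------------------------------------------------------------
# maximum likelihood


def test_intercept_only_fit_is_logit_of_event_rate(cohort_3m):
    data, y = cohort_3m
    model = fit_mle(data, y, factors=[])
    assert model.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)


def test_mle_recovers_generating_coefficients():
    data, y = endpoint_data(5000, seed=77, timepoint="3m")
    est = NtcpLogisticRegression(factors=["dmean_c", "dmean_i", "age"]).fit(data, y)
    truth = {"dmean_c": 0.097, "dmean_i": 0.101, "age": 0.285}
    for col, b, se in zip(est.design_columns_, est.coef_, est.se_):
        assert abs(b - truth[col]) < 1.96 * se * 1.5


def test_separation_raises():
    frame = pd.DataFrame({"smoking": [0, 1]})
    with pytest.raises(SeparationError):
        NtcpLogisticRegression(factors=["smoking"]).fit(frame, [0, 1])


def test_mle_matches_brute_force_likelihood_grid():
    """On a tiny one-covariate cohort the MLE equals a grid search of the
    log-likelihood to 3 decimals."""
    rng = np.random.default_rng(8)
    x = rng.integers(0, 2, size=50)
    y = rng.binomial(1, expit(-0.4 + 1.2 * x))
    frame = pd.DataFrame({"smoking": x})
    model = fit_mle(frame, y, factors=["smoking"])

    def loglik(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.logaddexp(0, eta))

    b0g, b1g, best = 0.0, 0.0, -np.inf
    lo0, hi0, lo1, hi1 = -4, 4, -4, 4
    for _ in range(4):  # successive grid refinement
        g0 = np.linspace(lo0, hi0, 41)
        g1 = np.linspace(lo1, hi1, 41)
        for a in g0:
            for b in g1:
                ll = loglik(a, b)
                if ll > best:
                    best, b0g, b1g = ll, a, b
        span0, span1 = (hi0 - lo0) / 10, (hi1 - lo1) / 10
        lo0, hi0 = b0g - span0, b0g + span0
        lo1, hi1 = b1g - span1, b1g + span1
    assert model.intercept == pytest.approx(b0g, abs=1e-3)
    assert model.terms["smoking"] == pytest.approx(b1g, abs=1e-3)


# ---------------------------------------------------------------------------
# odds ratios


@pytest.mark.parametrize("beta,printed", [(0.292, 1.339), (1.034, 2.812)])
def test_odds_ratio_reproduces_printed_values(beta, printed):
    assert round(odds_ratio(beta).value, 3) == printed


def test_odds_ratio_null_is_symmetric_on_log_scale():
    o = odds_ratio(0.0, se=0.3)
    assert o.value == 1.0
    assert math.log(o.ci_low) == pytest.approx(-math.log(o.ci_high))


def test_odds_ratio_rejects_negative_se():
    with pytest.raises(ValueError):
        odds_ratio(0.5, se=-1.0)


def test_model_serialization_round_trip(tmp_path, cohort_3m):
    from ntcpx.io import read_model, write_model

    data, y = cohort_3m
    model = fit_mle(data, y, factors=["dmean_c", "age", "t_stage"])
    path = tmp_path / "m.json"
    write_model(model, path)
    back = read_model(path)
    assert back.to_dict() == model.to_dict()
    np.testing.assert_allclose(back.linear_predictor(data.head(5)),
                               model.linear_predictor(data.head(5)))
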