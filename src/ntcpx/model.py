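"""Logistic NTCP model: design matrices, maximum-likelihood fitting, odds ratios.

The normal tissue complication probability of a patient with covariate
values ``x_1 .. x_n`` is modelled as

    NTCP = exp(S) / (1 + exp(S)),    S = beta_0 + sum_i beta_i * x_i,

where the ``x_i`` are the prognostic factors (doses in Gy, age in years,
reference-coded indicators for categorical factors) and the ``beta_i`` are
logistic regression coefficients estimated by maximum likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .factors import CodingScheme, FactorSpec, default_coding

__all__ = [
    "LogisticNtcpModel",
    "NtcpLogisticRegression",
    "SeparationError",
    "build_design_matrix",
    "decode_design_row",
    "fit_mle",
    "linear_predictor",
    "ntcp",
    "odds_ratio",
    "odds_ratio_table",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximiser (separated data)."""


# ---------------------------------------------------------------------------
# Model container


@dataclass
class LogisticNtcpModel:
    """Intercept plus per-factor coefficient terms of a logistic NTCP model.

    ``terms`` maps a factor name either to a scalar coefficient (continuous
    and binary factors) or to a ``{level: coefficient}`` mapping for
    categorical factors, in which the reference level carries 0.
    """

    intercept: float
    terms: dict[str, Any]
    fit_metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def factor_set(self) -> list[str]:
        return list(self.terms)

    def copy(self) -> "LogisticNtcpModel":
        terms = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in self.terms.items()}
        return LogisticNtcpModel(self.intercept, terms, dict(self.fit_metadata))

    # -- evaluation ---------------------------------------------------------

    def linear_predictor(self, data) -> float | np.ndarray:
        """Evaluate S = intercept + sum of coefficient * covariate terms.

        ``data`` may be a single record (mapping or :class:`pandas.Series`)
        or a cohort :class:`pandas.DataFrame`; factor values are resolved by
        factor name or by the underlying cohort column name.
        """
        single = not isinstance(data, pd.DataFrame)
        frame = _as_frame(data)
        s = np.full(len(frame), self.intercept, dtype=float)
        for factor, term in self.terms.items():
            values = _factor_values(frame, factor)
            if isinstance(term, Mapping):
                coef = np.zeros(len(frame))
                unknown = set()
                for i, lv in enumerate(values):
                    try:
                        coef[i] = term[int(lv)]
                    except (KeyError, ValueError):
                        unknown.add(lv)
                if unknown:
                    raise ValueError(f"{factor}: level(s) {sorted(unknown)!r} not in model term")
                s += coef
            else:
                s += float(term) * np.asarray(values, dtype=float)
        return float(s[0]) if single else s

    def ntcp(self, data) -> float | np.ndarray:
        """Complication probability exp(S)/(1+exp(S)), strictly inside (0, 1).

        Saturated linear predictors are clipped a hair inside the unit
        interval so downstream log-likelihoods stay finite.
        """
        s = self.linear_predictor(data)
        p = np.clip(expit(s), 1e-12, 1.0 - 1e-12)
        return float(p) if np.isscalar(s) else p

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        terms = {
            k: ({str(lv): c for lv, c in v.items()} if isinstance(v, Mapping) else v)
            for k, v in self.terms.items()
        }
        return {
            "intercept": self.intercept,
            "terms": terms,
            "fit_metadata": self.fit_metadata,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticNtcpModel":
        terms = {
            k: ({int(lv): float(c) for lv, c in v.items()} if isinstance(v, Mapping) else float(v))
            for k, v in d["terms"].items()
        }
        return cls(float(d["intercept"]), terms, dict(d.get("fit_metadata", {})))


def linear_predictor(model: LogisticNtcpModel, record) -> float | np.ndarray:
    return model.linear_predictor(record)


def ntcp(model: LogisticNtcpModel, record) -> float | np.ndarray:
    return model.ntcp(record)


# ---------------------------------------------------------------------------
# Design matrices


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, pd.Series):
        return data.to_frame().T
    if isinstance(data, Mapping):
        return pd.DataFrame([data])
    raise TypeError(f"expected mapping, Series or DataFrame, got {type(data).__name__}")


def _factor_values(frame: pd.DataFrame, factor: str, spec: FactorSpec | None = None) -> np.ndarray:
    """Resolve raw factor values from a cohort frame or record.

    Baseline xerostomia is special-cased: when only the baseline Likert
    score column is present it is collapsed to the binary 0 = none /
    1 = a little coding (scores of 66+ identify patients excluded from the
    modelling population and are rejected here).
    """
    if factor in frame.columns:
        return frame[factor].to_numpy()
    column = spec.column if spec is not None else None
    if column is None:
        from .factors import FACTORS

        column = FACTORS[factor].column if factor in FACTORS else factor
    if column not in frame.columns:
        raise KeyError(f"factor {factor!r} missing from data (no column {column!r})")
    values = frame[column].to_numpy()
    if factor == "baseline_xer":
        values = np.asarray(values, dtype=float)
        if np.any(values >= 66):
            raise ValueError(
                "baseline_xer: baseline Likert score >= 66 found; such patients "
                "belong to the excluded stratum and cannot enter the model"
            )
        values = (values >= 33).astype(int)
    return values


def build_design_matrix(
    data: pd.DataFrame,
    factors: Sequence[str],
    coding: CodingScheme | None = None,
    drop_empty: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand cohort factor values into a model design matrix.

    Continuous factors pass through on their native scales; binary factors
    become a single 0/1 column; categorical factors become reference-coded
    indicator columns.  Indicator columns that are empty in ``data`` (a
    level nobody occupies) are dropped with a logged notice, since they are
    inestimable.

    Returns the design matrix (without intercept column) and a map from
    factor name to the design columns it produced.
    """
    coding = coding or default_coding()
    cols: dict[str, np.ndarray] = {}
    column_map: dict[str, list[str]] = {}
    for factor in factors:
        spec = coding.spec(factor)
        values = _factor_values(data, factor, spec)
        if spec.is_continuous:
            arr = np.asarray(values, dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"{factor}: missing values in continuous factor")
            cols[factor] = arr
            column_map[factor] = [factor]
            continue
        arr = np.asarray(values)
        try:
            arr = arr.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{factor}: non-integer level values") from exc
        bad = sorted(set(arr) - set(spec.levels))
        if bad:
            raise ValueError(f"{factor}: unseen level(s) {bad}; declared levels {list(spec.levels)}")
        if spec.kind == "binary":
            cols[factor] = (arr == spec.levels[1]).astype(float)
            column_map[factor] = [factor]
        else:
            kept: list[str] = []
            for lv in spec.levels:
                if lv == spec.reference:
                    continue
                name = f"{factor}[{lv}]"
                indicator = (arr == lv).astype(float)
                if drop_empty and len(arr) > 0 and indicator.sum() == 0:
                    logger.info("dropping empty indicator column %s (no patient at level %s)", name, lv)
                    continue
                cols[name] = indicator
                kept.append(name)
            column_map[factor] = kept
    X = pd.DataFrame(cols, index=data.index)
    return X, column_map


def decode_design_row(
    row: Mapping[str, float],
    factors: Sequence[str],
    coding: CodingScheme | None = None,
) -> dict[str, float | int]:
    """Invert one design-matrix row back to raw factor values."""
    coding = coding or default_coding()
    out: dict[str, float | int] = {}
    for factor in factors:
        spec = coding.spec(factor)
        if spec.is_continuous:
            out[factor] = float(row[factor])
        elif spec.kind == "binary":
            out[factor] = spec.levels[1] if row[factor] else spec.levels[0]
        else:
            level = spec.reference
            for lv in spec.levels:
                if lv != spec.reference and row.get(f"{factor}[{lv}]", 0):
                    level = lv
            out[factor] = level
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


class NtcpLogisticRegression(BaseEstimator):
    """Maximum-likelihood multivariate logistic NTCP model.

    A scikit-learn style estimator over cohort data frames: ``fit`` builds
    the reference-coded design matrix for ``factors`` and maximises the
    binomial log-likelihood, reporting Wald standard errors and p-values
    from the observed information.

    Parameters
    ----------
    factors :
        Prognostic factors to include; ``None`` means all 16 candidates.
    coding :
        Factor coding scheme; defaults to the standard scheme.

    Attributes
    ----------
    model_ : LogisticNtcpModel
        Fitted intercept and per-factor coefficient terms.
    design_columns_ : list of str
        Design columns in fit order.
    coef_, se_, pvalues_ : ndarray
        Coefficients, standard errors and Wald p-values per design column.
    intercept_, intercept_se_ : float
    llf_, ll_null_ : float
        Maximised and intercept-only log-likelihoods.
    """

    def __init__(self, factors: Sequence[str] | None = None, coding: CodingScheme | None = None):
        self.factors = factors
        self.coding = coding

    def fit(self, X: pd.DataFrame, y=None):
        from .factors import FACTOR_NAMES

        factors = list(self.factors) if self.factors is not None else list(FACTOR_NAMES)
        coding = self.coding or default_coding()
        if y is None:
            if "outcome" not in X.columns:
                raise ValueError("y not given and no 'outcome' column present")
            y = X["outcome"]
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcomes must be binary 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("need at least one event and one non-event")

        design, column_map = build_design_matrix(X, factors, coding)
        exog = sm.add_constant(design.to_numpy(), prepend=True, has_constant="add")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                "logistic likelihood has no finite maximiser (perfect separation "
                "or singular information matrix)"
            ) from exc
        params = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 1e3:
            raise SeparationError("logistic fit diverged; data are (quasi-)separated")

        self.design_columns_ = list(design.columns)
        self.column_map_ = column_map
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        bse = np.asarray(res.bse, dtype=float)
        self.intercept_se_ = float(bse[0])
        self.se_ = bse[1:]
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)[1:]
        self.llf_ = float(res.llf)
        self.ll_null_ = float(res.llnull)
        self.n_obs_ = int(len(y))
        self.n_events_ = int(y.sum())
        self.model_ = self._build_model(factors, coding)
        self.coding_ = coding
        return self

    def _build_model(self, factors: Sequence[str], coding: CodingScheme) -> LogisticNtcpModel:
        by_col = dict(zip(self.design_columns_, self.coef_))
        se_by_col = dict(zip(self.design_columns_, self.se_))
        p_by_col = dict(zip(self.design_columns_, self.pvalues_))
        terms: dict[str, Any] = {}
        for factor in factors:
            spec = coding.spec(factor)
            if spec.is_continuous or spec.kind == "binary":
                terms[factor] = float(by_col[factor])
            else:
                term = {int(spec.reference): 0.0}
                for lv in spec.levels:
                    col = f"{factor}[{lv}]"
                    if col in by_col:
                        term[int(lv)] = float(by_col[col])
                terms[factor] = term
        meta = {
            "log_likelihood": self.llf_,
            "ll_null": self.ll_null_,
            "n_obs": self.n_obs_,
            "n_events": self.n_events_,
            "intercept_se": self.intercept_se_,
            "standard_errors": {k: float(v) for k, v in se_by_col.items()},
            "p_values": {k: float(v) for k, v in p_by_col.items()},
        }
        return LogisticNtcpModel(self.intercept_, terms, meta)

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(self.model_.linear_predictor(X), dtype=float).reshape(-1)

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def fit_mle(
    data: pd.DataFrame,
    outcomes,
    factors: Sequence[str] | None = None,
    coding: CodingScheme | None = None,
) -> LogisticNtcpModel:
    """Fit a logistic NTCP model by maximum likelihood; see the estimator."""
    est = NtcpLogisticRegression(factors=factors, coding=coding).fit(data, outcomes)
    return est.model_


# ---------------------------------------------------------------------------
# Odds ratios


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float


def odds_ratio(beta: float, se: float = 0.0, z: float = 1.96) -> OddsRatio:
    """Odds ratio exp(beta) with Wald 95% CI exp(beta +/- 1.96 se)."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return OddsRatio(math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se))


def odds_ratio_table(model: LogisticNtcpModel) -> pd.DataFrame:
    """Per-design-column table of beta, p, OR and 95% CI for a fitted model."""
    ses = model.fit_metadata.get("standard_errors", {})
    ps = model.fit_metadata.get("p_values", {})
    rows = []
    for factor, term in model.terms.items():
        items = term.items() if isinstance(term, Mapping) else [(None, term)]
        for lv, beta in items:
            col = factor if lv is None else f"{factor}[{lv}]"
            if lv is not None and col not in ses and beta == 0.0:
                rows.append({"column": col, "beta": 0.0, "p": np.nan, "or": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "reference": True})
                continue
            se = ses.get(col)
            if se is None:
                oratio = odds_ratio(beta)
                rows.append({"column": col, "beta": beta, "p": np.nan, "or": oratio.value,
                             "ci_low": np.nan, "ci_high": np.nan, "reference": False})
            else:
                oratio = odds_ratio(beta, se)
                rows.append({"column": col, "beta": beta, "p": ps.get(col, np.nan),
                             "or": oratio.value, "ci_low": oratio.ci_low,
                             "ci_high": oratio.ci_high, "reference": False})
    rows.append({"column": "(constant)", "beta": model.intercept, "p": np.nan,
                 "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "reference": False})
    return pd.DataFrame(rows)
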