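"""L1-constrained logistic regression: shrinkage paths, ranking, nested CV.

The LASSO maximises the binomial log-likelihood subject to a budget on the
sum of absolute standardized coefficients, ``sum_j |beta_j| <= t``.  As the
budget grows, coefficients enter the model one by one; the order of entry
ranks the prognostic factors, and the tuning parameter is chosen by nested
stratified 10-fold cross-validation on the validation deviance.

The solver works in the equivalent Lagrangian (penalized) form

    min  (1/n) * sum_i logloss_i  +  lambda * sum_j |beta_j|

via cyclic coordinate descent on iteratively reweighted least-squares
approximations, with warm starts along a descending penalty grid — the
standard path algorithm for this problem.  Budget-form fits invert the
penalty-to-budget mapping by bisection and report the achieved budget.
Columns are standardized to unit variance for penalization; coefficients
are reported back on the original covariate scale.  The intercept is never
penalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from ._fastfit import newton_logit
from .factors import CodingScheme, default_coding
from .model import build_design_matrix

__all__ = [
    "LassoFit",
    "LassoPath",
    "CvResult",
    "LassoLogisticPath",
    "fit_lasso",
    "compute_path",
    "rank_factors",
    "nested_cv_select",
]

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# Standardization helpers


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Xs = np.where(ok, (X - mean) / np.where(ok, sd, 1.0), 0.0)
    return Xs, mean, np.where(ok, sd, np.inf)  # inf sd => degenerate column


def _destandardize(b0: float, beta_std: np.ndarray, mean: np.ndarray, sd: np.ndarray):
    with np.errstate(invalid="ignore"):
        beta = np.where(np.isfinite(sd), beta_std / sd, 0.0)
    intercept = b0 - float(np.sum(beta * mean))
    return intercept, beta


# ---------------------------------------------------------------------------
# Penalized coordinate-descent core (standardized scale)


def _cd_solve(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    b0: float,
    beta: np.ndarray,
    max_outer: int = 100,
    tol: float = 1e-9,
) -> tuple[float, np.ndarray, bool]:
    """One penalized fit at penalty ``lam``, warm-started at (b0, beta)."""
    n, p = Xs.shape
    beta = beta.copy()
    penalized = Xs.std(axis=0) > 1e-12  # degenerate columns never move

    def objective(b0_, beta_):
        eta = b0_ + Xs @ beta_
        return float(np.mean(np.logaddexp(0.0, eta)) - np.mean(y * eta)
                     + lam * np.abs(beta_).sum())

    prev_obj = objective(b0, beta)
    for _ in range(max_outer):
        eta = b0 + Xs @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        wn = w / n
        wsum = wn.sum()
        wxx = (wn[:, None] * Xs * Xs).sum(axis=0)
        r = z - eta  # residual of the working response
        active = np.flatnonzero(np.abs(beta) > 0)
        b0_old, beta_old = b0, beta.copy()
        for sweep in range(1000):
            # alternate full sweeps with active-set sweeps
            idx = range(p) if sweep % 10 == 0 else active
            max_delta = 0.0
            for j in idx:
                if not penalized[j]:
                    continue
                bj = beta[j]
                rho = float((wn * Xs[:, j]) @ r) + wxx[j] * bj
                bj_new = np.sign(rho) * max(abs(rho) - lam, 0.0) / wxx[j]
                if bj_new != bj:
                    r -= Xs[:, j] * (bj_new - bj)
                    beta[j] = bj_new
                    max_delta = max(max_delta, wxx[j] * (bj_new - bj) ** 2)
            # intercept
            db0 = float(wn @ r) / wsum
            if db0 != 0.0:
                b0 += db0
                r -= db0
                max_delta = max(max_delta, wsum * db0 * db0)
            active = np.flatnonzero(np.abs(beta) > 0)
            if max_delta < tol:
                break
        obj = objective(b0, beta)
        if max(abs(b0 - b0_old), float(np.max(np.abs(beta - beta_old), initial=0.0))) < 1e-7:
            return b0, beta, True
        if prev_obj - obj < 1e-11 * max(1.0, abs(prev_obj)):
            return b0, beta, True
        prev_obj = obj
    return b0, beta, False


def _lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    ybar = y.mean()
    score = np.abs(Xs.T @ (y - ybar)) / len(y)
    return float(score.max()) if score.size else 0.0


def _null_intercept(y: np.ndarray) -> float:
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return float(np.log(ybar / (1 - ybar)))


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class LassoFit:
    """One L1 fit: achieved budget, penalty and coefficients on both scales."""

    t: float
    penalty: float
    intercept: float
    coefficients: pd.Series
    coefficients_std: pd.Series
    converged: bool


@dataclass
class LassoPath:
    """A shrinkage path over a descending penalty grid."""

    columns: list[str]
    penalties: np.ndarray
    budgets: np.ndarray             # achieved sum |beta_std| per grid point
    coefs: np.ndarray               # (grid, p) original scale
    coefs_std: np.ndarray           # (grid, p) standardized scale
    intercepts: np.ndarray
    column_map: dict[str, list[str]] = field(default_factory=dict)

    def fit_at(self, i: int) -> LassoFit:
        return LassoFit(
            t=float(self.budgets[i]),
            penalty=float(self.penalties[i]),
            intercept=float(self.intercepts[i]),
            coefficients=pd.Series(self.coefs[i], index=self.columns),
            coefficients_std=pd.Series(self.coefs_std[i], index=self.columns),
            converged=True,
        )

    def to_tidy_frame(self) -> pd.DataFrame:
        """Tidy (penalty, budget, column, coefficient) rows for path plots."""
        rows = []
        for i, (lam, t) in enumerate(zip(self.penalties, self.budgets)):
            for j, col in enumerate(self.columns):
                rows.append({"penalty": lam, "t": t, "column": col,
                             "coefficient": self.coefs[i, j],
                             "coefficient_std": self.coefs_std[i, j]})
        return pd.DataFrame(rows)


@dataclass
class CvResult:
    """Nested cross-validation outcome for the LASSO tuning parameter."""

    chosen_penalty: float
    chosen_t: float
    selected_factors: list[str]
    outer_subsets: list[list[str]]
    penalties: np.ndarray
    mean_deviance: np.ndarray


# ---------------------------------------------------------------------------
# Path computation on raw design matrices


def _path_arrays(
    X: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Warm-started penalized fits along a descending penalty grid."""
    Xs, mean, sd = _standardize(X)
    p = X.shape[1]
    coefs_std = np.zeros((len(penalties), p))
    coefs = np.zeros((len(penalties), p))
    intercepts = np.zeros(len(penalties))
    budgets = np.zeros(len(penalties))
    b0 = _null_intercept(y)
    beta = np.zeros(p)
    for i, lam in enumerate(penalties):
        b0, beta, ok = _cd_solve(Xs, y, lam, b0, beta)
        if not ok:
            raise ConvergenceError(
                f"coordinate descent did not converge at penalty {lam:.3e} "
                f"(grid point {i}); sum|beta|={np.abs(beta).sum():.3f}"
            )
        coefs_std[i] = beta
        budgets[i] = np.abs(beta).sum()
        intercepts[i], coefs[i] = _destandardize(b0, beta, mean, sd)
    return coefs_std, coefs, intercepts, budgets


def default_penalty_grid(X: np.ndarray, y: np.ndarray, n_penalties: int = 100,
                         min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced descending grid from the all-zero penalty downwards."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    lam_max = _lambda_max(Xs, np.asarray(y, dtype=float))
    if lam_max <= 0:
        return np.full(max(n_penalties, 1), 0.0)
    return np.geomspace(lam_max, lam_max * min_ratio, n_penalties)


# ---------------------------------------------------------------------------
# Estimator


class LassoLogisticPath(BaseEstimator):
    """L1 shrinkage path and entry-order factor ranking over a cohort.

    Parameters
    ----------
    factors :
        Candidate prognostic factors; ``None`` means all 16.
    coding :
        Factor coding scheme (categoricals are penalized per dummy column).
    n_penalties, min_ratio :
        Penalty grid: ``n_penalties`` log-spaced values from the smallest
        penalty that zeroes every coefficient down to ``min_ratio`` of it.

    Attributes
    ----------
    path_ : LassoPath
    ranking_ : list of str
        Factors in descending order of importance (entry order).
    """

    def __init__(self, factors: Sequence[str] | None = None,
                 coding: CodingScheme | None = None,
                 n_penalties: int = 100, min_ratio: float = 1e-3):
        self.factors = factors
        self.coding = coding
        self.n_penalties = n_penalties
        self.min_ratio = min_ratio

    def _design(self, X: pd.DataFrame):
        from .factors import FACTOR_NAMES

        factors = list(self.factors) if self.factors is not None else list(FACTOR_NAMES)
        coding = self.coding or default_coding()
        design, column_map = build_design_matrix(X, factors, coding)
        return factors, design, column_map

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        factors, design, column_map = self._design(X)
        A = design.to_numpy(dtype=float)
        penalties = default_penalty_grid(A, y, self.n_penalties, self.min_ratio)
        coefs_std, coefs, intercepts, budgets = _path_arrays(A, y, penalties)
        self.factor_names_ = factors
        self.design_columns_ = list(design.columns)
        self.column_map_ = column_map
        self.path_ = LassoPath(
            columns=list(design.columns), penalties=penalties, budgets=budgets,
            coefs=coefs, coefs_std=coefs_std, intercepts=intercepts,
            column_map=column_map,
        )
        self.ranking_ = rank_factors(self.path_)
        return self


# ---------------------------------------------------------------------------
# Functional surface


def compute_path(
    design: pd.DataFrame | np.ndarray,
    outcomes,
    penalties: Sequence[float] | None = None,
    n_penalties: int = 100,
    min_ratio: float = 1e-3,
    column_map: dict[str, list[str]] | None = None,
) -> LassoPath:
    """Compute a shrinkage path on an explicit design matrix."""
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    columns = list(design.columns) if isinstance(design, pd.DataFrame) else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    if penalties is None:
        penalties = default_penalty_grid(X, y, n_penalties, min_ratio)
    penalties = np.asarray(penalties, dtype=float)
    if penalties.size == 0:
        raise ValueError("penalty grid is empty")
    order = np.argsort(penalties)[::-1]  # solve from strongest penalty down
    coefs_std, coefs, intercepts, budgets = _path_arrays(X, y, penalties[order])
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return LassoPath(
        columns=columns, penalties=penalties,
        budgets=budgets[inv], coefs=coefs[inv], coefs_std=coefs_std[inv],
        intercepts=intercepts[inv],
        column_map=column_map or {c: [c] for c in columns},
    )


def fit_lasso(
    design: pd.DataFrame | np.ndarray,
    outcomes,
    t: float,
    tol: float = 1e-6,
    max_bisect: int = 60,
) -> LassoFit:
    """L1-budget fit: maximise the likelihood subject to sum|beta_std| <= t.

    Solved by bisection on the penalty of the Lagrangian form; the reported
    ``t`` is the achieved budget, which never exceeds the requested one by
    more than the bisection tolerance.
    """
    if t < 0:
        raise ValueError("budget t must be non-negative")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    columns = list(design.columns) if isinstance(design, pd.DataFrame) else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    Xs, mean, sd = _standardize(X)
    p = X.shape[1]

    def pack(b0, beta_std, lam, converged=True):
        intercept, beta = _destandardize(b0, beta_std, mean, sd)
        return LassoFit(
            t=float(np.abs(beta_std).sum()), penalty=lam, intercept=intercept,
            coefficients=pd.Series(beta, index=columns),
            coefficients_std=pd.Series(beta_std, index=columns),
            converged=converged,
        )

    if t == 0:
        return pack(_null_intercept(y), np.zeros(p), lam=np.inf)

    # unconstrained MLE: if the budget is slack, return it directly
    Z = np.column_stack([np.ones(len(y)), Xs])
    beta_full, _, ok = newton_logit(Z, y)
    if ok and np.abs(beta_full[1:]).sum() <= t + 1e-10:
        return pack(beta_full[0], beta_full[1:], lam=0.0)

    lo, hi = 0.0, _lambda_max(Xs, y)  # t(hi)=0, t(lo)=t_mle > t
    b0, beta = _null_intercept(y), np.zeros(p)
    best = None
    for _ in range(max_bisect):
        lam = 0.5 * (lo + hi)
        b0, beta, ok = _cd_solve(Xs, y, lam, b0, beta)
        if not ok:
            raise ConvergenceError(f"no convergence at penalty {lam:.3e}")
        achieved = np.abs(beta).sum()
        if achieved <= t:
            best = (b0, beta.copy(), lam)
            hi = lam
        else:
            lo = lam
        if abs(achieved - t) <= tol * max(1.0, t):
            if achieved <= t:
                best = (b0, beta.copy(), lam)
            break
    if best is None:
        raise ConvergenceError("bisection failed to find a feasible penalty")
    return pack(*best)


def rank_factors(path: LassoPath) -> list[str]:
    """Rank factors by the budget at which they first enter the path.

    A factor enters when any of its design columns first becomes nonzero as
    the penalty relaxes.  Ties on the entry point are broken by the larger
    absolute standardized coefficient at the least-constrained fit; factors
    that never enter are ordered last by that same magnitude.
    """
    order = np.argsort(path.penalties)[::-1]  # strongest penalty first
    last = order[-1]
    col_idx = {c: j for j, c in enumerate(path.columns)}
    keys = []
    for factor, cols in path.column_map.items():
        js = [col_idx[c] for c in cols]
        entry = np.inf
        for rank_pos, i in enumerate(order):
            if np.any(np.abs(path.coefs_std[i, js]) > _ZERO_TOL):
                entry = rank_pos
                break
        magnitude = float(np.max(np.abs(path.coefs_std[last, js]), initial=0.0))
        keys.append((entry, -magnitude, factor))
    keys.sort()
    return [k[2] for k in keys]


def nested_cv_select(
    design: pd.DataFrame | np.ndarray,
    outcomes,
    folds: int = 10,
    random_state: int | None = 0,
    n_penalties: int = 100,
    min_ratio: float = 1e-3,
    penalties: Sequence[float] | None = None,
    column_map: dict[str, list[str]] | None = None,
) -> CvResult:
    """Choose the LASSO tuning parameter by nested stratified k-fold CV.

    The inner CV picks the penalty minimising the mean validation deviance;
    each outer fold reports the factor subset selected at that penalty on
    its training part, as a stability audit.  The final subset consists of
    the factors with nonzero coefficients when the full data are fitted at
    the penalty chosen by inner CV on the full data.
    """
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    columns = list(design.columns) if isinstance(design, pd.DataFrame) else [f"x{j}" for j in range(X.shape[1])]
    cmap = column_map or {c: [c] for c in columns}
    y = np.asarray(outcomes, dtype=float)
    n_events = int(y.sum())
    if min(n_events, len(y) - n_events) < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs at least {folds} events and "
            f"non-events (have {n_events} / {len(y) - n_events})"
        )
    if penalties is None:
        penalties = default_penalty_grid(X, y, n_penalties, min_ratio)
    penalties = np.asarray(penalties, dtype=float)
    grid = np.sort(penalties)[::-1]

    def inner_choose(Xa: np.ndarray, ya: np.ndarray, seed_offset: int) -> tuple[float, np.ndarray]:
        skf = StratifiedKFold(folds, shuffle=True,
                              random_state=None if random_state is None else random_state + seed_offset)
        dev = np.zeros(len(grid))
        for tr, va in skf.split(Xa, ya):
            coefs_std, coefs, intercepts, _ = _path_arrays(Xa[tr], ya[tr], grid)
            eta = intercepts[:, None] + coefs @ Xa[va].T
            pr = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            dev += (-2.0 * (np.log(pr) @ ya[va] + np.log(1 - pr) @ (1 - ya[va]))) / len(va)
        dev /= folds
        return float(grid[int(np.argmin(dev))]), dev

    def subset_at(Xa: np.ndarray, ya: np.ndarray, lam: float) -> tuple[list[str], float]:
        sub_grid = grid[grid >= lam]
        if sub_grid.size == 0 or sub_grid[-1] != lam:
            sub_grid = np.append(sub_grid, lam)
        coefs_std, _, _, budgets = _path_arrays(Xa, ya, sub_grid)
        beta = coefs_std[-1]
        sel = []
        cidx = {c: j for j, c in enumerate(columns)}
        for factor, cols in cmap.items():
            if any(abs(beta[cidx[c]]) > _ZERO_TOL for c in cols):
                sel.append(factor)
        return sel, float(budgets[-1])

    outer = StratifiedKFold(folds, shuffle=True, random_state=random_state)
    outer_subsets: list[list[str]] = []
    for k, (tr, _va) in enumerate(outer.split(X, y)):
        if min(y[tr].sum(), len(tr) - y[tr].sum()) < folds:
            raise ValueError("outer training fold too small for inner stratified CV")
        lam_k, _ = inner_choose(X[tr], y[tr], seed_offset=1 + k)
        sel_k, _ = subset_at(X[tr], y[tr], lam_k)
        outer_subsets.append(sel_k)

    lam_final, dev = inner_choose(X, y, seed_offset=0)
    selected, t_final = subset_at(X, y, lam_final)
    return CvResult(
        chosen_penalty=lam_final, chosen_t=t_final, selected_factors=selected,
        outer_subsets=outer_subsets, penalties=grid, mean_deviance=dev,
    )
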