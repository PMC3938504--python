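"""Model-size selection procedures.

Two routes to a definitive prognostic-factor set are provided:

* :class:`SuboptimalSelector` — the compact-model rule: walk the LASSO
  entry-order ranking, fit the maximum-likelihood model at each prefix,
  accept the first prefix whose Hosmer-Lemeshow p-value shows adequate
  calibration (p >= 0.05), then keep adding ranked factors only while the
  AUC still improves appreciably (relative gain >= 5% by default).

* :class:`ForwardLikelihoodSelector` — a bootstrap forward-selection
  comparator: within each bootstrap resample, factors are added greedily
  by maximised likelihood; the model order with the highest mean
  out-of-bag log-likelihood of predictions wins, and the definitive
  factors are the most frequently selected ones at that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._fastfit import newton_logit
from .factors import CodingScheme, default_coding
from .metrics import auc, hosmer_lemeshow
from .model import build_design_matrix

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "SuboptimalSelector",
    "ForwardLikelihoodSelector",
    "select_suboptimal",
    "forward_select_ll",
]


@dataclass
class SelectionStep:
    factors: list[str]
    hl_p: float | None = None
    auc: float | None = None
    mean_oob_ll: float | None = None
    accepted: bool = False
    note: str = ""


@dataclass
class SelectionTrace:
    """Audit trail of a selection walk plus the chosen factor subset."""

    method_label: str
    steps: list[SelectionStep] = field(default_factory=list)
    chosen: list[str] | None = None
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "method_label": self.method_label,
            "status": self.status,
            "chosen": self.chosen,
            "steps": [
                {"factors": s.factors, "hl_p": s.hl_p, "auc": s.auc,
                 "mean_oob_ll": s.mean_oob_ll, "accepted": s.accepted, "note": s.note}
                for s in self.steps
            ],
        }

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": [len(s.factors) for s in self.steps],
             "hl_p": [s.hl_p for s in self.steps],
             "auc": [s.auc for s in self.steps],
             "mean_oob_ll": [s.mean_oob_ll for s in self.steps],
             "accepted": [s.accepted for s in self.steps]}
        )


def _design_blocks(data: pd.DataFrame, factors: Sequence[str], coding: CodingScheme):
    design, column_map = build_design_matrix(data, factors, coding)
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    blocks = {f: [cols.index(c) for c in column_map[f]] for f in factors}
    return X, blocks


def _fit_prefix(X: np.ndarray, y: np.ndarray, cols: list[int]):
    Z = np.column_stack([np.ones(len(y)), X[:, cols]])
    beta, ll, ok = newton_logit(Z, y)
    eta = Z @ beta
    return expit(eta), ll, ok


class SuboptimalSelector(BaseEstimator):
    """Compact-model selection along a ranked factor list.

    Parameters
    ----------
    ranking :
        Factors in descending prognostic order (e.g. the LASSO entry
        order).  If ``None``, the ranking is computed by
        :class:`~ntcpx.lasso.LassoLogisticPath` on the training data.
    hl_threshold :
        Calibration gate: the first prefix whose Hosmer-Lemeshow p-value
        reaches this threshold is accepted.
    auc_gain_threshold :
        Growth rule: after the gate, a larger prefix is accepted only while
        its AUC gain over the current accepted model reaches this value.
    relative_auc_gain :
        Interpret the gain threshold as a relative change (default) or an
        absolute AUC difference.

    Attributes
    ----------
    trace_ : SelectionTrace
    selected_factors_ : list of str or None
        ``None`` when no prefix ever calibrates ("no calibrated model").
    """

    def __init__(self, ranking: Sequence[str] | None = None,
                 hl_threshold: float = 0.05, auc_gain_threshold: float = 0.05,
                 relative_auc_gain: bool = True,
                 coding: CodingScheme | None = None, hl_groups: int = 10):
        self.ranking = ranking
        self.hl_threshold = hl_threshold
        self.auc_gain_threshold = auc_gain_threshold
        self.relative_auc_gain = relative_auc_gain
        self.coding = coding
        self.hl_groups = hl_groups

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if y.min() == y.max():
            raise ValueError("need both outcome classes")
        coding = self.coding or default_coding()
        if self.ranking is None:
            from .lasso import LassoLogisticPath

            ranking = LassoLogisticPath(coding=coding).fit(X, y).ranking_
        else:
            ranking = list(self.ranking)
        if not ranking:
            raise ValueError("ranking is empty")

        A, blocks = _design_blocks(X, ranking, coding)
        trace = SelectionTrace(method_label="lasso-suboptimal")
        accepted_size = None
        accepted_auc = None
        cols: list[int] = []
        for k, factor in enumerate(ranking, start=1):
            cols = cols + blocks[factor]
            p, _ll, ok = _fit_prefix(A, y, cols)
            _stat, hl_p = hosmer_lemeshow(p, y, groups=self.hl_groups)
            a = auc(p, y)
            step = SelectionStep(factors=ranking[:k], hl_p=hl_p, auc=a,
                                 note="" if ok else "fit not fully converged")
            if accepted_size is None:
                if hl_p >= self.hl_threshold:
                    accepted_size, accepted_auc = k, a
                    step.accepted = True
                    step.note = (step.note + " calibration gate passed").strip()
            else:
                gain = (a - accepted_auc) / accepted_auc if self.relative_auc_gain else a - accepted_auc
                if gain >= self.auc_gain_threshold:
                    accepted_size, accepted_auc = k, a
                    step.accepted = True
                else:
                    trace.steps.append(step)
                    break
            trace.steps.append(step)

        if accepted_size is None:
            trace.status = "no calibrated model"
            trace.chosen = None
        else:
            trace.chosen = ranking[:accepted_size]
        self.trace_ = trace
        self.selected_factors_ = trace.chosen
        self.ranking_ = ranking
        return self


class ForwardLikelihoodSelector(BaseEstimator):
    """Bootstrap forward selection by likelihood.

    In each bootstrap resample, factors are added one at a time, each time
    picking the candidate that maximises the fitted log-likelihood; every
    model order is scored by the log-likelihood of its predictions on the
    out-of-bag records.  The order with the highest mean out-of-bag score
    across bootstraps is chosen, and the definitive factor set consists of
    the factors most frequently selected at that order.

    Parameters
    ----------
    candidates : factors to search over (default: all 16).
    n_boot : number of bootstrap resamples (2000 for a full analysis;
        smaller values give a faster, coarser search).
    max_order : largest model order to examine (default: all candidates).
    random_state : seed for resampling.
    """

    def __init__(self, candidates: Sequence[str] | None = None, n_boot: int = 2000,
                 max_order: int | None = None, random_state: int | None = 0,
                 coding: CodingScheme | None = None, max_redraws: int = 100):
        self.candidates = candidates
        self.n_boot = n_boot
        self.max_order = max_order
        self.random_state = random_state
        self.coding = coding
        self.max_redraws = max_redraws

    def fit(self, X: pd.DataFrame, y):
        from .factors import FACTOR_NAMES

        y = np.asarray(y, dtype=float)
        candidates = list(self.candidates) if self.candidates is not None else list(FACTOR_NAMES)
        if not candidates:
            raise ValueError("no candidate factors")
        coding = self.coding or default_coding()
        A, blocks = _design_blocks(X, candidates, coding)
        n = len(y)
        max_order = min(self.max_order or len(candidates), len(candidates))
        rng = np.random.default_rng(self.random_state)

        oob_ll = np.zeros((self.n_boot, max_order))
        chosen_at_order = [[] for _ in range(max_order)]
        for b in range(self.n_boot):
            for _ in range(self.max_redraws):
                idx = rng.integers(0, n, size=n)
                yb = y[idx]
                if 0.0 < yb.mean() < 1.0:
                    break
            else:
                raise RuntimeError("could not draw a two-class bootstrap resample")
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            Ab = A[idx]
            selected: list[str] = []
            cols: list[int] = []
            remaining = list(candidates)
            for order in range(max_order):
                best = None
                for f in remaining:
                    trial = cols + blocks[f]
                    Z = np.column_stack([np.ones(n), Ab[:, trial]])
                    _beta, ll, _ok = newton_logit(Z, yb, max_iter=30, tol=1e-7)
                    if best is None or ll > best[1]:
                        best = (f, ll, trial, _beta)
                    # keep the fitted beta of the winner for OOB scoring
                f, _ll, cols, beta = best
                remaining.remove(f)
                selected.append(f)
                chosen_at_order[order].append(f)
                if oob.size:
                    Zo = np.column_stack([np.ones(oob.size), A[oob][:, cols]])
                    eta = Zo @ beta
                    pr = np.clip(expit(eta), 1e-12, 1 - 1e-12)
                    oob_ll[b, order] = float(
                        np.mean(y[oob] * np.log(pr) + (1 - y[oob]) * np.log(1 - pr))
                    )
                else:
                    oob_ll[b, order] = np.nan

        mean_ll = np.nanmean(oob_ll, axis=0)
        best_order = int(np.argmax(mean_ll)) + 1
        counts = pd.Series(
            np.concatenate([chosen_at_order[o] for o in range(best_order)])
        ).value_counts()
        final = list(counts.index[:best_order])

        trace = SelectionTrace(method_label="forward-LL")
        for order in range(max_order):
            freq = pd.Series(chosen_at_order[order]).value_counts()
            trace.steps.append(SelectionStep(
                factors=list(freq.index[:1]), mean_oob_ll=float(mean_ll[order]),
                accepted=(order + 1 == best_order),
                note=f"order {order + 1}",
            ))
        trace.chosen = final
        self.trace_ = trace
        self.selected_factors_ = final
        self.order_ = best_order
        self.mean_oob_ll_ = mean_ll
        return self


def select_suboptimal(
    ranking: Sequence[str],
    data: pd.DataFrame,
    outcomes,
    hl_threshold: float = 0.05,
    auc_gain_threshold: float = 0.05,
    coding: CodingScheme | None = None,
    **kwargs,
) -> SelectionTrace:
    """Functional wrapper over :class:`SuboptimalSelector`."""
    sel = SuboptimalSelector(ranking=ranking, hl_threshold=hl_threshold,
                             auc_gain_threshold=auc_gain_threshold,
                             coding=coding, **kwargs).fit(data, outcomes)
    return sel.trace_


def forward_select_ll(
    data: pd.DataFrame,
    outcomes,
    candidates: Sequence[str] | None = None,
    n_boot: int = 2000,
    seed: int | None = 0,
    **kwargs,
) -> SelectionTrace:
    """Functional wrapper over :class:`ForwardLikelihoodSelector`."""
    sel = ForwardLikelihoodSelector(candidates=candidates, n_boot=n_boot,
                                    random_state=seed, **kwargs).fit(data, outcomes)
    return sel.trace_
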