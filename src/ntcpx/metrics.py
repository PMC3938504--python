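"""Model performance metrics: discrimination, calibration, explained variation.

Covers the standard performance panel for a fitted logistic NTCP model:

* AUC (Mann-Whitney concordance) with a stratified percentile-bootstrap
  95% confidence interval,
* Brier score and scaled Brier score (1 - Brier / Brier of the
  prevalence-only predictor),
* Nagelkerke R-squared (normalised Cox-Snell),
* Omnibus likelihood-ratio test against the intercept-only model,
* Hosmer-Lemeshow goodness-of-fit chi-square over deciles of risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "auc",
    "auc_ci",
    "brier",
    "scaled_brier",
    "nagelkerke_r2",
    "omnibus_test",
    "hosmer_lemeshow",
    "evaluate_predictions",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


def _check_classes(outcomes: np.ndarray) -> None:
    if outcomes.min() == outcomes.max():
        raise ValueError("need both outcome classes to compute discrimination metrics")


def auc(predictions, outcomes) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties count 1/2)."""
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    return float(roc_auc_score(y, np.asarray(predictions, dtype=float)))


def auc_ci(predictions, outcomes, n_boot: int = 2000, seed: int | None = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Stratified percentile-bootstrap confidence interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        im = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, im])
        stats_[b] = roc_auc_score(y[idx], p[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats_, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def brier(predictions, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    return float(np.mean((p - y) ** 2))


def scaled_brier(predictions, outcomes) -> float:
    """Brier skill relative to the prevalence-only predictor.

    1 for perfect predictions, 0 for always predicting the event rate,
    negative for a model worse than that reference.
    """
    p = np.asarray(predictions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    y = np.asarray(outcomes, dtype=float)
    prevalence = y.mean()
    reference = prevalence * (1.0 - prevalence)
    if reference == 0:
        raise ValueError("degenerate outcomes: only one class present")
    return float(1.0 - brier(p, y) / reference)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo R-squared.

    Cox-Snell R2 = 1 - exp(2 (ll_null - ll_model) / n), divided by its
    attainable maximum 1 - exp(2 ll_null / n).
    """
    if ll_model < ll_null - 1e-9:
        raise ValueError("model log-likelihood below null log-likelihood (fit bug?)")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


def omnibus_test(ll_model: float, ll_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square of the model against the null model.

    ``df`` is the number of added parameters (each indicator column of a
    categorical factor counts separately).  Returns (statistic, p).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = 2.0 * (ll_model - ll_null)
    if statistic < -1e-9:
        raise ValueError("negative likelihood-ratio statistic")
    statistic = max(statistic, 0.0)
    return float(statistic), float(stats.chi2.sf(statistic, df))


def hosmer_lemeshow(predictions, outcomes, groups: int = 10,
                    df: int | None = None) -> tuple[float, float]:
    """Hosmer-Lemeshow calibration chi-square over groups of predicted risk.

    Patients are split into ``groups`` quantile bins of predicted risk; the
    C statistic sums (observed - expected)^2 / (n_g pbar_g (1 - pbar_g))
    over bins and is referred to a chi-square with ``groups - 2`` degrees
    of freedom — the reference distribution for predictions fitted on the
    same (development) data.  Pass ``df=groups`` when scoring externally
    given probabilities.  Bins with degenerate expected counts are merged
    into their neighbour (with a logged warning), reducing the degrees of
    freedom.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < groups:
        raise ValueError(f"need at least {groups} observations for {groups} groups")
    order = np.argsort(p, kind="mergesort")
    bins = np.array_split(order, groups)

    # merge bins whose expected counts are degenerate (pbar of 0 or 1)
    merged: list[np.ndarray] = []
    for b in bins:
        pb = p[b].mean()
        if merged and (pb in (0.0, 1.0)):
            logger.warning("merging degenerate Hosmer-Lemeshow risk group")
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    # re-check the first group
    while len(merged) > 1 and p[merged[0]].mean() in (0.0, 1.0):
        logger.warning("merging degenerate Hosmer-Lemeshow risk group")
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged.pop(0)

    statistic = 0.0
    for b in merged:
        n_g = len(b)
        expected = p[b].sum()
        observed = y[b].sum()
        denom = expected * (1.0 - expected / n_g)
        if denom <= 0:
            # all predictions identical and extreme within the group
            continue
        statistic += (observed - expected) ** 2 / denom
    if df is None:
        df = len(merged) - 2
    else:
        df -= len(bins) - len(merged)
    df = max(df, 1)
    return float(statistic), float(stats.chi2.sf(statistic, df))


@dataclass
class EvaluationReport:
    """One performance row: discrimination, calibration and fit statistics."""

    label: str
    n_factors: int
    auc: float
    auc_ci: tuple[float, float]
    brier: float
    scaled_brier: float
    nagelkerke_r2: float
    omnibus_statistic: float
    omnibus_p: float
    hl_statistic: float
    hl_p: float
    n: int
    n_events: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d


def evaluate_predictions(
    predictions,
    outcomes,
    ll_model: float,
    ll_null: float,
    df: int,
    label: str = "",
    n_factors: int = 0,
    n_boot: int = 2000,
    seed: int | None = 0,
    hl_groups: int = 10,
) -> EvaluationReport:
    """Assemble the full performance panel from predictions and likelihoods."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    omni_stat, omni_p = omnibus_test(ll_model, ll_null, df)
    hl_stat, hl_p = hosmer_lemeshow(p, y, groups=hl_groups)
    return EvaluationReport(
        label=label,
        n_factors=n_factors,
        auc=auc(p, y),
        auc_ci=auc_ci(p, y, n_boot=n_boot, seed=seed),
        brier=brier(p, y),
        scaled_brier=scaled_brier(p, y),
        nagelkerke_r2=nagelkerke_r2(ll_model, ll_null, len(y)),
        omnibus_statistic=omni_stat,
        omnibus_p=omni_p,
        hl_statistic=hl_stat,
        hl_p=hl_p,
        n=len(y),
        n_events=int(y.sum()),
    )


def evaluate_model(model, data, outcomes, label: str = "", n_boot: int = 2000,
                   seed: int | None = 0, hl_groups: int = 10) -> EvaluationReport:
    """Apparent-performance panel of a fitted :class:`LogisticNtcpModel`.

    Metrics are computed on the same data the model was fitted to, which is
    how development-cohort performance tables are usually reported; honest
    out-of-sample figures require external cross-validation.
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(model.ntcp(data), dtype=float).reshape(-1)
    meta = model.fit_metadata
    ll_model = meta.get("log_likelihood")
    ll_null = meta.get("ll_null")
    if ll_model is None or ll_null is None:
        eps = 1e-12
        ll_model = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        ybar = np.clip(y.mean(), eps, 1 - eps)
        ll_null = float(np.sum(y * np.log(ybar) + (1 - y) * np.log(1 - ybar)))
    df = len(meta.get("standard_errors", {})) or sum(
        len(t) - 1 if isinstance(t, dict) else 1 for t in model.terms.values()
    )
    return evaluate_predictions(
        p, y, ll_model, ll_null, df, label=label,
        n_factors=len(model.terms), n_boot=n_boot, seed=seed, hl_groups=hl_groups,
    )
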