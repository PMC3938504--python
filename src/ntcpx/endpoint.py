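"""Endpoint derivation from the xerostomia Likert item.

The study endpoint, grade 3+ xerostomia, is a patient-rated score of 66
("quite a lot") or 100 ("a lot") on the four-point Likert item at the
follow-up time point.  Patients who already report grade 3+ xerostomia at
baseline are excluded from analysis, since the interest lies in xerostomia
induced by the radiotherapy itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .factors import LIKERT_LEVELS

__all__ = ["EndpointCohort", "derive_endpoint", "likert_to_grade3plus"]

logger = logging.getLogger(__name__)

#: Likert threshold defining grade 3+ (moderate-to-severe) xerostomia.
GRADE3_THRESHOLD = 66


def likert_to_grade3plus(score: int) -> bool:
    """True iff a Likert xerostomia score denotes grade 3+ (66 or 100)."""
    if score not in LIKERT_LEVELS:
        raise ValueError(
            f"invalid Likert score {score!r}; admissible values are {LIKERT_LEVELS}"
        )
    return score >= GRADE3_THRESHOLD


@dataclass
class EndpointCohort:
    """Analysable cohort after baseline exclusion, with the binary endpoint.

    ``included`` carries one row per analysable patient plus an ``outcome``
    column (1 = grade 3+ xerostomia at follow-up).  By construction
    ``n_assessed == len(included) + n_excluded_baseline``.
    """

    included: pd.DataFrame
    n_assessed: int
    n_excluded_baseline: int
    n_missing_followup: int
    timepoint: str

    @property
    def n_events(self) -> int:
        return int(self.included["outcome"].sum()) if len(self.included) else 0

    @property
    def event_rate_of_assessed(self) -> float:
        """Events as a fraction of all assessed patients (the reported rate)."""
        return self.n_events / self.n_assessed if self.n_assessed else float("nan")

    def summary(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "n_assessed": self.n_assessed,
            "n_excluded_baseline": self.n_excluded_baseline,
            "n_included": int(len(self.included)),
            "n_events": self.n_events,
            "n_missing_followup": self.n_missing_followup,
            "event_rate_of_assessed": self.event_rate_of_assessed,
        }


def _validate_scores(values: pd.Series, column: str) -> None:
    bad = values.dropna()[~values.dropna().isin(LIKERT_LEVELS)]
    if len(bad):
        ids = list(bad.index[:10])
        raise ValueError(
            f"{column}: invalid Likert score(s) {sorted(set(bad))} at rows {ids}"
        )


def derive_endpoint(
    cohort: pd.DataFrame,
    timepoint: Literal["3m", "12m"],
) -> EndpointCohort:
    """Dichotomise follow-up scores and apply the baseline-exclusion rule.

    Patients with a missing follow-up score at the requested time point are
    not assessed there and are dropped with a logged warning (the 12-month
    cohort is naturally smaller than the 3-month one).  Among the assessed,
    patients with a baseline score of 66+ are excluded; the rest receive the
    binary grade 3+ outcome from their follow-up score.
    """
    score_col = f"xer_score_{timepoint}"
    if score_col not in cohort.columns:
        raise KeyError(f"cohort has no column {score_col!r}")
    if "baseline_xer_score" not in cohort.columns:
        raise KeyError("cohort has no column 'baseline_xer_score'")

    scores = pd.to_numeric(cohort[score_col], errors="coerce")
    baseline = pd.to_numeric(cohort["baseline_xer_score"], errors="coerce")
    if baseline.isna().any():
        missing_ids = _ids(cohort, baseline.isna())
        raise ValueError(f"missing baseline xerostomia score for record(s) {missing_ids}")
    _validate_scores(baseline, "baseline_xer_score")
    _validate_scores(scores, score_col)

    assessed_mask = scores.notna()
    n_missing = int((~assessed_mask).sum())
    if n_missing:
        logger.warning(
            "%d record(s) missing the %s score; dropped from the %s analysis",
            n_missing, score_col, timepoint,
        )
    assessed = cohort.loc[assessed_mask]
    baseline_excluded = baseline.loc[assessed_mask] >= GRADE3_THRESHOLD

    included = assessed.loc[~baseline_excluded].copy()
    followup = scores.loc[assessed_mask].loc[~baseline_excluded]
    included["outcome"] = (followup >= GRADE3_THRESHOLD).astype(int)

    return EndpointCohort(
        included=included,
        n_assessed=int(assessed_mask.sum()),
        n_excluded_baseline=int(baseline_excluded.sum()),
        n_missing_followup=n_missing,
        timepoint=timepoint,
    )


def _ids(frame: pd.DataFrame, mask: pd.Series) -> list:
    if "id" in frame.columns:
        return list(frame.loc[mask, "id"][:10])
    return list(np.flatnonzero(mask)[:10])
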