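"""Synthetic cohort generation.

Real patient records behind the xerostomia NTCP models are not public, so
the package ships a generator that emulates their statistical structure:
continuous factors (parotid mean doses in Gy, age in years) are drawn from
scaled Beta distributions whose support matches the reported cohort ranges
and whose mode sits near the reported median; binary/ordinal factors are
drawn from the reported level frequencies; the binary grade 3+ xerostomia
outcome is drawn Bernoulli from a known logistic NTCP model (by default a
published coefficient set); and a configurable fraction of patients is
marked as already moderately-to-severely xerostomic at baseline, the
stratum the endpoint derivation excludes.

Factors are drawn independently — the source study reports no covariance
structure between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit

from .factors import FACTORS, FactorSpec
from .model import LogisticNtcpModel

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_marginals",
    "generate_cohort",
    "inject_baseline_grade3",
    "likert_frame_from_counts",
]

#: Beta concentration (a+b) for continuous factors: a moderate value giving
#: realistic within-range spread (about 19% of the range as one SD).
_BETA_CONCENTRATION = 6.0

COHORT_COLUMNS = [
    "id", "dmean_c_gy", "dmean_i_gy", "age", "gender", "education", "marriage",
    "smoking", "alcohol", "ajcc_stage", "t_stage", "node", "chemo",
    "baseline_xer_score", "family_history", "financial", "treatment_mode",
    "xer_score_3m", "xer_score_12m",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


def default_marginals() -> dict[str, FactorSpec]:
    """The standard 16-factor marginals (reported ranges and frequencies)."""
    return dict(FACTORS)


class SyntheticConfig(BaseModel):
    """Configuration of one synthetic cohort draw.

    Parameters
    ----------
    n_patients :
        Cohort size (0 gives an empty cohort).
    seed :
        Root seed; all sub-draws derive deterministic child streams.
    factor_marginals :
        Per-factor distribution specs; defaults to the reported marginals.
    true_model :
        Generating logistic NTCP model; defaults to the published 12-month
        compact (suboptimal) coefficient set.
    baseline_grade3_prevalence :
        Fraction of patients flagged with grade 3+ xerostomia already at
        baseline (the reported 3-month figure, 21/206, by default).
    timepoint_label :
        Which follow-up Likert column the generated outcome populates.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_patients: int = Field(ge=0)
    seed: int = 0
    factor_marginals: dict[str, FactorSpec] = Field(default_factory=default_marginals)
    true_model: LogisticNtcpModel | None = None
    baseline_grade3_prevalence: float = Field(default=21 / 206, ge=0.0, le=1.0)
    timepoint_label: Literal["3m", "12m"] = "12m"

    @field_validator("factor_marginals")
    @classmethod
    def _check_marginals(cls, v: dict[str, FactorSpec]) -> dict[str, FactorSpec]:
        for name, spec in v.items():
            if spec.is_continuous:
                if spec.low is None or spec.high is None or not spec.low < spec.high:
                    raise ValueError(f"{name}: continuous marginal needs low < high")
            else:
                freqs = np.asarray(spec.frequencies, dtype=float)
                if freqs.size != len(spec.levels) or freqs.sum() <= 0:
                    raise ValueError(f"{name}: frequencies must match levels and be positive")
        return v

    @model_validator(mode="after")
    def _check_model_factors(self) -> "SyntheticConfig":
        model = self.resolved_true_model()
        missing = [f for f in model.factor_set if f not in self.factor_marginals]
        if missing:
            raise ConfigurationError(f"true_model factors missing from marginals: {missing}")
        return self

    def resolved_true_model(self) -> LogisticNtcpModel:
        if self.true_model is not None:
            return self.true_model
        from .reference import published_model

        return published_model("12m", "suboptimal")

    def level_probabilities(self, factor: str) -> np.ndarray:
        spec = self.factor_marginals[factor]
        freqs = np.asarray(spec.frequencies, dtype=float)
        return freqs / freqs.sum()


@dataclass
class SyntheticCohort:
    """A generated cohort: records, generating probabilities, config echo."""

    frame: pd.DataFrame
    true_probabilities: np.ndarray
    config: SyntheticConfig

    def __len__(self) -> int:
        return len(self.frame)


def _draw_continuous(rng: np.random.Generator, spec: FactorSpec, n: int) -> np.ndarray:
    lo, hi = float(spec.low), float(spec.high)
    median = spec.median if spec.median is not None else (lo + hi) / 2
    mode_frac = np.clip((median - lo) / (hi - lo), 0.0, 1.0)
    a = 1.0 + mode_frac * (_BETA_CONCENTRATION - 2.0)
    b = _BETA_CONCENTRATION - a
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one synthetic cohort according to ``config``.

    Reproducible given the config seed: factor draws, outcome draws, Likert
    score assignment and baseline injection each consume a deterministic
    child stream of the root seed.
    """
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    rng_factors, rng_outcome, rng_scores, rng_baseline = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    data: dict[str, np.ndarray] = {}
    for name, spec in config.factor_marginals.items():
        if spec.is_continuous:
            data[name] = _draw_continuous(rng_factors, spec, n)
        else:
            probs = config.level_probabilities(name)
            data[name] = rng_factors.choice(np.asarray(spec.levels), size=n, p=probs)

    factor_frame = pd.DataFrame(data, index=pd.RangeIndex(n))
    model = config.resolved_true_model()
    if n:
        s = np.asarray(model.linear_predictor(factor_frame), dtype=float)
        p = expit(s)
        outcome = rng_outcome.binomial(1, p)
    else:
        p = np.empty(0)
        outcome = np.empty(0, dtype=int)

    # follow-up Likert item consistent with the binary endpoint
    if n:
        hi = rng_scores.choice([66, 100], size=n)
        lo = rng_scores.choice([0, 33], size=n)
        followup = np.where(outcome == 1, hi, lo)
    else:
        followup = np.empty(0, dtype=int)

    frame = pd.DataFrame(index=factor_frame.index)
    frame["id"] = [f"P{i + 1:05d}" for i in range(n)]
    frame["dmean_c_gy"] = factor_frame.get("dmean_c", np.nan)
    frame["dmean_i_gy"] = factor_frame.get("dmean_i", np.nan)
    for col in ["age", "gender", "education", "marriage", "smoking", "alcohol",
                "ajcc_stage", "t_stage", "node", "chemo", "family_history",
                "financial", "treatment_mode"]:
        if col in factor_frame:
            frame[col] = factor_frame[col]
    baseline_binary = factor_frame.get("baseline_xer", pd.Series(np.zeros(n, dtype=int), index=frame.index))
    frame["baseline_xer_score"] = np.where(np.asarray(baseline_binary) == 1, 33, 0) if n else np.empty(0, dtype=int)
    score_col = f"xer_score_{config.timepoint_label}"
    frame["xer_score_3m"] = pd.array([pd.NA] * n, dtype="Int64")
    frame["xer_score_12m"] = pd.array([pd.NA] * n, dtype="Int64")
    frame[score_col] = pd.array(followup, dtype="Int64")
    frame["outcome"] = outcome

    cohort = SyntheticCohort(frame=frame, true_probabilities=p, config=config)
    if config.baseline_grade3_prevalence > 0:
        cohort = inject_baseline_grade3(
            cohort, config.baseline_grade3_prevalence, rng=rng_baseline
        )
    return cohort


def likert_frame_from_counts(
    n_assessed: int,
    n_baseline_grade3: int,
    n_events: int,
    timepoint: str = "3m",
    seed: int = 0,
) -> pd.DataFrame:
    """A minimal Likert-score table with an exact endpoint accounting.

    ``n_baseline_grade3`` patients carry a baseline score of 66 (the
    excluded stratum); ``n_events`` of the remaining patients score 66 at
    the follow-up time point and the rest 0.  Useful for reconstructing a
    published cohort accounting from its counts.
    """
    if n_baseline_grade3 + n_events > n_assessed:
        raise ValueError("counts exceed the number of assessed patients")
    rng = np.random.default_rng(seed)
    n_included = n_assessed - n_baseline_grade3
    baseline = np.r_[np.full(n_baseline_grade3, 66), np.zeros(n_included, dtype=int)]
    followup = np.r_[rng.choice([0, 33, 66, 100], size=n_baseline_grade3),
                     np.full(n_events, 66), np.zeros(n_included - n_events, dtype=int)]
    frame = pd.DataFrame({
        "id": [f"P{i + 1:05d}" for i in range(n_assessed)],
        "baseline_xer_score": baseline,
        f"xer_score_{timepoint}": followup.astype(int),
    })
    return frame.sample(frac=1.0, random_state=seed).reset_index(drop=True)


def inject_baseline_grade3(
    cohort: SyntheticCohort,
    prevalence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Flag a fraction of records as grade 3+ xerostomic at baseline.

    Exactly ``round(prevalence * n)`` records (chosen uniformly at random)
    receive a baseline Likert score of 66, which marks them for exclusion
    when the endpoint is derived.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cohort)
    k = int(round(prevalence * n))
    frame = cohort.frame.copy()
    if k:
        idx = rng.choice(n, size=k, replace=False)
        frame.iloc[idx, frame.columns.get_loc("baseline_xer_score")] = 66
    return SyntheticCohort(frame=frame, true_probabilities=cohort.true_probabilities,
                           config=cohort.config)
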