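"""Published study quantities used as defaults and test anchors.

The source study enrolled 206 head-and-neck cancer patients treated with
IMRT, scored the single xerostomia item of the EORTC QLQ-H&N35 at baseline
and at 3 and 12 months, and reported multivariate logistic NTCP models for
moderate-to-severe (grade 3+) xerostomia at both time points — an "optimal"
factor set chosen by LASSO with nested cross-validation and a compact
"suboptimal" set chosen by a Hosmer-Lemeshow / AUC stopping rule.

This module transcribes those published artefacts:

* the reported cohort accounting (patients assessed, excluded for baseline
  grade 3+ xerostomia, and with the endpoint) per time point;
* the reported regression coefficients of the four NTCP models, on the
  printed scales (doses in Gy, age in years, categoricals reference-coded).

The coefficient sets double as the default generating truth of the
synthetic-cohort module, so simulated cohorts carry effect sizes of the
magnitude actually reported for this endpoint.
"""

from __future__ import annotations

from .model import LogisticNtcpModel

__all__ = [
    "STUDY_COUNTS",
    "published_model",
    "PUBLISHED_MODELS",
]

#: Reported patient accounting per time point: patients assessed by
#: questionnaire, patients excluded for moderate-to-severe xerostomia at
#: baseline, and patients with the grade 3+ endpoint at follow-up.
STUDY_COUNTS: dict[str, dict[str, int]] = {
    "3m": {"assessed": 206, "baseline_grade3": 21, "events": 87},
    "12m": {"assessed": 128, "baseline_grade3": 11, "events": 43},
}


def _model(intercept: float, terms: dict) -> LogisticNtcpModel:
    return LogisticNtcpModel(intercept=intercept, terms=terms)


# Reported NTCP model coefficients.  Continuous/binary factors map to a
# scalar coefficient; categorical factors map level -> coefficient with the
# reference level pinned at 0 (education printed as E(1)..E(4) corresponds
# to codes 0..3; T stage is reference-coded on T4 in the 12-month models).
PUBLISHED_MODELS: dict[tuple[str, str], LogisticNtcpModel] = {
    ("3m", "suboptimal"): _model(
        -21.298,
        {"dmean_c": 0.097, "dmean_i": 0.101, "age": 0.285},
    ),
    ("3m", "optimal"): _model(
        -22.283,
        {
            "dmean_c": 0.102,
            "dmean_i": 0.102,
            "age": 0.292,
            "financial": {0: 0.0, 1: -0.452, 2: 0.904, 3: -0.086},
            "t_stage": {1: 0.272, 2: -0.25, 3: -1.404, 4: 0.0},
            "ajcc_stage": {1: 0.0, 2: -0.481, 3: 0.455, 4: 0.560},
            "smoking": 0.187,
            "education": {0: 0.0, 1: -0.009, 2: 0.519, 3: 0.207},
        },
    ),
    ("12m", "suboptimal"): _model(
        -8.028,
        {
            "dmean_i": 0.155,
            "education": {0: 0.0, 1: -3.888, 2: -1.294, 3: -1.242},
            "dmean_c": 0.067,
            "smoking": 1.143,
            "t_stage": {1: -0.958, 2: -1.077, 3: -1.374, 4: 0.0},
        },
    ),
    ("12m", "optimal"): _model(
        -12.045,
        {
            "dmean_i": 0.176,
            "education": {0: 0.0, 1: -4.097, 2: -1.346, 3: -1.165},
            "dmean_c": 0.121,
            "smoking": 0.993,
            "t_stage": {1: -0.963, 2: -1.048, 3: -1.522, 4: 0.0},
            "baseline_xer": 0.898,
            "alcohol": 0.913,
            "family_history": -0.871,
            "node": 1.034,
        },
    ),
}

#: Reported standard-error-free odds ratios per model, for cross-checking
#: exp(beta) against the printed values.  Keys are (timepoint, kind); values
#: map a design-column-style label to the printed OR.  The 3-month optimal
#: smoking row prints an OR inconsistent with its own coefficient
#: (exp(0.187) = 1.206, printed 0.830); it is transcribed as printed and
#: flagged so callers can exclude it from consistency checks.
PUBLISHED_ODDS_RATIOS: dict[tuple[str, str], dict[str, float]] = {
    ("3m", "suboptimal"): {"dmean_c": 1.101, "dmean_i": 1.106, "age": 1.329},
    ("3m", "optimal"): {
        "dmean_c": 1.108,
        "dmean_i": 1.108,
        "age": 1.339,
        "financial[1]": 0.636,
        "financial[2]": 2.471,
        "financial[3]": 0.918,
        "t_stage[1]": 1.313,
        "t_stage[2]": 0.779,
        "t_stage[3]": 0.246,
        "ajcc_stage[2]": 0.618,
        "ajcc_stage[3]": 1.576,
        "ajcc_stage[4]": 1.751,
        "smoking": 0.830,  # inconsistent with exp(0.187); printed as-is
        "education[1]": 0.991,
        "education[2]": 1.680,
        "education[3]": 1.230,
    },
    ("12m", "suboptimal"): {
        "dmean_i": 1.167,
        "education[1]": 0.020,
        "education[2]": 0.274,
        "education[3]": 0.289,
        "dmean_c": 1.069,
        "smoking": 3.138,
        "t_stage[1]": 0.384,
        "t_stage[2]": 0.341,
        "t_stage[3]": 0.253,
    },
    ("12m", "optimal"): {
        "dmean_i": 1.193,
        "education[1]": 0.017,
        "education[2]": 0.260,
        "education[3]": 0.312,
        "dmean_c": 1.129,
        "smoking": 2.700,
        "t_stage[1]": 0.382,
        "t_stage[2]": 0.350,
        "t_stage[3]": 0.218,
        "baseline_xer": 2.455,
        "alcohol": 2.492,
        "family_history": 0.419,
        "node": 2.812,
    },
}

#: (timepoint, kind, column) labels whose printed OR is internally
#: inconsistent with the printed coefficient.
INCONSISTENT_OR_ROWS = {("3m", "optimal", "smoking")}


def published_model(timepoint: str, kind: str = "suboptimal") -> LogisticNtcpModel:
    """Return a copy of a published NTCP model.

    Parameters
    ----------
    timepoint : {"3m", "12m"}
    kind : {"suboptimal", "optimal"}
    """
    try:
        model = PUBLISHED_MODELS[(timepoint, kind)]
    except KeyError:
        raise KeyError(f"no published model for timepoint={timepoint!r}, kind={kind!r}") from None
    return model.copy()
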