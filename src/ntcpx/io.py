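"""Cohort table I/O and artifact serialisation.

The cohort file is a plain UTF-8 CSV with one row per patient and a fixed
header; Likert columns are restricted to {0, 33, 66, 100} and may be empty
when a follow-up questionnaire is missing.  Models, selection traces and
evaluation reports serialise to JSON with sorted keys so that repeat runs
with identical seeds produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .factors import FACTORS, LIKERT_LEVELS
from .model import LogisticNtcpModel

__all__ = [
    "COHORT_COLUMNS",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_json",
    "read_model",
    "write_model",
]

_LIKERT_COLUMNS = ("baseline_xer_score", "xer_score_3m", "xer_score_12m")
_CONTINUOUS_COLUMNS = {"dmean_c_gy": "dmean_c", "dmean_i_gy": "dmean_i", "age": "age"}
_LEVEL_COLUMNS = {
    spec.column: spec
    for spec in FACTORS.values()
    if not spec.is_continuous and spec.column not in _LIKERT_COLUMNS
}


class CohortValidationError(ValueError):
    """Aggregated row/column-level validation failures of a cohort table."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        shown = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} cohort validation error(s):\n{shown}{more}")


def validate_cohort(frame: pd.DataFrame) -> None:
    """Validate a cohort frame against the schema; raise on any violation."""
    errors: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError([f"missing column(s): {missing}"])
    for col, factor in _CONTINUOUS_COLUMNS.items():
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna()]
        errors += [f"row {i}: {col}: malformed number {frame.at[i, col]!r}" for i in bad]
        if col != "age":
            neg = frame.index[values <= 0]
            errors += [f"row {i}: {col}: dose must be positive" for i in neg]
    for col, spec in _LEVEL_COLUMNS.items():
        values = pd.to_numeric(frame[col], errors="coerce")
        ok = values.isin(spec.levels)
        for i in frame.index[~ok]:
            errors.append(
                f"row {i}: {col}: value {frame.at[i, col]!r} not in levels {list(spec.levels)}"
            )
    for col in _LIKERT_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        present = frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        bad = frame.index[present & ~values.isin(LIKERT_LEVELS)]
        for i in bad:
            errors.append(
                f"row {i}: {col}: value {frame.at[i, col]!r} not a Likert score {LIKERT_LEVELS}"
            )
        if col == "baseline_xer_score":
            empty = frame.index[~present]
            errors += [f"row {i}: baseline_xer_score: missing" for i in empty]
    if errors:
        raise CohortValidationError(errors)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns a typed cohort frame."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str})
    header = list(frame.columns)
    if header != COHORT_COLUMNS:
        raise CohortValidationError(
            [f"header mismatch: expected {COHORT_COLUMNS}, found {header}"]
        )
    validate_cohort(frame)
    for col in ("dmean_c_gy", "dmean_i_gy", "age"):
        frame[col] = frame[col].astype(float)
    for spec in _LEVEL_COLUMNS.values():
        frame[spec.column] = frame[spec.column].astype(int)
    frame["baseline_xer_score"] = frame["baseline_xer_score"].astype(int)
    for col in ("xer_score_3m", "xer_score_12m"):
        frame[col] = pd.array(pd.to_numeric(frame[col], errors="coerce"), dtype="Int64")
    return frame


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame to CSV in the canonical column order."""
    out = frame.reindex(columns=COHORT_COLUMNS)
    out.to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def write_model(model: LogisticNtcpModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_model(path: str | Path) -> LogisticNtcpModel:
    return LogisticNtcpModel.from_dict(json.loads(Path(path).read_text()))
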