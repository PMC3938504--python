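"""Candidate prognostic factors and their codings.

The xerostomia NTCP models draw on 16 candidate prognostic factors: two
dosimetric ones (mean dose to the contralateral and ipsilateral parotid
gland, in Gy) and 14 clinical ones (age plus binary / ordinal patient and
treatment characteristics).  This module declares each factor's type, its
admissible levels, the reference level used when expanding categoricals to
indicator columns, and the cohort marginal distribution used by the
synthetic-cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "FactorSpec",
    "CodingScheme",
    "FACTORS",
    "FACTOR_NAMES",
    "CONTINUOUS_FACTORS",
    "default_coding",
    "LIKERT_LEVELS",
]

#: Admissible values of the four-point Likert xerostomia item:
#: none (0), a little (33), quite a lot (66), a lot (100).
LIKERT_LEVELS = (0, 33, 66, 100)


@dataclass(frozen=True)
class FactorSpec:
    """Declarative description of one candidate prognostic factor.

    Parameters
    ----------
    name :
        Factor name used throughout the modelling API.
    column :
        Column holding the raw value in the cohort table (differs from
        ``name`` only for the dose columns, which carry a ``_gy`` unit
        suffix, and baseline xerostomia, which is derived from the
        baseline Likert score).
    kind :
        ``"continuous"``, ``"binary"`` or ``"categorical"``.
    levels :
        Ordered admissible levels for binary/categorical factors.
    reference :
        Default reference level (first listed level unless overridden).
    low, high, median :
        Support and centre of the cohort distribution for continuous
        factors (Gy for doses, years for age).
    frequencies :
        Cohort-level frequencies of ``levels`` (need not be normalised;
        the generator normalises).
    """

    name: str
    column: str
    kind: str
    levels: tuple[int, ...] = ()
    reference: int | None = None
    low: float | None = None
    high: float | None = None
    median: float | None = None
    frequencies: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind != "continuous":
            if not self.levels:
                raise ValueError(f"{self.name}: levels required")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(f"{self.name}: reference {ref} not a level")
            object.__setattr__(self, "reference", ref)

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"


def _f(name: str, kind: str, **kw) -> FactorSpec:
    return FactorSpec(name=name, column=kw.pop("column", name), kind=kind, **kw)


# Cohort marginals: dose/age ranges and medians, and per-level counts of the
# 3-month analysis cohort (n = 185).  Counts are normalised downstream, so a
# source table whose rows do not sum exactly to the cohort size is harmless.
FACTORS: dict[str, FactorSpec] = {
    s.name: s
    for s in [
        _f("dmean_c", "continuous", column="dmean_c_gy", low=4.9, high=68.3, median=30.6),
        _f("dmean_i", "continuous", column="dmean_i_gy", low=12.2, high=70.0, median=36.3),
        _f("age", "continuous", low=26.0, high=89.0, median=51.7),
        # 0 = female, 1 = male
        _f("gender", "binary", levels=(0, 1), frequencies=(25, 160)),
        # 0 = elementary, 1 = junior, 2 = senior, 3 = university
        _f("education", "categorical", levels=(0, 1, 2, 3), frequencies=(11, 32, 110, 32)),
        _f("marriage", "binary", levels=(0, 1), frequencies=(32, 153)),
        _f("smoking", "binary", levels=(0, 1), frequencies=(60, 125)),
        _f("alcohol", "binary", levels=(0, 1), frequencies=(73, 112)),
        _f("ajcc_stage", "categorical", levels=(1, 2, 3, 4), frequencies=(22, 18, 38, 107)),
        _f("t_stage", "categorical", levels=(1, 2, 3, 4), frequencies=(41, 64, 15, 65)),
        _f("node", "binary", levels=(0, 1), frequencies=(19, 166)),
        _f("chemo", "binary", levels=(0, 1), frequencies=(33, 152)),
        # Xerostomia before RT among analysable patients: 0 = none, 1 = a little
        _f("baseline_xer", "binary", column="baseline_xer_score", levels=(0, 1), frequencies=(75, 110)),
        _f("family_history", "binary", levels=(0, 1), frequencies=(134, 51)),
        # Household income band, 0 (lowest) .. 3 (highest)
        _f("financial", "categorical", levels=(0, 1, 2, 3), frequencies=(63, 94, 21, 7)),
        # 0 = simultaneous integrated boost (SIB), 1 = sequential mode (SQM)
        _f("treatment_mode", "binary", levels=(0, 1), frequencies=(88, 93)),
    ]
}

FACTOR_NAMES: tuple[str, ...] = tuple(FACTORS)
CONTINUOUS_FACTORS: tuple[str, ...] = tuple(n for n, s in FACTORS.items() if s.is_continuous)


@dataclass(frozen=True)
class CodingScheme:
    """Per-factor coding used to expand a cohort into a design matrix.

    Continuous factors pass through untransformed (doses stay in Gy, age in
    years, so fitted coefficients live on those scales).  Binary factors
    contribute one 0/1 column.  Categorical factors expand to
    ``len(levels) - 1`` indicator columns, omitting the reference level.
    """

    specs: Mapping[str, FactorSpec] = field(default_factory=lambda: dict(FACTORS))

    def spec(self, factor: str) -> FactorSpec:
        try:
            return self.specs[factor]
        except KeyError:
            raise KeyError(f"unknown factor {factor!r}") from None

    def with_reference(self, **references: int) -> "CodingScheme":
        """Return a scheme with the given factors' reference levels replaced."""
        specs = dict(self.specs)
        for name, ref in references.items():
            specs[name] = replace(self.spec(name), reference=ref)
        return CodingScheme(specs=specs)

    def columns_for(self, factor: str) -> list[str]:
        """Design-column names a factor expands to."""
        s = self.spec(factor)
        if s.is_continuous or s.kind == "binary":
            return [factor]
        return [f"{factor}[{lv}]" for lv in s.levels if lv != s.reference]

    def design_columns(self, factors: Sequence[str]) -> list[str]:
        cols: list[str] = []
        for f in factors:
            cols.extend(self.columns_for(f))
        return cols


def default_coding() -> CodingScheme:
    """The default coding: all 16 factors, first listed level as reference."""
    return CodingScheme()
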