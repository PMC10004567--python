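"""Candidate algorithm grid and prevalent-case identification.

An algorithm is a pair (minimum distinct coded months in the index year,
whether a confirmatory procedure is required in the lookback window). The
default grid crosses min_months 1..8 with both procedure options, giving 16
candidates; the "sensitive" family needs codes only, the "specific" family
additionally needs a chemotherapy/radiotherapy/surgery claim in the
``lookback_years`` calendar years strictly before the index year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .strata import PROCEDURE_CATEGORIES, eligible_mask

DEFAULT_CODE_ROOTS = ("C33", "C34")
DEFAULT_MIN_MONTHS = tuple(range(1, 9))


@dataclass(frozen=True)
class AlgorithmSpec:
    """One candidate phenotype definition."""

    min_months: int
    require_procedure: bool
    lookback_years: int = 3
    code_roots: tuple[str, ...] = DEFAULT_CODE_ROOTS
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.min_months <= 12:
            raise ValueError(f"min_months must be in 1..12, got {self.min_months}")
        if self.lookback_years < 1:
            raise ValueError(f"lookback_years must be >= 1, got {self.lookback_years}")
        if not self.code_roots:
            raise ValueError("code_roots must be non-empty")
        object.__setattr__(self, "code_roots", tuple(self.code_roots))
        if not self.label:
            family = "specific" if self.require_procedure else "sensitive"
            object.__setattr__(self, "label", f"{family}-m{self.min_months}")

    @property
    def family(self) -> str:
        return "specific" if self.require_procedure else "sensitive"


@dataclass(frozen=True)
class CaseSet:
    """Prevalent cases for one algorithm and index year."""

    index_year: int
    algorithm: AlgorithmSpec
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def is_lung_cancer_code(code: str, code_roots: Sequence[str] = DEFAULT_CODE_ROOTS) -> bool:
    """True iff a normalized code falls under any configured root (prefix match)."""
    return code.startswith(tuple(code_roots))


def count_code_months(
    claims: pd.DataFrame,
    person_id: str,
    index_year: int,
    code_roots: Sequence[str] = DEFAULT_CODE_ROOTS,
) -> int:
    """Distinct calendar months of the index year in which the person has at
    least one claim coded under the roots. Repeats within a month count once."""
    sel = claims[
        (claims["person_id"] == person_id)
        & (claims["year"] == index_year)
        & claims["icd10_code"].str.startswith(tuple(code_roots))
    ]
    return int(sel["month"].nunique())


def has_oncological_procedure(
    claims: pd.DataFrame, person_id: str, index_year: int, lookback_years: int = 3
) -> bool:
    """True iff the person has any chemotherapy/radiotherapy/surgery claim in
    the ``lookback_years`` calendar years strictly before the index year."""
    sel = claims[
        (claims["person_id"] == person_id)
        & claims["procedure_category"].isin(PROCEDURE_CATEGORIES)
        & (claims["year"] >= index_year - lookback_years)
        & (claims["year"] <= index_year - 1)
    ]
    return bool(len(sel))


def _coded_month_counts(
    claims: pd.DataFrame, index_year: int, code_roots: Sequence[str]
) -> pd.Series:
    sel = claims[
        (claims["year"] == index_year)
        & claims["icd10_code"].str.startswith(tuple(code_roots))
    ]
    return sel.groupby("person_id")["month"].nunique()


def identify_cases(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    spec: AlgorithmSpec,
    index_year: int,
) -> CaseSet:
    """Apply one algorithm to the claims table for an index year.

    Members are the persons affiliated at mid-year of the index year, aged
    >= 20 at index, with at least ``spec.min_months`` distinct coded months
    and — for the specific family — a lookback procedure.
    """
    elig = eligible_mask(enrollment, index_year)  # raises ConfigurationError if year absent
    eligible_ids = set(enrollment.loc[elig, "person_id"])

    month_counts = _coded_month_counts(claims, index_year, spec.code_roots)
    members = set(month_counts.index[month_counts >= spec.min_months])
    members &= eligible_ids

    if spec.require_procedure:
        proc = claims[
            claims["procedure_category"].isin(PROCEDURE_CATEGORIES)
            & (claims["year"] >= index_year - spec.lookback_years)
            & (claims["year"] <= index_year - 1)
        ]
        members &= set(proc["person_id"].unique())

    return CaseSet(index_year=index_year, algorithm=spec, members=frozenset(members))


def enumerate_algorithm_grid(
    min_months: Iterable[int] = DEFAULT_MIN_MONTHS,
    procedure_options: Iterable[bool] = (False, True),
    lookback_years: int = 3,
    code_roots: Sequence[str] = DEFAULT_CODE_ROOTS,
) -> list[AlgorithmSpec]:
    """Cartesian grid of candidate algorithms, ordered by min_months then by
    the procedure requirement (code-only first)."""
    months = sorted(set(min_months))
    options = sorted(set(bool(o) for o in procedure_options))
    if not months or not options:
        raise ConfigurationError("algorithm grid is empty")
    return [
        AlgorithmSpec(
            min_months=m,
            require_procedure=rp,
            lookback_years=lookback_years,
            code_roots=tuple(code_roots),
        )
        for m in months
        for rp in options
    ]
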