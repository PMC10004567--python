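"""Stratified prevalence rates per 100,000 with percentile-bootstrap CIs.

The resampling unit is the person: a replicate redraws enrollment rows with
replacement up to the original population size, each row carrying its
claims, and recomputes every stratum rate. Because identification is a
per-person predicate, a replicate's rate depends only on how many times
each person was drawn, so the implementation precomputes per-person case
indicators once and reweights — this is exactly equivalent to materialising
the resampled tables and re-running identification (the tests check this
against a naive oracle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .case_identification import AlgorithmSpec, CaseSet, identify_cases
from .errors import DoubleCountError, EmptyStratumError, ParameterError
from .strata import GENERAL, StratumKey, eligible_mask, stratum_mask

__all__ = [
    "StratumKey",
    "PrevalenceEstimate",
    "midyear_denominator",
    "stratum_prevalence",
    "aggregate_prevalence",
    "combine_case_sets",
    "bootstrap_ci",
]


@dataclass
class PrevalenceEstimate:
    """Numerator, denominator, rate and (optional) bootstrap CI for one
    (algorithm, year, stratum) cell."""

    algorithm_label: str
    index_year: int
    stratum: StratumKey
    numerator: int
    denominator: int
    rate_per_100k: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"numerator {self.numerator} outside [0, denominator={self.denominator}]"
            )
        expected = 100000.0 * self.numerator / self.denominator
        if abs(self.rate_per_100k - expected) > 1e-9:
            raise ValueError(
                f"rate {self.rate_per_100k} != 100000*{self.numerator}/{self.denominator}"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be set together")
        if self.ci_low is not None and self.ci_low > self.ci_high:
            raise ValueError(f"ci_low {self.ci_low} > ci_high {self.ci_high}")


def midyear_denominator(
    enrollment: pd.DataFrame, index_year: int, stratum: StratumKey = GENERAL
) -> int:
    """Persons affiliated at mid-year of the index year, aged >= 20, matching
    every non-"all" stratum field."""
    mask = eligible_mask(enrollment, index_year) & stratum_mask(enrollment, stratum, index_year)
    return int(mask.sum())


def _numerator(
    caseset: CaseSet, enrollment: pd.DataFrame, stratum: StratumKey
) -> int:
    mask = eligible_mask(enrollment, caseset.index_year)
    mask &= stratum_mask(enrollment, stratum, caseset.index_year)
    mask &= enrollment["person_id"].isin(caseset.members).to_numpy()
    return int(mask.sum())


def stratum_prevalence(
    caseset: CaseSet, enrollment: pd.DataFrame, stratum: StratumKey = GENERAL
) -> PrevalenceEstimate:
    """Point estimate (no CI) for one stratum."""
    denominator = midyear_denominator(enrollment, caseset.index_year, stratum)
    if denominator == 0:
        raise EmptyStratumError(
            f"stratum {stratum.label()!r} has an empty mid-year denominator "
            f"for {caseset.index_year}"
        )
    numerator = _numerator(caseset, enrollment, stratum)
    return PrevalenceEstimate(
        algorithm_label=caseset.algorithm.label,
        index_year=caseset.index_year,
        stratum=stratum,
        numerator=numerator,
        denominator=denominator,
        rate_per_100k=100000.0 * numerator / denominator,
    )


def aggregate_prevalence(
    contributory_numerators: Mapping | Iterable[int],
    subsidized_numerators: Mapping | Iterable[int],
    n_global: int,
    algorithm_label: str = "",
    index_year: int = 0,
) -> PrevalenceEstimate:
    """Combined-system rate: 100000 * (sum n_ijk + sum m_jk) / N_global.

    ``contributory_numerators`` are per-(region, age group, sex) case counts
    and ``subsidized_numerators`` per-(age group, sex); both may be mappings
    or plain iterables of counts. Must equal the union-case-set rate when
    the strata partition the population.
    """
    if n_global <= 0:
        raise EmptyStratumError("N_global must be positive")

    def total(counts) -> int:
        values = counts.values() if isinstance(counts, Mapping) else counts
        return int(sum(int(v) for v in values))

    numerator = total(contributory_numerators) + total(subsidized_numerators)
    return PrevalenceEstimate(
        algorithm_label=algorithm_label,
        index_year=index_year,
        stratum=GENERAL,
        numerator=numerator,
        denominator=int(n_global),
        rate_per_100k=100000.0 * numerator / n_global,
    )


def combine_case_sets(first: CaseSet, second: CaseSet) -> CaseSet:
    """Union of two case sets over disjoint populations (e.g. the two
    regimes); overlapping members indicate double counting."""
    overlap = first.members & second.members
    if overlap:
        sample = sorted(overlap)[:5]
        raise DoubleCountError(
            f"{len(overlap)} person(s) appear in both case sets (e.g. {sample})"
        )
    if first.index_year != second.index_year:
        raise ValueError("cannot combine case sets from different index years")
    return CaseSet(
        index_year=first.index_year,
        algorithm=first.algorithm,
        members=first.members | second.members,
    )


def bootstrap_ci(
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    spec: AlgorithmSpec,
    index_year: int,
    strata: Sequence[StratumKey] = (GENERAL,),
    B: int = 1000,
    seed: int = 0,
    max_chunk_elements: int = 20_000_000,
) -> list[PrevalenceEstimate]:
    """Percentile-bootstrap CIs (2.5/97.5) for every requested stratum.

    Resamples the ``len(enrollment)`` persons with replacement B times.
    Replicates in which a stratum is empty contribute rate 0 with a logged
    warning. Deterministic for a given seed.
    """
    if B < 2:
        raise ParameterError(f"bootstrap needs B >= 2 replicates, got {B}")

    caseset = identify_cases(claims, enrollment, spec, index_year)
    point = [stratum_prevalence(caseset, enrollment, s) for s in strata]

    n = len(enrollment)
    elig = eligible_mask(enrollment, index_year)
    member = enrollment["person_id"].isin(caseset.members).to_numpy() & elig
    s_masks = [stratum_mask(enrollment, s, index_year) & elig for s in strata]
    case_in_s = [member & m for m in s_masks]

    rng = np.random.default_rng(seed)
    rates = np.empty((B, len(strata)))
    chunk = max(1, max_chunk_elements // max(n, 1))
    warned = False
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        for j in range(len(strata)):
            num = case_in_s[j][idx].sum(axis=1)
            den = s_masks[j][idx].sum(axis=1)
            empty = den == 0
            if empty.any() and not warned:
                warnings.warn(
                    f"bootstrap replicate(s) with empty stratum "
                    f"{strata[j].label()!r}: contributing rate 0",
                    stacklevel=2,
                )
                warned = True
            den = np.where(empty, 1, den)
            r = 100000.0 * num / den
            rates[done : done + b, j] = np.where(empty, 0.0, r)
        done += b

    out = []
    for j, est in enumerate(point):
        lo, hi = np.percentile(rates[:, j], [2.5, 97.5])
        out.append(
            PrevalenceEstimate(
                algorithm_label=est.algorithm_label,
                index_year=index_year,
                stratum=est.stratum,
                numerator=est.numerator,
                denominator=est.denominator,
                rate_per_100k=est.rate_per_100k,
                ci_low=float(lo),
                ci_high=float(hi),
                n_boot=B,
                seed=seed,
            )
        )
    return out
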