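"""Synthetic enrollment/claims generator with known ground truth.

Persons are assigned to demographic strata, case status is drawn per index
year from the stratum's nominal prevalence, and claims are laid down so the
signal the identification algorithms look for (distinct coded months in the
index year, procedures in the lookback window) is controlled exactly by the
parameters. All randomness flows through ``numpy.random.default_rng``
(PCG64), so output is bit-reproducible for a given seed across platforms.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConsistencyError, ParameterError
from .strata import PROCEDURE_CATEGORIES, REGIONS, StratumKey

#: Default leaf codes drawn for lung-cancer-coded claims.
DEFAULT_CODE_LEAVES = ("C33", "C340", "C341", "C342", "C343", "C348", "C349")

#: Diagnosis code attached to procedure claims; deliberately outside the
#: configured malignancy roots so lookback procedures never add coded months.
PROCEDURE_CLAIM_CODE = "Z511"

_AGE_SAMPLING_BOUNDS = {"20-44": (20, 44), "45-64": (45, 64), "65+": (65, 89)}


class StratumSpec(BaseModel):
    """Population composition and nominal prevalence for one stratum."""

    regime: Literal["contributory", "subsidized"]
    sex: Literal["male", "female"]
    age_group: Literal["20-44", "45-64", "65+"]
    region: str | None = None
    weight: float = Field(ge=0.0)
    prevalence_per_100k: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_region(self) -> "StratumSpec":
        if self.regime == "contributory":
            if self.region not in REGIONS:
                raise ValueError(
                    f"contributory stratum requires a region from {REGIONS}, got {self.region!r}"
                )
        elif self.region is not None:
            raise ValueError("subsidized strata carry no region")
        return self

    def key(self) -> StratumKey:
        return StratumKey(
            regime=self.regime,
            sex=self.sex,
            age_group=self.age_group,
            region=self.region if self.region is not None else "all",
        )


def _check_pmf(v: list[float], name: str) -> list[float]:
    if len(v) != 12:
        raise ValueError(f"{name} must have 12 entries (months 1..12), got {len(v)}")
    if any(p < 0 or p > 1 for p in v):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if abs(sum(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 within 1e-9, got {sum(v)!r}")
    return v


class SimulationParams(BaseModel):
    """Full parameterisation of one synthetic dataset."""

    n_persons: int = Field(gt=0)
    index_years: list[int] = Field(min_length=1)
    lookback_years: int = Field(default=3, ge=0)
    strata: list[StratumSpec] = Field(min_length=1)
    persistence_distribution: list[float]
    false_coding_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    false_months_distribution: list[float] = Field(
        default_factory=lambda: [0.6, 0.3, 0.1] + [0.0] * 9
    )
    procedure_probability_case: float = Field(default=1.0, ge=0.0, le=1.0)
    procedure_probability_noncase: float = Field(default=0.0, ge=0.0, le=1.0)
    code_leaves: list[str] = Field(default_factory=lambda: list(DEFAULT_CODE_LEAVES))
    seed: int = 0

    @field_validator("persistence_distribution")
    @classmethod
    def _persistence_pmf(cls, v: list[float]) -> list[float]:
        return _check_pmf(v, "persistence_distribution")

    @field_validator("false_months_distribution")
    @classmethod
    def _false_pmf(cls, v: list[float]) -> list[float]:
        return _check_pmf(v, "false_months_distribution")

    @model_validator(mode="after")
    def _check_weights(self) -> "SimulationParams":
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum_weights must sum to 1 within 1e-9, got {total!r}")
        if self.lookback_years == 0 and (
            self.procedure_probability_case > 0 or self.procedure_probability_noncase > 0
        ):
            raise ValueError("procedure probabilities require lookback_years >= 1")
        return self


def generate_population(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the enrollment table and its ground-truth case table.

    Everyone is affiliated at mid-year of every index year; ages are
    sampled uniformly inside each stratum's band at the first index year.
    Returns ``(enrollment, truth)`` with one row per person in matching
    order.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_persons
    first_year = min(params.index_years)

    weights = np.array([s.weight for s in params.strata], dtype=float)
    weights = weights / weights.sum()  # guard rounding at the 1e-9 tolerance
    s_idx = rng.choice(len(params.strata), size=n, p=weights)

    lo = np.array([_AGE_SAMPLING_BOUNDS[s.age_group][0] for s in params.strata])
    hi = np.array([_AGE_SAMPLING_BOUNDS[s.age_group][1] for s in params.strata])
    ages = rng.integers(lo[s_idx], hi[s_idx] + 1)

    width = len(str(n))
    person_id = np.array([f"P{i:0{width}d}" for i in range(n)], dtype=object)
    sex = np.array([s.sex for s in params.strata], dtype=object)[s_idx]
    regime = np.array([s.regime for s in params.strata], dtype=object)[s_idx]
    region = np.array(
        [s.region if s.region is not None else "" for s in params.strata], dtype=object
    )[s_idx]
    age_group = np.array([s.age_group for s in params.strata], dtype=object)[s_idx]

    enrollment = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": first_year - ages,
            "region": region,
            "regime": regime,
        }
    )
    for y in params.index_years:
        enrollment[f"affiliated_{y}"] = True

    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "regime": regime,
            "sex": sex,
            "age_group": age_group,
            "region": region,
        }
    )
    prev = np.array([s.prevalence_per_100k for s in params.strata], dtype=float)
    p_case = prev[s_idx] / 100000.0
    for y in params.index_years:
        truth[f"is_case_{y}"] = rng.random(n) < p_case

    return enrollment, truth


def _distinct_months(rng: np.random.Generator, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each row i, pick k[i] distinct months of 1..12 uniformly.

    Returns (row_index, month) pairs for every generated claim.
    """
    n = len(k)
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    noise = rng.random((n, 12))
    rank = noise.argsort(axis=1).argsort(axis=1)  # rank of each month per row
    chosen = rank < k[:, None]
    rows, months = np.nonzero(chosen)
    return rows, months + 1


def generate_claims(
    enrollment: pd.DataFrame, truth: pd.DataFrame, params: SimulationParams
) -> pd.DataFrame:
    """Lay down coded claims and lookback procedure claims per the params.

    True cases get ``k ~ persistence_distribution`` distinct coded months in
    the index year and, with the configured probability, one procedure claim
    in the lookback window. Non-cases become false coders at
    ``false_coding_rate`` with months from ``false_months_distribution``.
    """
    if set(enrollment["person_id"]) != set(truth["person_id"]):
        raise ConsistencyError("enrollment and truth tables cover different persons")
    truth = truth.set_index("person_id").loc[enrollment["person_id"]].reset_index()

    rng = np.random.default_rng([params.seed, 1])
    ids = enrollment["person_id"].to_numpy()
    leaves = np.array(params.code_leaves, dtype=object)
    procs = np.array(PROCEDURE_CATEGORIES, dtype=object)
    persistence = np.array(params.persistence_distribution)
    false_months = np.array(params.false_months_distribution)

    parts: list[pd.DataFrame] = []

    def emit_coded(person_idx: np.ndarray, year: int, pmf: np.ndarray) -> None:
        if len(person_idx) == 0:
            return
        k = rng.choice(12, size=len(person_idx), p=pmf) + 1
        rows, months = _distinct_months(rng, k)
        codes = rng.choice(leaves, size=len(rows))
        parts.append(
            pd.DataFrame(
                {
                    "person_id": ids[person_idx[rows]],
                    "year": year,
                    "month": months,
                    "icd10_code": codes,
                    "procedure_category": "none",
                }
            )
        )

    def emit_procedures(person_idx: np.ndarray, year: int, prob: float) -> None:
        if len(person_idx) == 0 or prob == 0.0:
            return
        has = rng.random(len(person_idx)) < prob
        chosen = person_idx[has]
        if len(chosen) == 0:
            return
        p_year = rng.integers(year - params.lookback_years, year, size=len(chosen))
        p_month = rng.integers(1, 13, size=len(chosen))
        p_cat = rng.choice(procs, size=len(chosen))
        parts.append(
            pd.DataFrame(
                {
                    "person_id": ids[chosen],
                    "year": p_year,
                    "month": p_month,
                    "icd10_code": PROCEDURE_CLAIM_CODE,
                    "procedure_category": p_cat,
                }
            )
        )

    for year in params.index_years:
        is_case = truth[f"is_case_{year}"].to_numpy(dtype=bool)
        case_idx = np.flatnonzero(is_case)
        emit_coded(case_idx, year, persistence)
        emit_procedures(case_idx, year, params.procedure_probability_case)

        noncase_idx = np.flatnonzero(~is_case)
        if params.false_coding_rate > 0 and len(noncase_idx):
            is_false = rng.random(len(noncase_idx)) < params.false_coding_rate
            false_idx = noncase_idx[is_false]
            emit_coded(false_idx, year, false_months)
            emit_procedures(false_idx, year, params.procedure_probability_noncase)

    if not parts:
        return pd.DataFrame(
            columns=["person_id", "year", "month", "icd10_code", "procedure_category"]
        ).astype({"year": int, "month": int})
    claims = pd.concat(parts, ignore_index=True)
    claims = claims.sort_values(
        ["person_id", "year", "month", "icd10_code"], kind="stable"
    ).reset_index(drop=True)
    return claims


def true_prevalence(truth: pd.DataFrame, stratum: StratumKey, year: int) -> float:
    """Realized ground-truth rate per 100,000 in a stratum-year.

    Uses exact rational arithmetic before the final float conversion. The
    stratum is matched against the labels persons were *assigned* at
    generation time.
    """
    mask = np.ones(len(truth), dtype=bool)
    for name in ("regime", "sex", "age_group", "region"):
        value = getattr(stratum, name)
        if value != "all":
            mask &= (truth[name] == value).to_numpy()
    n = int(mask.sum())
    if n == 0:
        raise ParameterError(f"no persons in stratum {stratum.label()!r}")
    cases = int(truth.loc[mask, f"is_case_{year}"].sum())
    return float(Fraction(100000 * cases, n))


def write_simulation(
    out_dir: str, enrollment: pd.DataFrame, claims: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, str]:
    """Write enrollment.csv, claims.csv and truth.csv under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    claims_disk = claims.copy()
    claims_disk["service_date"] = (
        claims_disk["year"].astype(str) + "-" + claims_disk["month"].astype(str).str.zfill(2)
    )
    claims_disk = claims_disk[["person_id", "service_date", "icd10_code", "procedure_category"]]
    for name, df in (("enrollment", enrollment), ("claims", claims_disk), ("truth", truth)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths
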