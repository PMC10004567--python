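"""Stratum definitions shared across the pipeline.

A stratum is a (regime, sex, age group, region) cell; the literal ``"all"``
marks a marginalised dimension. Age groups are half-open bins
[20, 45), [45, 65), [65, inf) so that they partition the adult population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SEXES = ("male", "female")
REGIMES = ("contributory", "subsidized")
REGIONS = ("Atlantic", "Bogota", "Central", "Oriental", "Orinoquia/Amazonia", "Pacific")
AGE_GROUPS = ("20-44", "45-64", "65+")
PROCEDURE_CATEGORIES = ("chemotherapy", "radiotherapy", "surgery")

#: Half-open [lo, hi) age bounds per group.
AGE_BOUNDS = {"20-44": (20, 45), "45-64": (45, 65), "65+": (65, np.inf)}

MIN_AGE = 20


def age_group_of(age: int) -> str:
    """Return the age-group label for an integer age >= 20."""
    if age < MIN_AGE:
        raise ValueError(f"age {age} below the study floor of {MIN_AGE}")
    for label, (lo, hi) in AGE_BOUNDS.items():
        if lo <= age < hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class StratumKey:
    """One cell of the stratification grid; ``"all"`` marginalises a field."""

    regime: str = "all"
    sex: str = "all"
    age_group: str = "all"
    region: str = "all"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES + ("all",):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.sex not in SEXES + ("all",):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS + ("all",):
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.region not in REGIONS + ("all",):
            raise ValueError(f"unknown region {self.region!r}")
        # Subsidized data carry no region detail, so region-specific strata
        # are only meaningful inside the contributory regime.
        if self.region != "all" and self.regime != "contributory":
            raise ValueError(
                "region-specific strata require regime='contributory' "
                f"(got regime={self.regime!r}, region={self.region!r})"
            )

    @property
    def is_general(self) -> bool:
        return all(v == "all" for v in (self.regime, self.sex, self.age_group, self.region))

    def label(self) -> str:
        if self.is_general:
            return "general"
        parts = []
        for name in ("regime", "sex", "age_group", "region"):
            value = getattr(self, name)
            if value != "all":
                parts.append(f"{name}={value}")
        return ",".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "StratumKey":
        label = label.strip()
        if label in ("", "general"):
            return cls()
        kwargs = {}
        for part in label.split(","):
            name, _, value = part.partition("=")
            name = name.strip()
            if name not in ("regime", "sex", "age_group", "region"):
                raise ConfigurationError(f"unknown stratum field {name!r} in {label!r}")
            kwargs[name] = value.strip()
        return cls(**kwargs)


GENERAL = StratumKey()


def ages_at(enrollment: pd.DataFrame, index_year: int) -> np.ndarray:
    """Year-precision ages of every enrollment row at the index year."""
    return index_year - enrollment["birth_year"].to_numpy()


def stratum_mask(enrollment: pd.DataFrame, stratum: StratumKey, index_year: int) -> np.ndarray:
    """Boolean mask of enrollment rows matching every non-"all" stratum field.

    Age-group membership is evaluated at the index year.
    """
    mask = np.ones(len(enrollment), dtype=bool)
    if stratum.regime != "all":
        mask &= (enrollment["regime"] == stratum.regime).to_numpy()
    if stratum.sex != "all":
        mask &= (enrollment["sex"] == stratum.sex).to_numpy()
    if stratum.age_group != "all":
        lo, hi = AGE_BOUNDS[stratum.age_group]
        age = ages_at(enrollment, index_year)
        mask &= (age >= lo) & (age < hi)
    if stratum.region != "all":
        mask &= (enrollment["region"] == stratum.region).to_numpy()
    return mask


def eligible_mask(enrollment: pd.DataFrame, index_year: int) -> np.ndarray:
    """Denominator universe: affiliated at mid-year and aged >= 20 at index."""
    col = f"affiliated_{index_year}"
    if col not in enrollment.columns:
        raise ConfigurationError(
            f"enrollment table has no mid-year affiliation column for {index_year} "
            f"(expected {col!r})"
        )
    return enrollment[col].to_numpy(dtype=bool) & (ages_at(enrollment, index_year) >= MIN_AGE)


def expand_strata(dimensions: list[str], regime: str = "all") -> list[StratumKey]:
    """Expand dimension names into concrete strata (plus the general stratum).

    ``dimensions`` may contain "sex", "age_group" / "age", and "region".
    Region strata are emitted only for the contributory regime.
    """
    strata: list[StratumKey] = [StratumKey(regime=regime)]
    for dim in dimensions:
        dim = dim.strip().lower()
        if dim in ("sex",):
            strata += [StratumKey(regime=regime, sex=s) for s in SEXES]
        elif dim in ("age", "age_group"):
            strata += [StratumKey(regime=regime, age_group=a) for a in AGE_GROUPS]
        elif dim in ("region",):
            if regime in ("contributory", "all"):
                strata += [
                    StratumKey(regime="contributory", region=r) for r in REGIONS
                ]
        else:
            raise ConfigurationError(f"unknown stratification dimension {dim!r}")
    return strata
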