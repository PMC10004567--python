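"""Readers, writers, and schema validation for the pipeline's tabular files.

Tables are represented as pandas DataFrames with fixed column sets:

* enrollment — ``person_id, sex, birth_year, region, regime,
  affiliated_<year>`` (one boolean column per study year)
* claims — ``person_id, year, month, icd10_code, procedure_category``
* benchmarks — ``source, stratum, rate_per_100k``
* estimates — one row per (algorithm, year, stratum) with numerator,
  denominator, rate and CI bounds

Every reader returns the retained table together with a
:class:`ValidationReport` listing dropped rows and warnings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MalformedCodeError, SchemaError
from .strata import PROCEDURE_CATEGORIES, REGIMES, REGIONS, SEXES, StratumKey

BENCHMARK_SOURCES = ("CAC", "NCI", "GLOBOCAN")

_AFFILIATED_RE = re.compile(r"^affiliated_(\d{4})$")
_DATE_RE = re.compile(r"^(\d{4})-(\d{1,2})(?:-(\d{1,2}))?$")
_TRUTHY = {"true", "1", "t", "yes", "y"}
_FALSY = {"false", "0", "f", "no", "n", ""}


@dataclass
class EnrollmentRecord:
    """One person's demographics and per-year mid-year affiliation."""

    person_id: str
    sex: str
    birth_year: int
    regime: str
    region: str | None
    affiliated_midyear: dict[int, bool]


@dataclass
class ClaimRecord:
    """One service line: person, year-month, diagnosis code, procedure flag."""

    person_id: str
    year: int
    month: int
    icd10_code: str
    procedure_category: str = "none"


@dataclass
class BenchmarkValue:
    """One externally published rate to compare estimates against."""

    source: str
    stratum: StratumKey | str
    rate_per_100k: float

    def __post_init__(self) -> None:
        if self.rate_per_100k < 0:
            raise ValueError(f"benchmark rate must be >= 0, got {self.rate_per_100k}")
        if isinstance(self.stratum, str):
            self.stratum = StratumKey.from_label(self.stratum)


@dataclass
class ValidationReport:
    """Bookkeeping for one read: counts, dropped rows, warnings."""

    record_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    dropped_records: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def count(self, table: str, read: int, retained: int) -> None:
        self.record_counts[table] = {
            "read": read,
            "retained": retained,
            "dropped": read - retained,
        }


def normalize_icd10(code: object, record: str | None = None) -> str:
    """Upper-case a diagnosis code and strip dots and internal whitespace.

    Idempotent. Raises :class:`MalformedCodeError` for empty codes.
    """
    text = "" if code is None or (isinstance(code, float) and np.isnan(code)) else str(code)
    cleaned = "".join(text.split()).replace(".", "").upper()
    if not cleaned:
        where = f" (record {record})" if record is not None else ""
        raise MalformedCodeError(f"empty or whitespace-only ICD-10 code{where}")
    return cleaned


def _require_columns(df: pd.DataFrame, names: Iterable[str], table: str) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing mandatory column(s): {', '.join(missing)}")


def _apply_schema(df: pd.DataFrame, schema_config: Mapping[str, str] | None) -> pd.DataFrame:
    if schema_config:
        rename = {actual: logical for logical, actual in schema_config.items()}
        df = df.rename(columns=rename)
    return df


def _parse_bool(series: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY or s == "nan":
            return False
        raise SchemaError(f"cannot interpret {v!r} as a boolean affiliation flag")

    return series.map(one)


def read_enrollment(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an enrollment table.

    Rows violating the record invariants are dropped and listed in the
    report; duplicate person_ids keep the first occurrence with a warning.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df = _apply_schema(df, schema_config)
    _require_columns(df, ["person_id", "sex", "birth_year", "regime"], "enrollment")
    aff_cols = [c for c in df.columns if _AFFILIATED_RE.match(c)]
    if not aff_cols:
        raise SchemaError(
            "enrollment table is missing mandatory column(s): affiliated_<year> "
            "(at least one per study year)"
        )

    report = ValidationReport()
    n_read = len(df)

    birth = pd.to_numeric(df["birth_year"], errors="coerce")
    years = np.array([int(_AFFILIATED_RE.match(c).group(1)) for c in aff_cols])
    aff = pd.DataFrame({c: _parse_bool(df[c]) for c in aff_cols})

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        hit = mask & (reasons == "")
        reasons[hit] = reason

    flag(df["person_id"].str.strip() == "", "missing person_id")
    flag(~df["sex"].isin(SEXES), "invalid sex")
    flag(~df["regime"].isin(REGIMES), "invalid regime")
    flag(birth.isna(), "invalid birth_year")
    region_blank = df.get("region", pd.Series("", index=df.index)).str.strip() == ""
    flag((df["regime"] == "contributory") & region_blank, "missing region")
    if "region" in df.columns:
        flag(~region_blank & ~df["region"].isin(REGIONS), "invalid region")
    # age >= 0 at every affiliated year
    earliest = pd.Series(np.where(aff.to_numpy().any(axis=1),
                                  np.where(aff.to_numpy(), years, np.inf).min(axis=1),
                                  np.inf), index=df.index)
    flag(birth.notna() & (birth > earliest), "birth year after an affiliated year")

    bad = reasons != ""
    for idx in df.index[bad]:
        report.dropped_records.append((f"row {idx + 2}", reasons[idx]))

    kept = df.loc[~bad].copy()
    dup = kept["person_id"].duplicated(keep="first")
    if dup.any():
        for pid in kept.loc[dup, "person_id"].unique():
            report.warnings.append(f"duplicate person_id {pid!r}: kept first occurrence")
    kept = kept.loc[~dup]

    out = pd.DataFrame(
        {
            "person_id": kept["person_id"].str.strip(),
            "sex": kept["sex"],
            "birth_year": birth.loc[kept.index].astype(int),
            "region": kept.get("region", pd.Series("", index=kept.index)).str.strip(),
            "regime": kept["regime"],
        }
    )
    for c in aff_cols:
        out[c] = aff.loc[kept.index, c].to_numpy()
    out = out.reset_index(drop=True)

    report.count("enrollment", n_read, len(out))
    return out, report


def read_claims(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    delimiter: str = ",",
    horizon: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a claims table.

    Service dates are truncated to year-month; diagnosis codes are
    normalized; an empty procedure column defaults to ``"none"``.
    ``horizon=(first_year, last_year)`` optionally drops rows outside the
    study window.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df = _apply_schema(df, schema_config)
    _require_columns(df, ["person_id", "service_date", "icd10_code"], "claims")

    report = ValidationReport()
    n_read = len(df)

    years = np.full(len(df), -1, dtype=int)
    months = np.full(len(df), -1, dtype=int)
    codes: list[str] = []
    reasons = [""] * len(df)
    for i, (date, raw_code) in enumerate(zip(df["service_date"], df["icd10_code"])):
        m = _DATE_RE.match(str(date).strip())
        if not m or not 1 <= int(m.group(2)) <= 12:
            reasons[i] = "unparseable date"
            codes.append("")
            continue
        years[i], months[i] = int(m.group(1)), int(m.group(2))
        if horizon is not None and not horizon[0] <= years[i] <= horizon[1]:
            reasons[i] = "outside study horizon"
            codes.append("")
            continue
        try:
            codes.append(normalize_icd10(raw_code, record=f"row {i + 2}"))
        except MalformedCodeError:
            reasons[i] = "malformed icd10_code"
            codes.append("")

    proc_raw = df.get("procedure_category", pd.Series("", index=df.index))
    proc = proc_raw.str.strip().replace("", "none")
    valid_proc = proc.isin(PROCEDURE_CATEGORIES + ("none",)).to_numpy()
    for i in np.flatnonzero(~valid_proc):
        if not reasons[i]:
            reasons[i] = "invalid procedure_category"

    bad = np.array([r != "" for r in reasons])
    for i in np.flatnonzero(bad):
        report.dropped_records.append((f"row {i + 2}", reasons[i]))

    keep = ~bad
    out = pd.DataFrame(
        {
            "person_id": df["person_id"].to_numpy()[keep],
            "year": years[keep],
            "month": months[keep],
            "icd10_code": np.array(codes, dtype=object)[keep],
            "procedure_category": proc.to_numpy()[keep],
        }
    )
    report.count("claims", n_read, len(out))
    return out, report


def read_benchmarks(path: str | Path, delimiter: str = ",") -> list[BenchmarkValue]:
    """Read a benchmark table into :class:`BenchmarkValue` objects."""
    df = pd.read_csv(path, sep=delimiter, dtype={"source": str, "stratum": str})
    _require_columns(df, ["source", "stratum", "rate_per_100k"], "benchmarks")
    values = []
    for _, row in df.iterrows():
        rate = float(row["rate_per_100k"])
        if rate < 0:
            raise SchemaError(f"negative benchmark rate {rate} for source {row['source']!r}")
        values.append(BenchmarkValue(str(row["source"]), str(row["stratum"]), rate))
    return values


ESTIMATE_COLUMNS = [
    "algorithm_label",
    "index_year",
    "regime",
    "sex",
    "age_group",
    "region",
    "numerator",
    "denominator",
    "rate_per_100k",
    "ci_low",
    "ci_high",
    "n_boot",
    "seed",
]


def estimates_to_frame(estimates: Sequence) -> pd.DataFrame:
    """Flatten PrevalenceEstimate objects into the on-disk column layout."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "algorithm_label": e.algorithm_label,
                "index_year": e.index_year,
                "regime": e.stratum.regime,
                "sex": e.stratum.sex,
                "age_group": e.stratum.age_group,
                "region": e.stratum.region,
                "numerator": e.numerator,
                "denominator": e.denominator,
                "rate_per_100k": e.rate_per_100k,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_boot": e.n_boot,
                "seed": e.seed,
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: Sequence, path: str | Path, delimiter: str = ",") -> None:
    """Write estimates as delimited text, rates and CI bounds at 2 decimals."""
    if len(estimates) == 0:
        raise ValueError("refusing to write an empty estimates table")
    df = estimates_to_frame(estimates)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.2f")


def read_estimates(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read an estimates file back; rates are recomputed exactly from the
    integer numerator/denominator so downstream invariants hold."""
    df = pd.read_csv(path, sep=delimiter, keep_default_na=False,
                     na_values=[""], dtype={"regime": str, "sex": str,
                                            "age_group": str, "region": str})
    _require_columns(df, ESTIMATE_COLUMNS[:-2], "estimates")
    df["rate_per_100k"] = 100000.0 * df["numerator"] / df["denominator"]
    return df
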