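"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from claimsprev.strata import PROCEDURE_CATEGORIES


def make_enrollment(rows: list[dict], years: tuple[int, ...] = (2018,)) -> pd.DataFrame:
    """Build an enrollment frame from compact row dicts.

    Defaults: contributory male born 1970 in Bogota, affiliated everywhere.
    """
    out = []
    for row in rows:
        base = {
            "person_id": row["person_id"],
            "sex": row.get("sex", "male"),
            "birth_year": row.get("birth_year", 1970),
            "region": row.get("region", "Bogota"),
            "regime": row.get("regime", "contributory"),
        }
        for y in years:
            base[f"affiliated_{y}"] = row.get(f"affiliated_{y}", row.get("affiliated", True))
        out.append(base)
    return pd.DataFrame(out)


def make_claims(rows: list[tuple]) -> pd.DataFrame:
    """Build a claims frame from (person_id, year, month, code[, procedure])."""
    out = []
    for row in rows:
        pid, year, month, code = row[:4]
        proc = row[4] if len(row) > 4 else "none"
        out.append(
            {
                "person_id": pid,
                "year": year,
                "month": month,
                "icd10_code": code,
                "procedure_category": proc,
            }
        )
    if not out:
        return pd.DataFrame(
            columns=["person_id", "year", "month", "icd10_code", "procedure_category"]
        )
    return pd.DataFrame(out)


def brute_force_cases(claims: pd.DataFrame, enrollment: pd.DataFrame, spec, index_year: int):
    """Independent per-person month-scan oracle, written as literal loops."""
    by_person: dict[str, list[tuple]] = {}
    for c in claims.itertuples(index=False):
        by_person.setdefault(c.person_id, []).append(
            (int(c.year), int(c.month), str(c.icd10_code), c.procedure_category)
        )

    members = set()
    for p in enrollment.itertuples(index=False):
        if not bool(getattr(p, f"affiliated_{index_year}")):
            continue
        if index_year - int(p.birth_year) < 20:
            continue
        own = by_person.get(p.person_id, [])
        months = set()
        for year, month, code, _ in own:
            if year == index_year and any(code.startswith(root) for root in spec.code_roots):
                months.add(month)
        if len(months) < spec.min_months:
            continue
        if spec.require_procedure:
            found = False
            for year, _, _, proc in own:
                if (
                    index_year - spec.lookback_years <= year <= index_year - 1
                    and proc in PROCEDURE_CATEGORIES
                ):
                    found = True
                    break
            if not found:
                continue
        members.add(p.person_id)
    return members


def random_instance(rng: np.random.Generator, n_persons: int = 60, index_year: int = 2018):
    """A random small enrollment + claims pair exercising every edge:
    under-age rows, unaffiliated rows, non-matching codes, procedures in
    and out of the lookback window."""
    rows = []
    for i in range(n_persons):
        rows.append(
            {
                "person_id": f"p{i}",
                "sex": rng.choice(["male", "female"]),
                "birth_year": int(rng.integers(1930, 2005)),  # ages ~13..88
                "region": rng.choice(["Bogota", "Central", "Pacific"]),
                "regime": "contributory",
                "affiliated": bool(rng.random() < 0.9),
            }
        )
    enrollment = make_enrollment(rows, years=(index_year,))

    codes = ["C33", "C340", "C341", "C349", "C50", "J45", "Z511"]
    claim_rows = []
    for i in range(n_persons):
        for _ in range(int(rng.integers(0, 9))):
            year = int(rng.integers(index_year - 4, index_year + 1))
            month = int(rng.integers(1, 13))
            code = codes[int(rng.integers(0, len(codes)))]
            proc = (
                str(rng.choice(list(PROCEDURE_CATEGORIES)))
                if rng.random() < 0.25
                else "none"
            )
            claim_rows.append((f"p{i}", year, month, code, proc))
    return enrollment, make_claims(claim_rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_enrollment():
    return make_enrollment(
        [
            {"person_id": "a", "sex": "male", "birth_year": 1960},
            {"person_id": "b", "sex": "female", "birth_year": 1950},
            {"person_id": "c", "sex": "female", "birth_year": 1999},
            {"person_id": "d", "sex": "male", "birth_year": 1980, "affiliated": False},
        ],
        years=(2018,),
    )
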