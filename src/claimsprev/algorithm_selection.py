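"""Score grid algorithms against external benchmark rates and pick winners.

An algorithm's consistency score counts how many benchmark point values
fall inside its bootstrap CI; the absolute distance between the algorithm's
rate and the benchmarks breaks ties, then the smaller minimum-months
threshold. Scores are summed over index years, and one winner is chosen
per family (sensitive = code-only, specific = code + procedure).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .claims_io import BenchmarkValue
from .errors import PairingError, SelectionError
from .prevalence_estimation import PrevalenceEstimate

_MIN_MONTHS_RE = re.compile(r"-m(\d+)$")


@dataclass
class SelectionResult:
    """Benchmark-consistency summary for one algorithm."""

    algorithm_label: str
    family: str
    consistency_score: int
    distance: float
    selected: bool


def consistency_score(
    estimate: PrevalenceEstimate, benchmarks: Sequence[BenchmarkValue]
) -> tuple[int, float]:
    """(number of benchmarks inside the CI, sum of |rate - benchmark|)."""
    if estimate.ci_low is None or estimate.ci_high is None:
        raise ValueError("estimate has no bootstrap CI")
    if not benchmarks:
        raise ValueError("benchmarks must be non-empty")
    for b in benchmarks:
        if b.stratum != estimate.stratum:
            raise PairingError(
                f"benchmark from {b.source} is for stratum {b.stratum.label()!r} "
                f"but the estimate is for {estimate.stratum.label()!r}"
            )
    score = sum(1 for b in benchmarks if estimate.ci_low <= b.rate_per_100k <= estimate.ci_high)
    distance = sum(abs(estimate.rate_per_100k - b.rate_per_100k) for b in benchmarks)
    return score, distance


def _family_of(label: str) -> str:
    return label.split("-", 1)[0]


def _min_months_of(label: str) -> int:
    m = _MIN_MONTHS_RE.search(label)
    return int(m.group(1)) if m else 0


def select_algorithms(
    estimates: Sequence[PrevalenceEstimate],
    benchmarks: Sequence[BenchmarkValue],
) -> list[SelectionResult]:
    """Rank every algorithm within its family and flag one winner per family.

    ``estimates`` are general-stratum estimates with CIs, one per
    (algorithm, index year); scores and distances are pooled over years.
    Ranking: higher total score, then lower total distance, then lower
    min_months. Deterministic and invariant to input order.
    """
    if not estimates:
        raise SelectionError("no estimates supplied")
    totals: dict[str, dict[str, float]] = defaultdict(lambda: {"score": 0, "distance": 0.0})
    for est in estimates:
        score, distance = consistency_score(est, benchmarks)
        totals[est.algorithm_label]["score"] += score
        totals[est.algorithm_label]["distance"] += distance

    families: dict[str, list[str]] = defaultdict(list)
    for label in totals:
        families[_family_of(label)].append(label)
    for family in ("sensitive", "specific"):
        if family in families and not families[family]:
            raise SelectionError(f"no algorithms in family {family!r}")
    if not families:
        raise SelectionError("no algorithm families present")

    results: list[SelectionResult] = []
    for family in sorted(families):
        ranked = sorted(
            families[family],
            key=lambda lab: (
                -totals[lab]["score"],
                totals[lab]["distance"],
                _min_months_of(lab),
                lab,
            ),
        )
        for rank, label in enumerate(ranked):
            results.append(
                SelectionResult(
                    algorithm_label=label,
                    family=family,
                    consistency_score=int(totals[label]["score"]),
                    distance=float(totals[label]["distance"]),
                    selected=rank == 0,
                )
            )
    return results


def selected_pair(results: Sequence[SelectionResult]) -> dict[str, str]:
    """Map family -> selected algorithm label."""
    return {r.family: r.algorithm_label for r in results if r.selected}
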