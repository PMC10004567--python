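"""Publication-shaped output tables and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .algorithm_selection import SelectionResult, select_algorithms, selected_pair
from .case_identification import enumerate_algorithm_grid
from .claims_io import (
    BenchmarkValue,
    estimates_to_frame,
    read_benchmarks,
    read_claims,
    read_enrollment,
    write_estimates,
)
from .errors import ConfigurationError
from .prevalence_estimation import PrevalenceEstimate, bootstrap_ci
from .strata import AGE_GROUPS, GENERAL, REGIONS, SEXES, StratumKey, expand_strata
from .synthetic_claims import SimulationParams, generate_claims, generate_population

BENCHMARK_SOURCE_ORDER = ("CAC", "NCI", "GLOBOCAN")


def _format_cell(est: PrevalenceEstimate) -> str:
    if est.ci_low is None:
        return f"{est.rate_per_100k:.2f}"
    return f"{est.rate_per_100k:.2f} ({est.ci_low:.2f}; {est.ci_high:.2f})"


def _table_rows(strata_present: set[StratumKey], regime: str) -> list[tuple[str, StratumKey]]:
    rows: list[tuple[str, StratumKey]] = [("General prevalence", StratumKey(regime=regime))]
    rows += [(s.capitalize(), StratumKey(regime=regime, sex=s)) for s in SEXES]
    rows += [(a, StratumKey(regime=regime, age_group=a)) for a in AGE_GROUPS]
    if any(s.region != "all" for s in strata_present):
        rows += [(r, StratumKey(regime="contributory", region=r)) for r in REGIONS]
    return rows


def render_prevalence_table(
    estimates: Sequence[PrevalenceEstimate],
    benchmarks: Sequence[BenchmarkValue] = (),
    family_pair: Mapping[str, str] | None = None,
    regime: str = "all",
) -> pd.DataFrame:
    """Rows = strata (general, sex, age group, region when present); columns
    = (year, family) rate cells plus one column per benchmark source.

    Cells are formatted ``"rate (lo; hi)"`` at 2 decimals; missing cells
    render as ``"N"``.
    """
    if not estimates:
        raise ValueError("no estimates to render")
    if family_pair is None:
        labels = sorted({e.algorithm_label for e in estimates})
        family_pair = {lab.split("-", 1)[0]: lab for lab in labels}

    years = sorted({e.index_year for e in estimates})
    lookup = {(e.algorithm_label, e.index_year, e.stratum): e for e in estimates}
    strata_present = {e.stratum for e in estimates}
    rows = _table_rows(strata_present, regime)

    bench_lookup: dict[tuple[str, StratumKey], float] = {}
    for b in benchmarks:
        # benchmark strata are regime-agnostic; match on the non-regime fields
        key = StratumKey(
            sex=b.stratum.sex,
            age_group=b.stratum.age_group,
            region=b.stratum.region,
            regime="contributory" if b.stratum.region != "all" else "all",
        )
        bench_lookup[(b.source, key)] = b.rate_per_100k

    out_rows = []
    for row_label, stratum in rows:
        row: dict[str, str] = {"stratum": row_label}
        for year in years:
            for family in ("sensitive", "specific"):
                label = family_pair.get(family)
                est = lookup.get((label, year, stratum)) if label else None
                row[f"{year} {family.capitalize()}"] = _format_cell(est) if est else "N"
        bench_key = StratumKey(
            sex=stratum.sex,
            age_group=stratum.age_group,
            region=stratum.region,
            regime="contributory" if stratum.region != "all" else "all",
        )
        for source in BENCHMARK_SOURCE_ORDER:
            value = bench_lookup.get((source, bench_key))
            row[source] = "N" if value is None else f"{value:g}"
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(
    config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Execute simulate/read -> identify (grid) -> estimate (+CIs) ->
    select -> report, writing every artifact plus a reproducibility manifest.

    Config keys: ``seed``, ``index_years``, one of ``simulate`` (simulation
    params) or ``inputs`` (enrollment/claims paths), and optionally
    ``grid``, ``strata`` (dimension names), ``bootstrap.replicates``,
    ``benchmarks`` (path or inline list), ``out_dir``.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "claimsprev-output"))
    out.mkdir(parents=True, exist_ok=True)

    try:
        index_years = [int(y) for y in cfg["index_years"]]
    except KeyError as exc:
        raise ConfigurationError("config must list index_years") from exc

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = dict(cfg["simulate"])
        sim_cfg.setdefault("seed", seed)
        sim_cfg.setdefault("index_years", index_years)
        params = SimulationParams(**sim_cfg)
        enrollment, truth = generate_population(params)
        claims = generate_claims(enrollment, truth, params)
        truth.to_csv(out / "truth.csv", index=False)
    elif "inputs" in cfg:
        enrollment, _ = read_enrollment(cfg["inputs"]["enrollment"])
        claims, _ = read_claims(cfg["inputs"]["claims"])
    else:
        raise ConfigurationError("config needs either a 'simulate' or an 'inputs' section")

    # --- benchmarks -------------------------------------------------------
    benchmarks: list[BenchmarkValue] = []
    bench_cfg = cfg.get("benchmarks")
    if isinstance(bench_cfg, (str, Path)):
        benchmarks = read_benchmarks(bench_cfg)
    elif isinstance(bench_cfg, Sequence):
        benchmarks = [
            BenchmarkValue(b["source"], b.get("stratum", "general"), float(b["rate_per_100k"]))
            for b in bench_cfg
        ]

    # --- grid and strata --------------------------------------------------
    grid_cfg = cfg.get("grid", {})
    grid = enumerate_algorithm_grid(
        min_months=grid_cfg.get("min_months", range(1, 9)),
        procedure_options=grid_cfg.get("procedure_options", (False, True)),
        lookback_years=int(grid_cfg.get("lookback_years", 3)),
        code_roots=tuple(grid_cfg.get("code_roots", ("C33", "C34"))),
    )
    strata = expand_strata(cfg.get("strata", []), regime=cfg.get("regime", "all"))
    B = int(cfg.get("bootstrap", {}).get("replicates", 1000))

    # --- estimate ---------------------------------------------------------
    estimates: list[PrevalenceEstimate] = []
    for i, spec in enumerate(grid):
        for j, year in enumerate(index_years):
            run_seed = seed + 7919 * (i * len(index_years) + j + 1)
            estimates.extend(
                bootstrap_ci(claims, enrollment, spec, year, strata, B=B, seed=run_seed)
            )
    estimates_path = out / "estimates.csv"
    write_estimates(estimates, estimates_path)

    # --- select -----------------------------------------------------------
    selection: list[SelectionResult] = []
    general_benchmarks = [b for b in benchmarks if b.stratum == GENERAL]
    if general_benchmarks:
        general_estimates = [e for e in estimates if e.stratum.is_general]
        selection = select_algorithms(general_estimates, general_benchmarks)
        pd.DataFrame(
            [
                {
                    "algorithm_label": r.algorithm_label,
                    "family": r.family,
                    "score": r.consistency_score,
                    "distance": r.distance,
                    "selected": r.selected,
                }
                for r in selection
            ]
        ).to_csv(out / "selection.csv", index=False)
        pair = selected_pair(selection)
    else:
        warnings.warn("no general-stratum benchmarks configured: selection skipped")
        pair = None

    # --- report -----------------------------------------------------------
    report = render_prevalence_table(
        estimates, benchmarks, family_pair=pair, regime=cfg.get("regime", "all")
    )
    report.to_csv(out / "report.csv", index=False)

    manifest = {
        "config_sha256": _config_hash(cfg),
        "seed": seed,
        "claimsprev_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "enrollment": enrollment,
        "claims": claims,
        "estimates": estimates,
        "estimates_frame": estimates_to_frame(estimates),
        "selection": selection,
        "report": report,
        "out_dir": out,
    }
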