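# claimsprev

Computable phenotyping and prevalence estimation from administrative
health-claims tables.

The pipeline identifies prevalent patients for a condition (default:
malignant tumors of the trachea, bronchi and lungs, ICD-10 roots C33/C34)
in person-level claims data, using a grid of candidate algorithms that
cross a *minimum number of distinct coded calendar months in the index
year* (1–8) with *whether a confirmatory oncological procedure —
chemotherapy, radiotherapy or surgery — is required in the three calendar
years preceding the index year* (16 candidates in total). For every
algorithm it estimates crude prevalence rates per 100,000 affiliates,
overall and stratified by regime, sex, age group (20–44, 45–64, 65+) and
region, with percentile-bootstrap confidence intervals (persons resampled
with replacement). Algorithms are then scored against externally published
benchmark rates — how many benchmark point values fall inside the
bootstrap CI, with absolute distance and the smaller month threshold as
tie-breaks — and one winner is selected per family ("sensitive" =
codes only, "specific" = codes + procedure).

Because the real enrollment/claims databases are not publicly
distributable, the package ships a synthetic-data module that generates
enrollment and claims tables with known ground truth (configurable
stratum composition, nominal prevalence, coding persistence, false-coding
noise, and procedure probabilities), so every stage is testable offline.

## Package layout

| Module | Role |
| --- | --- |
| `claimsprev.claims_io` | schema validation and CSV readers/writers for enrollment, claims, benchmark and estimate tables |
| `claimsprev.synthetic_claims` | seeded synthetic population/claims generator with a ground-truth table |
| `claimsprev.case_identification` | the algorithm grid and case identification (`identify_cases`) |
| `claimsprev.prevalence_estimation` | stratified rates per 100,000 and percentile-bootstrap CIs |
| `claimsprev.algorithm_selection` | benchmark-consistency scoring and per-family selection |
| `claimsprev.reporting` | publication-shaped tables and the end-to-end pipeline driver |

## CLI

```bash
# generate a synthetic dataset (enrollment.csv, claims.csv, truth.csv)
claimsprev simulate --config sim.yaml --out-dir data/

# apply one algorithm for one index year
claimsprev identify --claims data/claims.csv --enrollment data/enrollment.csv \
    --year 2018 --min-months 4 --require-procedure --out cases.csv

# stratified estimates with bootstrap CIs
claimsprev estimate --claims data/claims.csv --enrollment data/enrollment.csv \
    --year 2018 --min-months 4 --strata sex,age,region \
    --boot 1000 --seed 20230310 --out estimates.csv

# score against benchmarks and pick winners
claimsprev select --estimates estimates.csv --benchmarks benchmarks.csv \
    --out selection.csv

# render the comparison table
claimsprev report --estimates estimates.csv --selection selection.csv \
    --benchmarks benchmarks.csv --out report.csv

# or run everything from one config
claimsprev run --config pipeline.yaml
```

A pipeline config names the seed, index years, either a `simulate` block
(simulation parameters) or an `inputs` block (paths to enrollment/claims
CSVs), plus optional `grid`, `strata`, `bootstrap.replicates` and
`benchmarks` entries; see `tests/test_reporting.py::demo_config` for a
complete example. Reruns with the same config are byte-identical and a
`manifest.json` records the config hash, seed and library versions.

### File formats

* enrollment CSV: `person_id, sex, birth_year, region, regime,
  affiliated_<year>` (one boolean column per study year)
* claims CSV: `person_id, service_date` (ISO `YYYY-MM` or `YYYY-MM-DD`),
  `icd10_code, procedure_category` (empty = none)
* benchmarks CSV: `source, stratum, rate_per_100k` with stratum
  `general` or e.g. `sex=male`, `age_group=45-64`, `region=Bogota`

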