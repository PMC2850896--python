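# fourcomp

A four-compartment (4C) molecular body-composition reference model with a
complete DXA method-agreement analysis (cross-sectional and change tracking)
and a synthetic two-phase athlete cohort generator, so the full pipeline runs
and is testable without any external data.

## What it does

- **`fourcomp.compartments`** — deterministic 4C arithmetic: fat mass from
  body volume, total body water, bone mineral and body weight, with the
  linear coefficients *derived* from the component densities (0.9937, 2.982,
  3.317, 1.34 g/cc; fat 0.9007) and the soft-tissue mineral model
  Ms = 0.0129·TBW; fat-free mass decomposition (protein as residual), FFM
  density and fractions; measurement-record CSV I/O.
- **`fourcomp.error_propagation`** — Dahlberg technical error of measurement
  (TEM) and CV from test-retest replicates, and quadrature propagation of
  instrument TEMs through the 4C coefficients into kg-FM / %FM units.
- **`fourcomp.agreement`** — paired t / Wilcoxon with a Shapiro normality
  gate, one-sample tests against reference constants, criterion-on-predictor
  regression with slope=1/intercept=0 tests and SEE, Bland–Altman bias and
  95% limits of agreement with diff-vs-mean trend, closed-form LOA from
  method moments, Fisher-z detectable-correlation power, covariate
  correlations.
- **`fourcomp.cohort`** — seeded generator of two-phase (weight stability →
  pre-competition) cohorts of athletes whose raw BV/TBW/BMC are derived
  exactly from latent component masses (the 4C round trip is exact by
  construction) and whose DXA values follow a calibrated conditional error
  model; optional measurement-noise injection.
- **`fourcomp.pipeline` / `fourcomp.cli`** — the study orchestrator: summary
  tables, per-phase cross-sectional DXA performance, change-tracking
  agreement, covariate scan, precision-band exclusion filter, and report
  bundles (CSV + plain text + JSON + run log).

## CLI

```bash
# simulate a 27-subject cohort (writes cohort.csv + cohort.csv.meta.json)
fourcomp simulate --seed 1 --out cohort.csv

# analyse an existing cohort CSV into a report directory
fourcomp analyze --input cohort.csv --out reports/

# simulate + analyse in one run, excluding |d%FM by DXA| < 2.9
fourcomp replicate --seed 1 --exclude-precision-band 2.9 --out reports/
```

Cohort CSVs have the header
`subject_id,phase,bw_kg,bv_l,tbw_kg,bmc_kg,dxa_fm_kg,dxa_ffm_kg`
(phase ∈ `stability|precompetition`; optional regional columns
`{trunk,arms,legs}_{fm,lst}_kg`). Generator overrides can be supplied as a
YAML file via `--config` (any `CohortConfig` field).

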