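# mbda

A toolkit for a multi-biomarker disease activity (MBDA) score for
rheumatoid arthritis: the 12-biomarker scoring algorithm (integer score
1–100 with remission/low/moderate/high categories) together with the full
development machinery around it — biomarker prioritization ranking,
CW-LASSO algorithm training (curds-and-whey shrinkage over LASSO component
models with nested 10-fold cross-validation), performance evaluation,
immunoassay QC rules, comorbidity confounding analysis, and a synthetic
cohort generator so every stage runs without external patient data.

## How scoring works

Eleven serum markers (TNF-RI, IL-6, VCAM-1, EGF, VEGF-A, YKL-40, MMP-1,
MMP-3, SAA, leptin, resistin), power-transformed (`x^0.1`), feed three
linear component models predicting TJC28, SJC28 and patient global
assessment. A 2×2 shrinkage matrix improves the two joint-count
predictions by exploiting their correlation (predicted PGA and CRP are
deliberately excluded from the shrinkage). The improved predictions are
combined with measured CRP (mg/L) in a DAS28-CRP-analogous equation

    pre = 0.56·√IPTJC + 0.28·√ISJC + 0.36·ln(CRP+1) + 0.14·PPGA + 0.96

and scaled to an integer score `clamp(round(pre·10.53 + 1), 1, 100)`
(rounding half away from zero). Categories: ≤25 remission, 26–29 low,
30–44 moderate, ≥45 high — derived from the DAS28-CRP cutoffs 2.3 / 2.7 /
4.1 through the same scaling relation.

All constants live in a config file (`src/mbda/data/default_coefficients.yaml`);
the code hard-codes nothing. The shipped per-component coefficients are
illustrative placeholders (the originally fitted values are not available
in machine-readable form); `mbda train` writes a fitted replacement.

## CLI

One entry point, `mbda`, with subcommands wiring the pipeline. Every run
writes a `*.manifest.json` next to its output (seed, config hash, paths,
version).

```bash
mbda synth --preset training-like --n 249 --seed 7 --out cohort.csv
mbda qc --cohort cohort.csv --duplicate-cv 0.1 --out qc_report.csv
mbda prioritize --cohort cohort.csv --endpoints das28crp4,cdai --out ranks.csv
mbda train --cohort cohort.csv --family cw-lasso --seed 17 --out model.yaml
mbda score --cohort cohort.csv --coeffs model.yaml --out scores.csv
mbda evaluate --scores scores.csv --truth cohort.csv --out report.json
mbda comorbid --cohort cohort.csv --measures crp,cdai,das28crp4,mbda --out comorbid.csv
mbda demo --outdir demo/   # the whole pipeline end to end
```

Cohort CSV column dictionary: `patient_id`, `visit_id`, `tjc28` (0–28),
`sjc28` (0–28), `pga` (0–10), `crp_mg_l` (≥0), optional `esr_mm_h`, `age`,
`sex`, `rf_status`, `ccp_status`, `therapy_<name>` and `comorbid_<name>`
0/1 flags; any other column is a marker concentration in pg/mL (CRP is
carried in mg/L via `crp_mg_l`). Rows failing range checks are rejected
with row-level diagnostics; missing required columns are a schema error.

## Package layout

| module | contents |
|---|---|
| `mbda.core` | domain types, power transform, cohort CSV I/O, coefficients config |
| `mbda.indices` | DAS28-CRP(4), DAS28-ESR(4), CDAI, SDAI and category maps |
| `mbda.scoring` | component predictions → shrinkage → combination → integer score |
| `mbda.qc` | duplicate-well CV flags, ±3 SD control ranges, out-of-curve imputation |
| `mbda.prioritize` | univariate FDR screening, entry-order priorities, combined/grand ranks |
| `mbda.train` | stepwise OLS/LASSO/elastic-net paths, nested 10-fold CV, CW shrinkage estimation |
| `mbda.evaluate` | AUROC (Mann–Whitney), patient-level LOOCV, change correlation, CRP share |
| `mbda.comorbid` | median ratios, age/sex-adjusted regression, BH multiplicity control |
| `mbda.synth` | latent-factor synthetic cohort generator with study-like presets |
| `mbda.cli` | the `mbda` command |
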