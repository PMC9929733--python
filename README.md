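# nextbg

Inpatient next-blood-glucose prediction analysis as a reusable, tested
pipeline. The package generates synthetic point-of-care (POC) glucose
cohorts, applies reading-level exclusion rules, computes a battery of
time-series predictors, stratifies observations by 24-hour glycemic
variability, scores predictions clinically and statistically, and compares
cross-validated regression learners.

## What it does

1. **Simulate** (`nextbg.synthetic_cohort`) — admissions with right-skewed
   reading counts (median 12, IQR 5–24), inter-reading gaps matching the
   percentiles 0.58/2.48/3.88/4.88/8.23 h, per-admission mean glucose near
   141 mg/dL, a stationary lag-1 autoregressive glucose process, four
   controllable coefficient-of-variation (CV) strata, and optional
   demographic/medication covariates.
2. **Preprocess** (`nextbg.preprocess`) — 5-minute wall-clock block
   deduplication, the 90-minute adjacency exclusion, and the >10-hour
   next-gap index-eligibility rule, with reconciled count reports.
3. **Featurize** (`nextbg.ts_predictors`, `nextbg.variability`) — per index
   observation: 14 trailing moving averages (0.5–72 h), 7 rolling
   regressions (last 3–500 observations), recursive regression,
   sample-and-hold, previous reading, and the trailing-24 h CV stratum
   (low ≤0.15 < medium ≤0.30 < high ≤0.45 < very high).
4. **Evaluate** (`nextbg.evaluation`) — squared Pearson correlation, RMSE,
   median absolute error, qualitative R² bands, and Clarke Error Grid zone
   proportions, overall, per stratum, and per clinical subpopulation.
5. **Compare learners** (`nextbg.learners`) — seeded 5-fold cross-validation
   of linear regression, partial least squares, k-nearest neighbors, and
   random forest on a row sample, with predictor-only (model A) and
   predictor-plus-covariate (model B) feature sets and fold-based 95% CIs.
6. **Orchestrate** (`nextbg.pipeline`, `nextbg.cli`) — run everything from a
   single YAML config with a reproducibility manifest; all interchange is
   plain CSV/JSON.

## CLI

```bash
nextbg run-all --config examples/config_small.yaml --out out/
```

or stage by stage:

```bash
nextbg simulate   --config cfg.yaml --out out/cohort
nextbg preprocess --cohort out/cohort --out out
nextbg featurize  --cohort out/cohort --preprocessed out --out out/prediction_rows.csv
nextbg evaluate   --rows out/prediction_rows.csv --out out --plot
nextbg ml-compare --rows out/prediction_rows.csv --config cfg.yaml --out out
nextbg report     --out-dir out
```

Outputs: `table2_r2.csv` (predictor × stratum R²), `table3_clarke.csv`
(zone proportions by population), `table4_learners.csv` (cross-validated
learner metrics with CIs), `metrics.json`, `manifest.json`, and `report.md`
with an error-grid figure and an example-admission predictor overlay.

Example config:

```yaml
cohort:
  n_admissions: 500
  seed: 11
  ar_coefficient: 0.7
  covariate_flags: true
learners:
  sample_size: 10000   # capped at the available rows
  n_folds: 5
  seed: 12
  feature_sets: [model_A, model_B]
```

## Notes

- Rolling-regression extrapolations are floored at 1 mg/dL so every emitted
  prediction is physically positive.
- The "within 90 minutes" and "within 10 hours" rules are inclusive
  (≤90 min, ≤600 min); CV band boundaries belong to the lower stratum.
- Readings excluded by the 10-hour rule stay available as lookback history;
  they are only barred from being index rows.
- A Cubist-style rule-ensemble learner slot exists in the registry; with no
  faithful implementation available it is skipped and the substitution is
  recorded in `ml_metadata.json`.
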