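# lrtrial

Likely-responder causal re-analysis of two-arm randomized trials.

Given a subject-level trial table (treatment arm, baseline scale items,
drinking outcomes), the pipeline:

1. derives the primary outcome — the change in heavy-drinking-day count
   between the 28-day baseline window and the final 28-day maintenance
   window, with missing days counted as heavy;
2. fills missing baseline items by chained-equations imputation;
3. fits a regression forest on the **active arm only** to predict each
   subject's response to active treatment, then scores *every* subject
   (counterfactually for the placebo arm) — a prognostic balancing score;
4. classifies **likely responders** (predicted change ≥ 14 days, which
   guarantees ≥ 50% of any feasible baseline);
5. partitions rank-ordered scores into contiguous quantile strata and tests
   the treatment difference within strata and pooled, by OLS with treatment,
   centered baseline count, stratum, and treatment-by-stratum terms;
6. controls family-wise error across the two primary hypotheses (responder
   subgroup first, whole sample second) by **closed testing** at α = 0.05;
7. compares responder groups at baseline (rank-sum / chi-square) and at
   study end (arm × responder cell-means contrasts); and
8. estimates per-feature **risk differences**: the median change in
   predicted response caused by a one-unit increment of a single baseline
   item, with bootstrap intervals and a pairwise-additivity check.

A synthetic-trial generator with known heterogeneous treatment effects
(block-correlated scale items, feature-dependent effect, MAR missingness,
oracle potential outcomes) stands in for unavailable clinical data and backs
the validation suite.

## CLI

Every stage is a subcommand; `run-all` drives the whole pipeline from one
YAML config with a master seed that deterministically sub-seeds every
stochastic stage (re-runs are byte-identical).

```bash
# end to end from a config
lrtrial run-all --config pipeline.yaml

# or stage by stage
lrtrial simulate --config sim.yaml --out-trial trial.csv \
    --out-oracle oracle.csv --out-schema schema.yaml
lrtrial impute   --trial trial.csv --schema schema.yaml --out imputed.csv
lrtrial fit      --trial imputed.csv --schema schema.yaml \
    --out-scores scores.csv --out-diagnostics diag.json
lrtrial classify --scores scores.csv --out labels.csv
lrtrial stratify --scores scores.csv --k 5 --out strata_full.csv
lrtrial stratify --scores scores.csv --k 2 --labels labels.csv \
    --out strata_lr.csv
lrtrial test     --trial imputed.csv --schema schema.yaml \
    --strata-lr strata_lr.csv --strata-full strata_full.csv \
    --out-lr table_lr.csv --out-full table_full.csv \
    --out-verdict closed_test.json
lrtrial compare  --trial imputed.csv --schema schema.yaml \
    --labels labels.csv --out-baseline table1.csv --out-secondary table4.csv
lrtrial riskdiff --trial imputed.csv --schema schema.yaml --out table5.csv
```

A minimal pipeline config (see `lrtrial.cli_reporting.PipelineConfig`):

```python
from lrtrial import default_pipeline_config, run_pipeline
cfg = default_pipeline_config(n_subjects=338, master_seed=7,
                              out_dir="out", n_trees=1000)
run_pipeline(cfg)   # writes trial/imputed CSVs, tables 1–5 analogues,
                    # QQ pairs, monthly summaries, closed-test verdict,
                    # and a run manifest
```

## Layout

| module | role |
|---|---|
| `lrtrial.trial_data` | data model, validation, CSV I/O, outcome derivation |
| `lrtrial.synthetic_trial` | trial simulator with oracle effects |
| `lrtrial.imputation` | chained-equations imputation (PMM / normal draws) |
| `lrtrial.response_model` | active-arm regression forest, OOB diagnostics |
| `lrtrial.responder_stratification` | responder labels, quantile strata, balance |
| `lrtrial.causal_testing` | stratified OLS, pooled contrasts, closed testing |
| `lrtrial.group_comparisons` | baseline and end-of-study group contrasts |
| `lrtrial.risk_difference` | perturbation risk differences, additivity |
| `lrtrial.cli_reporting` / `lrtrial.cli` | pipeline orchestration and CLI |
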