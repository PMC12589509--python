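# brainsex

A tested, reusable pipeline for studying a **brain-sex classification
continuum** in simulated longitudinal morphometric cohorts: covariate-
constrained 1:1 female–male matching, multi-site ComBat-style harmonization,
eTIV residualization, nested cross-validated gradient boosting that maps
regional brain volumes to P(female), and linear mixed-effects association
batteries (age, pubertal development, menarche onset, mental health) with
sequential (type I) and marginal (type II) ANOVA and Benjamini–Hochberg
correction.

Because the motivating analyses were developed on restricted-access cohorts,
the package ships a first-class **synthetic cohort generator** that emulates
the relevant statistical structure — sex differences in intracranial volume
(males ~10% larger by default), per-feature eTIV scaling, sex-specific age
slopes, puberty effects concentrated on a designated "limbic" feature subset,
additive/multiplicative site effects, subject random intercepts across two
sessions, earlier female pubertal onset, menarche status, and a latent
distress factor coupled (in females) to limbic female-likeness. Every
injected effect is written to a hidden-truth sidecar so downstream stages can
be validated against ground truth.

## Layout

| module                  | role |
|-------------------------|------|
| `brainsex.synthetic`    | generative model: cohorts, PDS tables, questionnaire items |
| `brainsex.harmonization`| parametric empirical-Bayes ComBat, cross-sectional + longitudinal |
| `brainsex.prep`         | Euler-number QC, greedy 1:1 matching, balance diagnostics |
| `brainsex.features`     | limbic / non-limbic / whole-brain partition registry, eTIV residualization |
| `brainsex.classifier`   | nested 5-fold CV gradient boosting, AUC, gain-share importances |
| `brainsex.longitudinal` | LME association models, type I/II ANOVA, PDS scoring, menarche groups, site filter, BH-FDR |
| `brainsex.mental`       | baseline PCA (PC1) mental-health score with loading projection to follow-up |
| `brainsex.pipeline`     | end-to-end orchestration and reporting |

## CLI

```bash
brainsex simulate  --seed 1 --out out/sim          # cohort + puberty + items + truth
brainsex harmonize --cohort cohort.csv --variant long --covariates sex,age_months --out adj.csv
brainsex qc-match  --cohort adj.csv --out out/match
brainsex train     --cohort matched.csv --features limbic --n-limbic 20 --n-nonlimbic 40 --out out/models
brainsex run-all   --seed 1 --out out/run          # full study replica
```

`run-all` writes every intermediate table (CSV), model artifact (JSON), tidy
association results and a markdown report under the output directory.

## Notes

- Defaults follow the stated methods where given: matching thresholds
  (12 months age, 3% eTIV, 1 SD Euler), Euler QC at 3 SD below the mean,
  boosting with learning rate 0.01 and 1000 initial rounds, labels coded
  males = 0 / females = 1, PDS items 1–4 with the menstruation item No = 1 /
  Yes = 4, site filter at 20 observations.
- The demo pipeline configuration scales the boosting budget down
  (`learning_rate 0.05, 150 rounds`) to fit CI budgets; the full-scale
  defaults live in `TrainingParams`.
- Effect magnitudes of the generator are free parameters: the source
  analyses report no generative effect sizes beyond the eTIV sex ratio and
  the 1–2 year earlier female pubertal onset.
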