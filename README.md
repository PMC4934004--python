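# affectdyn

Mixed-effects location-scale modelling of affect dynamics in e-diary
(ecological momentary assessment) data. The package decomposes affective
dysregulation into three person-level subcomponents —

* **homebase** — the baseline attractor state (person-specific intercept),
* **variability** — moment-to-moment fluctuation around the homebase
  (within-person residual variance, log-linear in group dummies or
  person-specific),
* **attractor strength** — the pull back to baseline (inversely reflected by
  the autoregressive slope of the lagged outcome),

and estimates group differences in all three simultaneously, in two
frameworks:

1. a **frequentist** two-level AR(1) model with correlated random intercept
   and slope and group-specific log-linear within-person variance, fitted by
   full maximum likelihood (closed-form marginal likelihood, GLS-profiled
   fixed effects, multi-start quasi-Newton), with Wald tables using the
   persons-minus-coefficients df convention;
2. a **Bayesian** extension with person-specific within-person variances:
   person triplets (homebase, slope, log variance) drawn from group-specific
   trivariate normal populations with a shared covariance, sampled by
   Metropolis-within-Gibbs (vague normal priors with variance 1000, slope
   means truncated to (−1, 1), inverse-Wishart(I, 4) population covariance;
   4 chains × 5000 burn-in + 2500 kept by default) with classic
   Gelman–Rubin diagnostics, per-person posterior means, and group-density
   plots.

A fully seeded synthetic e-diary generator (stationary within-day AR(1)
dynamics, day-boundary chain breaks, optional Likert discretization and
non-compliance, emotion/intensity item coding) provides test beds for both
study designs (15-minute × 24 h and hourly × 48 h protocols).

## CLI

```sh
affectdyn simulate   --config examples/demo_study.yaml --seed 1 --out sim.csv
affectdyn preprocess --data sim.csv --outcome distress --out analysis.csv
affectdyn fit-freq   --data analysis.csv --reference-group BPD --out table.csv
affectdyn fit-bayes  --data analysis.csv --reference-group BPD \
                     --chains 4 --burn-in 5000 --keep 2500 --seed 1 --outdir bayes/
affectdyn run        --config examples/demo_pipeline.yaml --outdir out/
```

`fit-freq --pooled-patients` collapses all non-reference groups into one
dummy (healthy-controls-vs-all-patients contrast). `run` executes the full
pipeline (simulate → preprocess → fit-freq → fit-bayes → report), writing
coefficient tables (CSV + text), posterior draws, a convergence report,
per-person posterior means and group-density plots (SVG); reruns with the
same config are bit-identical for frequentist outputs and draw-identical
for Bayesian outputs.

### Data format

Long CSV, one row per answered prompt item:

```
person_id, group, day, prompt_index, item, intensity, pleasantness, distress
```

`item` is `distress`, an emotion label, or `no emotion`; `pleasantness`
(pleasant/unpleasant) is only needed for "emotion but cannot name it".
Unanswered prompts are absent rows — `prompt_index` keeps its original
within-day position so lags never bridge gaps. Preprocessing codes signed
valence (negative emotions × −1, range −11..+11, "no emotion" → 0), builds
the person-mean-centered lagged predictor with day-boundary and
missing-prompt exclusion, and applies zero-variance / linear-trend
participant exclusion rules.

All generative defaults in the example configs are illustrative values, not
estimates of any real population.

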