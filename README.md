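# cshazard

Time-to-event analysis for **current-status data**: cohorts in which every
subject is observed once, at a single observation age, and only the
case/control status at that age is known. Chronic conditions with very high
lifetime risk — hypertension is the motivating example — are usually
analysed by logistic regression on case/control labels, but a case is really
a *left-censored* onset age and a control a *right-censored* one. This
package treats them that way, for epidemiologists and statistical
geneticists who want to know whether their "controls" are controls at all or
merely cases with a late age of onset.

## What it computes

With `S(t) = e^{-H(t)}` the onset-age survival function and covariates
acting proportionally on the hazard (`h(t|z) = h0(t) e^{β·z}`):

* **Frequentist fits** of six parametric baseline hazards (exponential,
  Weibull, gamma, log-normal, log-logistic, generalized gamma) by
  current-status maximum likelihood, plus the nonparametric MLE of the onset
  distribution (isotonic regression of event indicators on age), ranked by
  −ln L.
* **A Bayesian piecewise-constant hazard** on one-year age bins with a
  correlated gamma prior process
  `λ0(t+1) | λ0(t) ~ Gamma(α, rate α/λ0(t))` — a martingale in the rates,
  with smoothing controlled by `α ~ U(10,100)` — fitted by adaptive MCMC,
  optionally with a **permanent-stayer (cure) fraction** π so that the
  population survival is `Sp(t) = π + (1−π) S(t)`.
* **Model comparison** by DIC and the effective number of parameters
  `pD = D̄ − D̂`, Rhat convergence checks, HPD intervals, and posterior
  summaries of the survival curve (median onset age, survival at landmark
  ages) and hazard curve (initial rate, maximum rate, age of maximum).
* **Covariate selection**: a four-step forward-backward logistic screen over
  a candidate pool with age and age² always retained, deviance-based
  pseudo-r² variance accounting, Welch's t dimorphism tests, and an
  age-interaction AIC screen for time-dependence.
* **A synthetic-cohort generator** with known ground truth (baseline hazard,
  covariate effects, cure fraction, survey weights), so every stage is
  testable without participant-level study data. Phenotype utilities
  (blood-pressure averaging rules, 140/90 and 2017 130/80 thresholds,
  anthropometric derivations, insulin recalibration, survey-weight
  harmonization) handle real cohort tables.

## Worked example

```python
from cshazard import (GeneratorSpec, simulate_current_status,
                      fit_gamma_process_ph, posterior_survival_summary,
                      hazard_peak, McmcConfig, rank_families)

cohort = simulate_current_status(GeneratorSpec(n=2000, seed=1))  # median onset 48 y
sample = fit_gamma_process_ph(cohort, McmcConfig.preset("quick", seed=1))
surv = posterior_survival_summary(sample, ages=[85.0])
print(round(surv["median_age"], 1), [round(v, 1) for v in surv["median_age_interval"]])
print(round(100 * surv["mean"][0], 1))
print(rank_families(cohort).head(3)[["distribution", "neg_log_lik"]])
```

prints (this exact run):

```
48.4 [45.9, 51.0]
14.2
        distribution  neg_log_lik
0      Nonparametric  1015.905452
1        loglogistic  1035.542900
2  generalized_gamma  1035.834551
```

The cohort was generated with a log-normal onset age of median 48 years:
the posterior median onset age is 48.4 (95% HPD [45.9, 51.0]) and about 14%
of the population is still event-free at 85. The likelihood ranking puts
the nonparametric fit first — it always does, since it maximizes over all
distributions — with the best parametric families about 20 log-likelihood
units behind and within a unit of each other (at n = 2000 the smooth
unimodal families are barely distinguishable from the generating
log-normal).

A command-line pipeline wraps the same stages:

```bash
cshazard simulate --n 1000 --seed 1 --out cohort.csv
cshazard fit-parametric --input cohort.csv --out ranking.tsv
cshazard fit-ph --input cohort.csv --preset quick --seed 1 --out run/
```

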