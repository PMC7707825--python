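# Methods

## The data structure

Every analysis here starts from *current-status* data: each subject is seen
exactly once, at an observation age `a`, and only the indicator of whether a
chronic event (hypertension, in the motivating application) has already
occurred by `a` is recorded. A case is therefore left-censored (onset at some
unknown `T <= a`) and a control right-censored (`T > a`); the mixture of the
two is interval-censored data. Writing `S(t) = exp(-H(t))` for the onset-age
survival function, the likelihood is

    L = prod_cases [1 - Sp(a_i | z_i)] * prod_controls Sp(a_i | z_i)

with `Sp(t) = pi + (1 - pi) S(t)` when a permanent-stayer (cure) fraction
`pi` is modelled and `Sp = S` otherwise. Covariates act proportionally on the
hazard, `h(t|z) = h0(t) exp(beta . z)`, so `S(t|z) = S0(t)^{exp(beta . z)}`.
Log-probabilities are computed through the cumulative hazard with
complementary forms (`log(1 - Sp) = log(1-pi) + log(-expm1(-H))`) so nothing
degrades when `S` is near 0 or 1.

## Baseline hazards

Six parametric families (exponential, Weibull, gamma, log-normal,
log-logistic, generalized gamma) are backed by the corresponding
`scipy.stats` distributions; `H(t) = -logsf(t)`. The generalized gamma uses
the three-parameter Stacy form — density proportional to
`(t/b)^{ac-1} exp(-(t/b)^c)` — which reduces to the gamma family at power
`c = 1` and to the Weibull family at shape `a = 1`; both reductions are
verified by tests. The piecewise-constant baseline places one rate per
one-year age bin `[t, t+1)`; bins start at the cohort's youngest integer age
by default (configurable), the hazard is zero below the first bin, and ages
beyond the last bin extend the final rate by default (`tail_rule="extend"`,
so survival cannot freeze above zero artificially; `"zero"` is available).

## Frequentist fits

Parametric maximum likelihood runs Nelder-Mead on log-transformed positive
parameters (the log-normal location is a free real) from five deterministic
starts anchored at a constant-hazard moment estimate; the starts are run
short and the best point is then polished to full tolerance. The inner loop
evaluates each family's log-survival directly through `scipy.special`
ufuncs (verified against the distribution objects in tests) rather than
frozen distribution instances. Multi-start exists
mainly for the generalized gamma, whose three parameters are weakly
identified from current-status data; its convergence flag is reported
honestly rather than silenced. Fits on a cohort with no cases or no controls
raise a degenerate-data error.

The nonparametric MLE of the onset-age distribution under current-status
observation is the weighted isotonic regression of event indicators on
observation age (pool-adjacent-violators; `sklearn.isotonic` provides the
solver, whose weighted-least-squares block means coincide with the binomial
NPMLE). Ties in age are pre-pooled; survey weights enter as isotonic
weights. Because the NPMLE maximizes the likelihood over *all*
distributions, its -lnL bounds every parametric family's from below; the
ranking table sorts ascending by -lnL with the nonparametric row first or
tied-first. Tests verify the PAVA solution against an independent exhaustive
search over contiguous-block partitions on all small cohorts.

## The Bayesian hazard model

The piecewise-constant baseline gets a correlated gamma prior process:

    lam0(first bin) ~ Gamma(shape = alpha, rate = beta0)
    lam0(t+1) | lam0(t) ~ Gamma(shape = alpha, rate = alpha / lam0(t))

so `E[lam0(t+1) | lam0(t)] = lam0(t)` (the rate chain is a martingale) and
`Var = lam0(t)^2 / alpha`: alpha is a smoothing parameter, with hyperprior
`alpha ~ Uniform(10, 100)`; `beta0 ~ Uniform(0.001, 0.01)`; an optional cure
fraction has `pi ~ Uniform(0, 1)`. The transition's second argument must be
a *rate* equal to `alpha / lam0(t)` for the martingale property to hold;
that reading is adopted throughout. The first-interval prior follows the
same rate convention by default (`first_bin="rate"`); a scale convention is
available. Note that with `alpha >= 10` the first-interval prior behaves
like at least nine pseudo-events concentrated in the first bin, which pulls
the earliest rate upward when the data are thin there; with cohorts of a
thousand subjects or more the likelihood dominates, but first-bin summaries
should be read with this in mind.

Observation ages are floored to one-year bins at fit time; a subject
observed at integer age `a` is taken to have traversed every bin up to and
including `[a, a+1)`, so the youngest age's cases identify the first rate.
Grouping subjects by (binned age, status) makes each likelihood evaluation
O(number of bins).

### Sampler

Adaptive random-walk Metropolis-within-Gibbs: rates are updated one at a
time on the log scale (with the Jacobian), alpha/beta0/pi by random walks
whose out-of-support proposals are rejected (valid Metropolis under the
uniform priors). Each coordinate's log step size is tuned toward a 0.44
acceptance rate during burn-in and frozen afterwards. The Bayesian logistic
model (diffuse normal priors, variance 1e6 on every coefficient) uses the
same scheme but proposes in Cholesky-rotated coordinates seeded at the
posterior mode — raw age and age² columns are correlated above 0.99 and
unrotated coordinate walks would not mix. Kernels are numba-compiled, with
a pure-Python fallback when numba is absent. Chain seeds derive from a
`SeedSequence` of the user seed; a given build is bit-reproducible for a
fixed (seed, config), but bit-identity across library versions is not
promised, only statistical equivalence. Sampler correctness is tested
against deterministic fine-grid quadrature of the unnormalized posterior on
a two-bin model.

Run-length presets mirror the study configurations: `quick` (3 chains x
10,000 iterations, burn-in 2,500, thin 10), `quad` (3 x 100,000 / 10,000 /
50), `full` (3 x 1,000,000 / 100,000 / 1,000), plus `sweep` (3 x 4,000 /
1,000 / 3) for multi-seed simulation studies where hundreds of fits are
needed; all simulation-study tests state their preset.

### Diagnostics and comparison

`rhat` defaults to the split-chain rank-normalized estimator (arviz), more
conservative than the classical between/within ratio, which remains
available via `method="classic"`; fits warn above 1.05. `hpd_interval` is
the shortest contiguous window holding the requested mass of sorted draws.
DIC uses deviance = -2 log-likelihood (likelihood only, no prior);
`pD = Dbar - Dhat` with `Dhat` evaluated at the posterior means of the
parameters on their **natural** scale (rates, pi, coefficients) — the
convention of the generic Gibbs engines this model class is usually run in —
not at means of the sampler's internal log-scale coordinates. Negative pD is
reported and flagged, never hidden.

Posterior curve summaries integrate each retained rate vector into survival
curves (pointwise means with 95% bands); the per-draw median onset age is
found by inverting the piecewise-linear cumulative hazard, and draws whose
curve never reaches 0.5 inside the binned support are reported as
right-censored at the support end (with the censored fraction) rather than
extrapolated. The hazard-peak summary takes each draw's argmax bin, breaking
ties toward the youngest age.

## Covariate selection

Four phases over a candidate pool, with age and age² always retained:
single screens (each candidate alongside the base terms — the adjusted
reading, since candidate effects are benchmarked against the age-adjusted
model; an unadjusted variant is available via `adjust_base_in_single=False`),
backward elimination (largest p first, one at a time, refitting), forward
reconsideration of the single-screen rejects, and a final prune. All tests
use Wald p-values from ML logistic fits (statsmodels GLM) at a flat 0.05 —
no multiplicity correction, matching the design being reproduced; stepwise
MCMC would be prohibitive, so the Bayesian refit is reserved for the final
selected model. Rank-deficient designs are skipped/dropped with warnings.
Ties at the threshold resolve by pool order (documented, deterministic).

Variance accounting uses the deviance-based pseudo-r²
`(1 - exp((D1 - D0)/n)) / (1 - exp(-D0/n))` against the intercept-only null
deviance. The time-dependence screen augments the selected model with one
age x covariate interaction at a time and compares AICs. The sex-dimorphism
screen is Welch's unequal-variance t-test with fractional
Welch-Satterthwaite degrees of freedom.

## The synthetic-cohort generator

The generator emulates the structure of a cross-sectional blood-pressure
study: latent onset ages from any baseline (closed-form inverse survival for
parametric families, linear inversion of the cumulative hazard for piecewise
baselines), proportional covariate effects, an optional cure fraction,
observation ages from an adult age distribution, and current-status
censoring. Defaults — the study conditions under which all simulation tests
run — are: observation ages uniform on [18, 85]; a log-normal onset age with
`mu = log 48`, `sigma = 0.49`, chosen so the latent onset distribution has
median 48 years and roughly 12% event-free at 85, the scale of the
discovery-cohort posterior summaries this package targets; covariates
independent (an optional correlation matrix goes through a Gaussian copula);
optional log-normal survey weights normalized to mean one. Logistic-mode
truth is the concave quadratic `logit p = -6.542 + 0.19977 age - 0.0013372
age²` (standardized slopes 1.2 and -0.5 for the uniform age range), i.e.
prevalence rising and then flattening with age at roughly one-half overall —
a deliberately well-powered version of that concave pattern: a pre-run power
calculation shows the age² Wald statistic near 6 at n = 1000, so
DIC comparisons across the intercept/age/age² ladder separate by more than
5 in nearly every seed. Effect covariates in selection studies are standard
normal with standardized coefficients of 0.3.

What the generator does *not* emulate: competing mortality (no follow-up
structure exists to inform it), within-subject measurement error in blood
pressure, covariate correlation by default, or survey cluster structure.
Passing tests therefore demonstrate correctness of the estimators under the
stated sampling model, not robustness to those real-data features.

## Problem sizes used in the checks

Simulation-based checks run at: n = 1000–2000 subjects per cohort and 5–50
seeds per property (20 seeds for parameter recovery at n = 5000 and for
cure-fraction coverage; 50 seeds for selection operating characteristics;
5 seeds for the permanent-stayer null, which needs two MCMC fits per seed);
multi-seed MCMC studies use the `sweep` preset and single headline fits the
`quick` preset. These sizes are the package's chosen study conditions and
are stated here so the checks are reproducible as specified.

## Known limitations

* The first-interval gamma prior inflates the earliest hazard rate when few
  subjects inform it (see above); the effect fades with cohort size but the
  "initial hazard" summary partially reflects alpha's posterior.
* The generalized gamma is weakly identified from current-status data; its
  fits can legitimately report non-convergence, mirroring its poor standing
  in likelihood rankings of this model class.
* pD for the smoothed hazard model depends on the effective shrinkage and is
  not expected to match the raw parameter count.
* No multiplicity control in selection; operating characteristics are
  per-candidate by design.
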