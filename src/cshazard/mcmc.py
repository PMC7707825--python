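"""Bayesian inference: logistic regression and piecewise-constant hazards
with a correlated gamma prior process, plus convergence and model-comparison
diagnostics.

The hazard model places the baseline rate on one-year age bins with the
sequential prior

    lambda0(first bin) ~ Gamma(shape=alpha, rate=beta0)
    lambda0(t+1) | lambda0(t) ~ Gamma(shape=alpha, rate=alpha / lambda0(t))

so that ``E[lambda0(t+1) | lambda0(t)] = lambda0(t)`` — the rate chain is a
martingale — and ``Var = lambda0(t)^2 / alpha``: larger ``alpha`` means a
smoother hazard.  Hyperpriors are ``alpha ~ Uniform(10, 100)`` and
``beta0 ~ Uniform(0.001, 0.01)``; an optional permanent-stayer fraction has
``pi ~ Uniform(0, 1)``.  Logistic models use diffuse normal priors
(mean 0, variance 1e6) on every coefficient.

Model comparison uses the deviance information criterion:
``pD = Dbar - Dhat`` (posterior mean deviance minus deviance at the
posterior mean) and ``DIC = Dbar + pD``.  Deviance is ``-2 log L``
(likelihood only); ``Dhat`` is evaluated at the posterior means of the
parameters on their natural scale (rates, coefficients, pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import arviz as az
import numpy as np

from . import _samplers
from .errors import DegenerateDataError, ValidationError

PRESETS = {
    # n_chains, n_iter, burn_in, thin — the study run configurations
    "quick": (3, 10_000, 2_500, 10),
    "quad": (3, 100_000, 10_000, 50),
    "full": (3, 1_000_000, 100_000, 1_000),
    # a short configuration for simulation sweeps
    "sweep": (3, 4_000, 1_000, 3),
}


@dataclass(frozen=True)
class McmcConfig:
    """Chain geometry: chains, iterations, burn-in, thinning, seed."""

    n_chains: int = 3
    n_iter: int = 10_000
    burn_in: int = 2_500
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValidationError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "McmcConfig":
        if name not in PRESETS:
            raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        c, n, b, t = PRESETS[name]
        return cls(n_chains=c, n_iter=n, burn_in=b, thin=t, seed=seed)

    @property
    def n_retained(self) -> int:
        per_chain = len(range(self.burn_in, self.n_iter, self.thin))
        return self.n_chains * per_chain

    def chain_seeds(self) -> np.ndarray:
        ss = np.random.SeedSequence(self.seed)
        return (ss.generate_state(self.n_chains) & 0x7FFFFFFF).astype(np.int64)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the standing priors (all proper)."""

    effect_prior_var: float = 1e6
    alpha_bounds: tuple = (10.0, 100.0)
    beta0_bounds: tuple = (0.001, 0.01)
    pi_bounds: tuple = (0.0, 1.0)


@dataclass
class PosteriorSample:
    """MCMC draws across chains with aligned per-draw deviances."""

    draws: np.ndarray          # (chains, retained, params)
    names: Sequence[str]
    deviance: np.ndarray       # (chains, retained)
    config: McmcConfig
    deviance_fn: Optional[Callable] = None  # deviance at a parameter vector
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.shape[:2] != self.deviance.shape:
            raise ValidationError("deviance trace must align with draws")
        if not np.all(np.isfinite(self.draws)):
            raise ValidationError("draws must be finite")

    @property
    def n_chains(self):
        return self.draws.shape[0]

    def index(self, name: str) -> int:
        try:
            return list(self.names).index(name)
        except ValueError:
            raise ValidationError(f"unknown parameter {name!r}") from None

    def chains(self, name: str) -> np.ndarray:
        """(chains, retained) array for one parameter."""
        return self.draws[:, :, self.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.chains(name).reshape(-1)

    def posterior_mean(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2]).mean(axis=0)

    def save(self, path) -> None:
        """Columnar text: chain, iteration, one column per parameter, deviance."""
        C, I, P = self.draws.shape
        header = "chain\titeration\t" + "\t".join(self.names) + "\tdeviance"
        rows = np.column_stack([
            np.repeat(np.arange(C), I),
            np.tile(np.arange(I), C),
            self.draws.reshape(C * I, P),
            self.deviance.reshape(-1),
        ])
        np.savetxt(path, rows, delimiter="\t", header=header, comments="")


def rhat(sample, parameter=None, method: str = "rank") -> float:
    """Potential scale reduction factor for one parameter.

    ``method="rank"`` (default) is the split-chain rank-normalized
    estimator; ``method="classic"`` the original between/within variance
    ratio.  Requires at least two chains of at least ten retained draws.
    """
    if isinstance(sample, PosteriorSample):
        arr = sample.chains(parameter)
    else:
        arr = np.asarray(sample, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("rhat needs >= 2 chains")
    if arr.shape[1] < 10:
        raise ValidationError("rhat needs >= 10 retained draws per chain")
    if method == "rank":
        return float(az.rhat(arr))
    if method == "classic":
        m, n = arr.shape
        means = arr.mean(axis=1)
        W = arr.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
        if W == 0:
            return 1.0
        return float(np.sqrt(var_plus / W))
    raise ValidationError("method must be 'rank' or 'classic'")


@dataclass(frozen=True)
class DicSummary:
    """DIC bookkeeping: Dbar, Dhat, pD = Dbar - Dhat, DIC = Dbar + pD."""

    dbar: float
    dhat: float
    pd: float
    dic: float
    negative_pd: bool = False


def dic(sample: PosteriorSample) -> DicSummary:
    """Deviance information criterion from a posterior sample."""
    dev = sample.deviance.reshape(-1)
    if not np.all(np.isfinite(dev)):
        bad = np.flatnonzero(~np.isfinite(dev))
        raise ValidationError(f"non-finite deviance at draws {bad[:10].tolist()}")
    if sample.deviance_fn is None:
        raise ValidationError("sample carries no deviance function")
    dbar = float(dev.mean())
    dhat = float(sample.deviance_fn(sample.posterior_mean()))
    pd = dbar - dhat
    if pd < 0:
        warnings.warn(f"negative pD ({pd:.3f}); DIC may be unreliable",
                      RuntimeWarning, stacklevel=2)
    return DicSummary(dbar=dbar, dhat=dhat, pd=pd, dic=dbar + pd,
                      negative_pd=pd < 0)


def hpd_interval(draws, mass: float = 0.95) -> tuple:
    """Shortest contiguous interval holding ``ceil(mass * N)`` sorted draws."""
    if not (0.0 < mass < 1.0):
        raise ValidationError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 draws")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ---------------------------------------------------------------------------
# Bayesian logistic regression
# ---------------------------------------------------------------------------

def _logistic_design(cohort, covariate_terms):
    ages = cohort.observation_ages
    cols = [np.ones(cohort.n)]
    names = ["intercept"]
    for term in covariate_terms:
        if term == "age":
            cols.append(ages)
        elif term == "age2":
            cols.append(ages ** 2)
        else:
            cols.append(cohort.covariate_array(term))
        names.append(term)
    return np.column_stack(cols), names


def _posterior_mode(X, y, w, prior_prec, max_iter=60):
    """Damped Newton on the log posterior (always well-posed thanks to the
    proper prior, even under perfect separation or a constant column)."""
    n, p = X.shape
    theta = np.zeros(p)

    def objective(th):
        eta = X @ th
        ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * prior_prec * th @ th

    obj = objective(theta)
    for _ in range(max_iter):
        eta = X @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - mu)) - prior_prec * theta
        wt = w * mu * (1.0 - mu)
        H = X.T @ (X * wt[:, None]) + prior_prec * np.eye(p)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj:
                break
            t *= 0.5
        if abs(cand_obj - obj) < 1e-10 and np.max(np.abs(t * step)) < 1e-8:
            theta, obj = cand, cand_obj
            break
        theta, obj = cand, cand_obj
    eta = X @ theta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = w * mu * (1.0 - mu)
    H = X.T @ (X * wt[:, None]) + prior_prec * np.eye(p)
    cov = np.linalg.inv(H)
    return theta, cov


def fit_bayes_logistic(cohort, covariate_terms: Sequence[str],
                       config: McmcConfig,
                       priors: PriorSpec = PriorSpec(),
                       use_weights: bool = False) -> PosteriorSample:
    """Posterior of a Bayesian logistic regression by adaptive MCMC.

    ``covariate_terms`` may contain ``"age"``, ``"age2"`` and covariate
    names; an intercept is always included.  Chains start at the posterior
    mode and propose in Cholesky-rotated coordinates.  A convergence
    warning is raised if any parameter's split-Rhat exceeds 1.05.
    """
    X, names = _logistic_design(cohort, covariate_terms)
    y = cohort.events.astype(float)
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
    else:
        w = np.ones(cohort.n)
    for j, name in enumerate(names):
        if name != "intercept" and np.var(X[:, j]) == 0:
            warnings.warn(f"covariate {name!r} has zero variance; its "
                          "posterior will mirror the prior", RuntimeWarning,
                          stacklevel=2)
    prior_prec = 1.0 / priors.effect_prior_var
    theta0, cov = _posterior_mode(X, y, w, prior_prec)
    if np.max(np.abs(theta0)) > 30:
        warnings.warn("very large coefficient at the posterior mode; the data "
                      "may be separated (the diffuse prior keeps the posterior "
                      "proper)", RuntimeWarning, stacklevel=2)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(names)))
    Xt = X @ L
    eta0 = X @ theta0

    chains, devs = [], []
    for chain_seed in config.chain_seeds():
        th, dv, _ = _samplers.logistic_chain(
            Xt, y, w, L, theta0, eta0, prior_prec,
            config.n_iter, config.burn_in, config.thin,
            int(chain_seed), 1.0)
        chains.append(th)
        devs.append(dv)
    draws = np.stack(chains)
    deviance = np.stack(devs)

    def deviance_fn(theta):
        eta = X @ np.asarray(theta, dtype=float)
        return -2.0 * float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    sample = PosteriorSample(draws=draws, names=names, deviance=deviance,
                             config=config, deviance_fn=deviance_fn,
                             meta={"model": "logistic", "terms": list(covariate_terms),
                                   "seed": config.seed})
    _warn_rhat(sample)
    return sample


def _warn_rhat(sample):
    if sample.n_chains < 2 or sample.draws.shape[1] < 10:
        return
    for name in sample.names:
        r = rhat(sample, name)
        if np.isfinite(r) and r > 1.05:
            warnings.warn(f"Rhat for {name!r} is {r:.3f} (> 1.05): chains may "
                          "not have converged", RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Gamma-process proportional hazards
# ---------------------------------------------------------------------------

def _grouped_counts(cohort, bin_start, use_weights):
    ages = np.floor(cohort.observation_ages).astype(int)
    amin = int(ages.min()) if bin_start is None else int(bin_start)
    if np.any(ages < amin):
        raise ValidationError("bin_start lies above some observation ages")
    amax = int(ages.max())
    nb = amax - amin + 1
    expo = ages - amin  # subject spans bins 0..expo inclusive
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
    else:
        w = np.ones(cohort.n)
    ev = cohort.events
    m_case = np.bincount(expo[ev], weights=w[ev], minlength=nb).astype(float)
    m_ctrl = np.bincount(expo[~ev], weights=w[~ev], minlength=nb).astype(float)
    return amin, nb, m_case, m_ctrl


def fit_gamma_process_ph(cohort, config: McmcConfig, with_cure: bool = False,
                         priors: PriorSpec = PriorSpec(),
                         fix_alpha: Optional[float] = None,
                         fix_beta0: Optional[float] = None,
                         bin_start: Optional[int] = None,
                         first_bin: str = "rate",
                         use_weights: bool = False) -> PosteriorSample:
    """Posterior of the piecewise-constant baseline hazard under the
    correlated gamma prior process (optionally with a cure fraction).

    Observation ages are floored to one-year bins; a subject observed at
    integer age ``a`` is taken to have traversed every bin up to and
    including ``[a, a+1)``.  Empty bins are allowed (prior-dominated).
    ``first_bin`` selects the second-parameter convention of the
    first-interval prior: ``"rate"`` (default) or ``"scale"``.
    """
    ev = cohort.events
    if ev.all():
        raise DegenerateDataError("cohort has no controls")
    if not ev.any():
        raise DegenerateDataError("cohort has no cases")
    if first_bin not in ("rate", "scale"):
        raise ValidationError("first_bin must be 'rate' or 'scale'")
    amin, nb, m_case, m_ctrl = _grouped_counts(cohort, bin_start, use_weights)

    # crude constant-hazard initial value
    frac = float(ev.mean())
    mean_expo = float(np.mean(np.floor(cohort.observation_ages)) - amin + 1)
    lam0 = max(-np.log(max(1.0 - frac, 1e-3)) / mean_expo, 1e-4)
    loglam_init = np.full(nb, np.log(lam0))
    alpha_init = float(fix_alpha) if fix_alpha is not None else 30.0
    beta0_init = float(fix_beta0) if fix_beta0 is not None else 0.005
    pi_init = 0.1 if with_cure else 0.0

    chains, devs = [], []
    for chain_seed in config.chain_seeds():
        dr, dv, _ = _samplers.ph_chain(
            m_case, m_ctrl, loglam_init, alpha_init, beta0_init, pi_init,
            fix_alpha is None, fix_beta0 is None, bool(with_cure),
            first_bin == "scale",
            float(priors.alpha_bounds[0]), float(priors.alpha_bounds[1]),
            float(priors.beta0_bounds[0]), float(priors.beta0_bounds[1]),
            config.n_iter, config.burn_in, config.thin, int(chain_seed))
        chains.append(dr)
        devs.append(dv)
    draws = np.stack(chains)
    deviance = np.stack(devs)
    names = [f"lam_{amin + j}" for j in range(nb)] + ["alpha", "beta0", "pi"]

    def deviance_fn(params):
        lam = np.asarray(params[:nb], dtype=float)
        pi = float(params[nb + 2]) if with_cure else 0.0
        Hc = np.cumsum(lam)
        S = np.exp(-Hc)
        sp = pi + (1 - pi) * S
        fp = (1 - pi) * (-np.expm1(-Hc))
        with np.errstate(divide="ignore"):
            terms = m_ctrl * np.where(m_ctrl > 0, np.log(sp), 0.0) \
                + m_case * np.where(m_case > 0, np.log(fp), 0.0)
        return -2.0 * float(np.sum(terms))

    sample = PosteriorSample(
        draws=draws, names=names, deviance=deviance, config=config,
        deviance_fn=deviance_fn,
        meta={"model": "gamma_process_ph", "bin_start": amin, "n_bins": nb,
              "with_cure": bool(with_cure), "first_bin": first_bin,
              "seed": config.seed})
    if nb <= 5:  # per-rate Rhat on long rate chains is noisy; check opt-in
        _warn_rhat(sample)
    return sample


# ---------------------------------------------------------------------------
# posterior curve summaries
# ---------------------------------------------------------------------------

def _lam_matrix(sample):
    nb = sample.meta["n_bins"]
    return sample.draws.reshape(-1, sample.draws.shape[2])[:, :nb]


def _pi_vector(sample):
    flat = sample.draws.reshape(-1, sample.draws.shape[2])
    if sample.meta.get("with_cure"):
        return flat[:, sample.index("pi")]
    return np.zeros(flat.shape[0])


def posterior_survival_summary(sample: PosteriorSample, ages,
                               band_mass: float = 0.95) -> dict:
    """Pointwise posterior mean and credible band of the population survival
    curve, plus the posterior of the median event age.

    Ages beyond the binned support use the extend tail rule with a warning.
    Per-draw median event ages that fall beyond the binned support are
    right-censored at the support end rather than extrapolated; the summary
    reports the censored fraction.
    """
    if sample.meta.get("model") != "gamma_process_ph":
        raise ValidationError("survival summaries need a hazard-model sample")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    amin = sample.meta["bin_start"]
    nb = sample.meta["n_bins"]
    lam = _lam_matrix(sample)
    pi = _pi_vector(sample)
    if np.any(ages > amin + nb):
        warnings.warn("ages beyond the binned support: extending the last "
                      "bin's rate", RuntimeWarning, stacklevel=2)
    u = np.clip(ages - amin, 0.0, None)
    full = np.minimum(np.floor(u).astype(int), nb)
    frac = np.clip(u - full, 0.0, 1.0)
    E = np.zeros((ages.size, nb))
    for i in range(ages.size):
        E[i, :full[i]] = 1.0
        if full[i] < nb:
            E[i, full[i]] = frac[i]
        else:
            E[i, nb - 1] += u[i] - nb  # extend tail
    H = lam @ E.T                      # (draws, ages)
    Sp = pi[:, None] + (1 - pi[:, None]) * np.exp(-H)
    lo = (1 - band_mass) / 2
    mean_curve = Sp.mean(axis=0)
    lower = np.quantile(Sp, lo, axis=0)
    upper = np.quantile(Sp, 1 - lo, axis=0)

    # per-draw median event age (population curve crossing 0.5)
    csum = np.cumsum(lam, axis=1)
    medians = np.full(lam.shape[0], np.nan)
    censored = np.zeros(lam.shape[0], dtype=bool)
    ok = pi < 0.5
    target = np.where(ok, -np.log(np.clip((0.5 - pi) / (1 - pi), 1e-300, 1.0)), np.inf)
    for d in range(lam.shape[0]):
        if not ok[d]:
            censored[d] = True
            medians[d] = amin + nb
            continue
        idx = np.searchsorted(csum[d], target[d])
        if idx >= nb:
            censored[d] = True
            medians[d] = amin + nb
        else:
            prev = csum[d, idx - 1] if idx > 0 else 0.0
            rate = lam[d, idx]
            medians[d] = amin + idx + (target[d] - prev) / max(rate, 1e-300)
    med_lo, med_hi = hpd_interval(medians, band_mass)
    return {
        "ages": ages,
        "mean": mean_curve,
        "lower": lower,
        "upper": upper,
        "median_age": float(np.median(medians)),
        "median_age_interval": (med_lo, med_hi),
        "median_censored_fraction": float(censored.mean()),
    }


def hazard_peak(sample: PosteriorSample, band_mass: float = 0.95) -> dict:
    """Posterior of the hazard curve's landmarks: the age of the maximum
    rate (ties broken toward the youngest bin), the first-bin rate and the
    maximum rate, each with an HPD interval."""
    if sample.meta.get("model") != "gamma_process_ph":
        raise ValidationError("hazard summaries need a hazard-model sample")
    amin = sample.meta["bin_start"]
    lam = _lam_matrix(sample)
    age_of_max = amin + np.argmax(lam, axis=1)  # argmax returns first max
    initial = lam[:, 0]
    maxima = lam.max(axis=1)
    return {
        "age_of_max": float(np.median(age_of_max)),
        "age_of_max_interval": hpd_interval(age_of_max, band_mass),
        "initial_rate": float(initial.mean()),
        "initial_rate_interval": hpd_interval(initial, band_mass),
        "max_rate": float(maxima.mean()),
        "max_rate_interval": hpd_interval(maxima, band_mass),
    }


def gamma_process_step_draws(lam_t: float, alpha: float, n_draws: int,
                             seed: int = 0) -> np.ndarray:
    """Monte-Carlo draws of lambda(t+1) given lambda(t) from the prior
    process (exposed for prior-predictive checks)."""
    if lam_t <= 0 or alpha <= 0:
        raise ValidationError("lam_t and alpha must be positive")
    return _samplers.gamma_process_step_draws(float(lam_t), float(alpha),
                                              int(n_draws), int(seed))
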