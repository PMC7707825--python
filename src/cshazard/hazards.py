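"""Hazard, cumulative-hazard and survival mathematics.

The age at onset ``T`` of a chronic condition is described through its hazard
``h(t)`` (instantaneous event rate at age ``t`` given event-free survival to
``t``), the cumulative hazard ``H(t) = \\int_0^t h(u) du`` and the survival
function ``S(t) = Pr(T > t) = exp(-H(t))``.

Three layers are composed here:

* a **baseline hazard** — one of six parametric families
  (:class:`ParametricHazard`) or a step function on one-year age bins
  (:class:`PiecewiseConstantHazard`);
* optional **proportional covariate effects** — :class:`PHModel`, where a
  covariate vector ``z`` with log-hazard-ratios ``beta`` multiplies the
  baseline hazard by ``exp(beta·z)`` so that ``S(t|z) = S0(t)**exp(beta·z)``;
* an optional **permanent-stayer (cure) fraction** — :class:`CureMixture`,
  where a proportion ``pi`` of the population never experiences the event and
  the population survival is the two-component mixture
  ``Sp(t) = pi + (1 - pi) * S(t)``.

For current-status data each subject is seen once, at an observation age
``a``: a *case* (event already occurred) is left-censored and contributes
``log(1 - Sp(a|z))``, a *control* is right-censored and contributes
``log Sp(a|z)``.  :func:`current_status_loglik` evaluates this likelihood for
any of the model layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import NoMedianError, ValidationError

PARAMETRIC_FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "generalized_gamma",
)

# ordered parameter names per family; all are positive except lognormal mu,
# which is a free real (log-scale location)
_FAMILY_PARAMS = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "scale"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("shape", "scale"),
    "generalized_gamma": ("shape", "power", "scale"),
}


def _check_ages(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("ages must be non-negative")
    return t


@dataclass(frozen=True)
class ParametricHazard:
    """A parametric baseline hazard.

    ``family`` is one of :data:`PARAMETRIC_FAMILIES`; ``params`` holds the
    family's named parameters:

    =================== ==========================================
    exponential         rate
    weibull             shape, scale
    gamma               shape, scale
    lognormal           mu, sigma       (of log event age)
    loglogistic         shape, scale
    generalized_gamma   shape, power, scale   (Stacy form)
    =================== ==========================================

    The generalized gamma uses the three-parameter Stacy form with density
    proportional to ``(t/scale)**(shape*power - 1) * exp(-(t/scale)**power)``;
    it reduces to the gamma family at ``power = 1`` and to the Weibull family
    at ``shape = 1``.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ValidationError(f"unknown family {self.family!r}")
        names = _FAMILY_PARAMS[self.family]
        got = tuple(sorted(self.params))
        if got != tuple(sorted(names)):
            raise ValidationError(
                f"{self.family} needs parameters {names}, got {got}"
            )
        for name in names:
            v = float(self.params[name])
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite")
            if name != "mu" and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        object.__setattr__(self, "params", dict(self.params))

    @property
    def param_names(self) -> tuple:
        return _FAMILY_PARAMS[self.family]

    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in self.param_names])

    def _dist(self):
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "loglogistic":
            return stats.fisk(p["shape"], scale=p["scale"])
        if self.family == "generalized_gamma":
            return stats.gengamma(p["shape"], p["power"], scale=p["scale"])
        raise AssertionError(self.family)

    def cumulative_hazard(self, t):
        t = _check_ages(t)
        with np.errstate(divide="ignore"):
            return -self._dist().logsf(t)

    def survival(self, t):
        t = _check_ages(t)
        return self._dist().sf(t)

    def hazard(self, t):
        t = _check_ages(t)
        d = self._dist()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.exp(d.logpdf(t) - d.logsf(t))
        return h

    def quantile_event_age(self, survival_target):
        """Age at which the survival function first reaches ``survival_target``."""
        return float(self._dist().isf(survival_target))

    def to_dict(self):
        return {"kind": "parametric", "family": self.family,
                "params": dict(self.params)}


@dataclass(frozen=True)
class PiecewiseConstantHazard:
    """Step-function baseline hazard on consecutive one-year age bins.

    Bin ``j`` covers ``[start + j, start + j + 1)`` and carries rate
    ``rates[j]``.  Below ``start`` the hazard is zero (``H(t)=0`` for
    ``t <= start``); beyond the last bin ``tail_rule`` applies:
    ``"extend"`` continues at the last bin's rate (the default, so survival
    does not freeze above zero artificially), ``"zero"`` switches the hazard
    off.
    """

    start: float
    rates: Sequence[float]
    tail_rule: str = "extend"

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 1 or rates.size == 0:
            raise ValidationError("rates must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValidationError("rates must be finite and non-negative")
        if self.tail_rule not in ("extend", "zero"):
            raise ValidationError("tail_rule must be 'extend' or 'zero'")
        object.__setattr__(self, "rates", rates)

    @property
    def n_bins(self) -> int:
        return len(self.rates)

    @property
    def end(self) -> float:
        return self.start + self.n_bins

    def hazard(self, t):
        t = _check_ages(t)
        u = np.atleast_1d(t) - self.start
        h = np.zeros_like(u, dtype=float)
        inside = (u >= 0) & (u < self.n_bins)
        h[inside] = self.rates[np.floor(u[inside]).astype(int)]
        beyond = u >= self.n_bins
        if self.tail_rule == "extend":
            h[beyond] = self.rates[-1]
        return h if np.ndim(t) else float(h[0])

    def cumulative_hazard(self, t):
        t = _check_ages(t)
        u = np.clip(np.atleast_1d(t) - self.start, 0.0, None)
        csum = np.concatenate([[0.0], np.cumsum(self.rates)])
        k = np.minimum(np.floor(u).astype(int), self.n_bins)
        frac = np.clip(u - k, 0.0, 1.0)
        H = csum[k] + np.where(k < self.n_bins, self.rates[np.minimum(k, self.n_bins - 1)] * frac, 0.0)
        beyond = u > self.n_bins
        if self.tail_rule == "extend":
            H[beyond] += (u[beyond] - self.n_bins) * self.rates[-1]
        return H if np.ndim(t) else float(H[0])

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def quantile_event_age(self, survival_target):
        """Smallest age with ``S(t) <= survival_target`` (linear in each bin)."""
        H_target = -np.log(survival_target)
        csum = np.concatenate([[0.0], np.cumsum(self.rates)])
        if H_target <= csum[-1]:
            j = int(np.searchsorted(csum, H_target, side="left"))
            j = max(j - 1, 0)
            # advance past zero-rate bins that cannot absorb any hazard
            while j < self.n_bins and csum[j + 1] < H_target:
                j += 1
            rate = self.rates[j]
            frac = 0.0 if rate == 0 else (H_target - csum[j]) / rate
            return float(self.start + j + frac)
        if self.tail_rule == "extend" and self.rates[-1] > 0:
            extra = (H_target - csum[-1]) / self.rates[-1]
            return float(self.end + extra)
        raise NoMedianError(
            "cumulative hazard saturates below the requested survival level"
        )

    def to_dict(self):
        return {"kind": "piecewise", "start": float(self.start),
                "rates": [float(r) for r in self.rates],
                "tail_rule": self.tail_rule}


@dataclass(frozen=True)
class PHModel:
    """Proportional-hazards wrapper: hazard(t|z) = baseline(t) * exp(beta·z)."""

    baseline: object
    beta: Mapping[str, float] = field(default_factory=dict)

    @property
    def covariate_names(self) -> tuple:
        return tuple(self.beta)

    def linear_predictor(self, z=None):
        if not self.beta:
            return 0.0
        if z is None:
            raise ValidationError(
                f"model has covariates {self.covariate_names}, none supplied"
            )
        lp = 0.0
        for name, coef in self.beta.items():
            if name not in z:
                raise ValidationError(f"covariate {name!r} missing")
            lp = lp + coef * np.asarray(z[name], dtype=float)
        return lp

    def cumulative_hazard(self, t, z=None):
        return self.baseline.cumulative_hazard(t) * np.exp(self.linear_predictor(z))

    def hazard(self, t, z=None):
        return self.baseline.hazard(t) * np.exp(self.linear_predictor(z))

    def survival(self, t, z=None):
        return np.exp(-self.cumulative_hazard(t, z))

    def to_dict(self):
        return {"kind": "ph", "baseline": self.baseline.to_dict(),
                "beta": {k: float(v) for k, v in self.beta.items()}}


@dataclass(frozen=True)
class CureMixture:
    """Population survival with a permanent-stayer fraction.

    ``Sp(t|z) = pi + (1 - pi) * S(t|z)``: a proportion ``pi`` never
    experiences the event, so the population survival plateaus at ``pi``.
    ``pi = 0`` reduces exactly to the susceptible model.
    """

    pi: float
    model: object

    def __post_init__(self):
        if not (0.0 <= self.pi <= 1.0):
            raise ValidationError(f"pi must lie in [0, 1], got {self.pi}")

    def population_survival(self, t, z=None):
        S = _survival_of(self.model, t, z)
        return self.pi + (1.0 - self.pi) * S

    # mirror the hazard-model surface so summaries treat the layers uniformly
    def survival(self, t, z=None):
        return self.population_survival(t, z)

    def to_dict(self):
        inner = self.model.to_dict()
        return {"kind": "cure", "pi": float(self.pi), "model": inner}


def _survival_of(model, t, z=None):
    if isinstance(model, PHModel):
        return model.survival(t, z)
    return model.survival(t)


def _resolve(model):
    """Split any model layer into (pi, ph_model)."""
    if isinstance(model, CureMixture):
        inner = model.model
        pi = model.pi
    else:
        inner = model
        pi = 0.0
    if not isinstance(inner, PHModel):
        inner = PHModel(baseline=inner)
    return pi, inner


def model_from_dict(doc: Mapping) -> object:
    kind = doc["kind"]
    if kind == "parametric":
        return ParametricHazard(doc["family"], doc["params"])
    if kind == "piecewise":
        return PiecewiseConstantHazard(doc["start"], doc["rates"],
                                       doc.get("tail_rule", "extend"))
    if kind == "ph":
        return PHModel(model_from_dict(doc["baseline"]), doc.get("beta", {}))
    if kind == "cure":
        return CureMixture(doc["pi"], model_from_dict(doc["model"]))
    raise ValidationError(f"unknown model kind {kind!r}")


def population_survival(model, t, z=None):
    """``Sp(t|z)`` for any model layer (pi taken as 0 without a cure layer)."""
    pi, ph = _resolve(model)
    return pi + (1.0 - pi) * ph.survival(t, z)


def current_status_loglik(model, cohort, use_weights: bool = False) -> float:
    """Log-likelihood of a current-status cohort under ``model``.

    Cases are left-censored, ``log(1 - Sp(a_i|z_i))``; controls are
    right-censored, ``log Sp(a_i|z_i)``.  Computed through the cumulative
    hazard with complementary forms so that probabilities near 0 and 1 do
    not lose precision.  Returns ``-inf`` (with a warning naming the count
    of offending records) when a case sits where ``Sp = 1`` or a control
    where ``Sp = 0``.
    """
    pi, ph = _resolve(model)
    ages = cohort.observation_ages
    events = cohort.events
    missing = [n for n in ph.covariate_names if n not in cohort.covariate_names]
    if missing:
        raise ValidationError(f"cohort lacks model covariates {missing}")
    z = {n: cohort.covariate_array(n) for n in ph.covariate_names} or None
    H = ph.baseline.cumulative_hazard(ages) * np.exp(ph.linear_predictor(z))
    H = np.asarray(H, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        # control: log Sp = log(pi + (1-pi) e^{-H})
        if pi > 0:
            log_sp = np.logaddexp(np.log(pi), np.log1p(-pi) - H)
        else:
            log_sp = -H
        # case: log(1 - Sp) = log(1-pi) + log(1 - e^{-H})
        log_one_minus_s = np.where(H > 0, np.log(-np.expm1(-H)), -np.inf)
        log_fp = (np.log1p(-pi) if pi < 1 else -np.inf) + log_one_minus_s

    contrib = np.where(events, log_fp, log_sp)
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
        contrib = contrib * w
    bad = ~np.isfinite(contrib)
    if np.any(bad):
        warnings.warn(
            f"current-status likelihood is -inf: {int(bad.sum())} record(s) "
            "have probability zero under this model",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    return float(contrib.sum())


def survival_at(model, age, z=None) -> float:
    """Population survival probability at ``age``."""
    _check_ages(age)
    return float(population_survival(model, age, z))


def median_event_age(model, z=None) -> float:
    """Smallest age at which the population survival drops to one half.

    With a cure fraction ``pi >= 0.5`` the population curve plateaus above
    0.5 and no median exists (:class:`NoMedianError`).
    """
    pi, ph = _resolve(model)
    if pi >= 0.5:
        raise NoMedianError(f"cure fraction pi={pi} >= 0.5: Sp never reaches 0.5")
    target_s = (0.5 - pi) / (1.0 - pi)  # susceptible survival at the median
    hr = np.exp(ph.linear_predictor(z)) if ph.beta else 1.0
    # S0(t)^hr = target  =>  S0(t) = target^(1/hr)
    base_target = target_s ** (1.0 / hr)
    return float(ph.baseline.quantile_event_age(base_target))
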