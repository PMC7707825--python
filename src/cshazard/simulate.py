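"""Synthetic current-status cohorts with known ground truth.

The generator emulates the structure of a cross-sectional blood-pressure
study: each subject has a latent event age ``T`` drawn from a hazard model
(optionally with proportional covariate effects and a never-event fraction
``pi``), is observed once at an age drawn from an adult age distribution, and
is recorded only as case (``T <= a``) or control (``T > a``).  A logistic
mode draws the binary outcome directly from a logit that is linear in age,
age² and covariates, for benchmarking logistic against time-to-event fits.

Defaults are calibrated to the discovery-study scale this package targets:
observation ages uniform on [18, 85]; a log-normal latent onset age with
median 48 years and ``sigma = 0.49`` (about 12% event-free at 85); logistic
truth a concave quadratic in age (rising, then flattening prevalence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import Cohort, harmonize_weights
from .errors import ValidationError
from .hazards import (
    CureMixture,
    ParametricHazard,
    PHModel,
    PiecewiseConstantHazard,
    model_from_dict,
)

DEFAULT_BASELINE = ParametricHazard("lognormal", {"mu": math.log(48.0), "sigma": 0.49})

#: concave-quadratic logit in age: standardized slopes (1.2, -0.5) for
#: age ~ U(18, 85), expressed on the raw age scale
DEFAULT_LOGISTIC_TRUTH = {
    "intercept": -6.542,
    "age": 0.19977,
    "age2": -0.0013372,
}


def _make_dist(spec):
    kind, *args = spec
    if kind == "normal":
        return stats.norm(loc=args[0], scale=args[1])
    if kind == "lognormal":
        return stats.lognorm(args[1], scale=math.exp(args[0]))
    if kind == "uniform":
        return stats.uniform(loc=args[0], scale=args[1] - args[0])
    if kind == "bernoulli":
        return stats.bernoulli(args[0])
    raise ValidationError(f"unknown distribution kind {kind!r}")


@dataclass
class GeneratorSpec:
    """Full recipe for one synthetic cohort.

    ``effects`` are log hazard ratios on the named covariates (proportional
    hazards scale); ``cure_pi`` is the permanent-stayer fraction;
    ``logistic_truth`` (intercept / age / age² / covariate coefficients)
    switches on logistic-mode generation via :func:`simulate_logistic`.
    Covariates are drawn independently unless ``correlation`` supplies a
    correlation matrix (applied through a Gaussian copula).
    """

    n: int = 1000
    seed: int = 0
    age_dist: tuple = ("uniform", 18.0, 85.0)
    baseline: object = field(default_factory=lambda: DEFAULT_BASELINE)
    effects: Mapping[str, float] = field(default_factory=dict)
    cure_pi: float = 0.0
    covariate_dists: Mapping[str, tuple] = field(default_factory=dict)
    correlation: Optional[Sequence[Sequence[float]]] = None
    logistic_truth: Optional[Mapping[str, float]] = None
    with_weights: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not (0.0 <= self.cure_pi <= 1.0):
            raise ValidationError("cure_pi must lie in [0, 1]")
        for name in self.effects:
            if name not in self.covariate_dists:
                raise ValidationError(
                    f"effect on {name!r} has no covariate distribution"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "age_dist": list(self.age_dist),
            "baseline": self.baseline.to_dict(),
            "effects": dict(self.effects),
            "cure_pi": self.cure_pi,
            "covariate_dists": {k: list(v) for k, v in self.covariate_dists.items()},
            "correlation": None if self.correlation is None
            else np.asarray(self.correlation).tolist(),
            "logistic_truth": None if self.logistic_truth is None
            else dict(self.logistic_truth),
            "with_weights": self.with_weights,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorSpec":
        doc = dict(doc)
        if "baseline" in doc and isinstance(doc["baseline"], Mapping):
            doc["baseline"] = model_from_dict(doc["baseline"])
        if "age_dist" in doc:
            doc["age_dist"] = tuple(doc["age_dist"])
        if "covariate_dists" in doc:
            doc["covariate_dists"] = {k: tuple(v)
                                      for k, v in doc["covariate_dists"].items()}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _draw_covariates(spec: GeneratorSpec, rng) -> pd.DataFrame:
    names = list(spec.covariate_dists)
    if not names:
        return pd.DataFrame(index=range(spec.n))
    if spec.correlation is None:
        cols = {name: _make_dist(spec.covariate_dists[name]).rvs(
            size=spec.n, random_state=rng) for name in names}
        return pd.DataFrame(cols).astype(float)
    corr = np.asarray(spec.correlation, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValidationError("correlation matrix shape must match covariates")
    z = rng.multivariate_normal(np.zeros(len(names)), corr, size=spec.n)
    u = stats.norm.cdf(z)
    cols = {}
    for j, name in enumerate(names):
        cols[name] = _make_dist(spec.covariate_dists[name]).ppf(u[:, j])
    return pd.DataFrame(cols).astype(float)


def _invert_cumhaz(baseline, targets: np.ndarray) -> np.ndarray:
    """Event ages solving H0(T) = targets (vectorized)."""
    if isinstance(baseline, ParametricHazard):
        # S0(T) = exp(-target)  -> closed-form inverse survival
        with np.errstate(over="ignore"):
            return baseline._dist().isf(np.exp(-targets))
    if isinstance(baseline, PiecewiseConstantHazard):
        out = np.empty_like(targets)
        for i, h in enumerate(targets):
            try:
                out[i] = baseline.quantile_event_age(math.exp(-h))
            except Exception:
                out[i] = math.inf
        return out
    raise ValidationError(f"cannot invert baseline of type {type(baseline)!r}")


def simulate_event_times(spec: GeneratorSpec, rng=None,
                         covariates: Optional[pd.DataFrame] = None):
    """Latent event ages (``inf`` for permanent stayers) plus covariates.

    Inverts the proportional-hazards cumulative hazard:
    ``T`` solves ``H0(T) * exp(beta·z) = -log U`` with ``U ~ Uniform(0,1)``;
    with probability ``cure_pi`` the subject never experiences the event.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if isinstance(spec.baseline, PiecewiseConstantHazard):
        if np.all(spec.baseline.rates == 0) and spec.cure_pi < 1:
            if spec.baseline.tail_rule == "zero":
                raise ValidationError("all-zero hazard with pi < 1 is degenerate")
    z = _draw_covariates(spec, rng) if covariates is None else covariates
    lp = np.zeros(spec.n)
    for name, beta in spec.effects.items():
        lp += beta * z[name].to_numpy()
    u = rng.uniform(size=spec.n)
    targets = -np.log(u) * np.exp(-lp)  # H0(T) targets
    times = _invert_cumhaz(spec.baseline, targets)
    if spec.cure_pi > 0:
        cured = rng.uniform(size=spec.n) < spec.cure_pi
        times = np.where(cured, np.inf, times)
    return times, z


def _attach(spec: GeneratorSpec, ages, events, z, rng, group_label):
    df = pd.DataFrame({
        "observation_age": ages,
        "event": np.asarray(events, dtype=bool),
        "sbp": math.nan, "dbp": math.nan,
        "on_treatment": False, "ever_diagnosed": None,
        "survey_weight": math.nan, "stratum": None,
    })
    for name in z.columns:
        df[name] = z[name].to_numpy()
    if spec.with_weights:
        raw = rng.lognormal(mean=0.0, sigma=0.5, size=spec.n)
        df["survey_weight"] = harmonize_weights(raw, n_cycles=1)
    return Cohort(df, list(z.columns), group_label=group_label or "synthetic")


def simulate_current_status(spec: GeneratorSpec, group_label: str = "") -> Cohort:
    """A current-status cohort: observation ages from ``age_dist``, event
    status = (latent event age <= observation age)."""
    rng = np.random.default_rng(spec.seed)
    times, z = simulate_event_times(spec, rng)
    ages = _make_dist(spec.age_dist).rvs(size=spec.n, random_state=rng)
    events = times <= ages
    return _attach(spec, ages, events, z, rng, group_label)


def simulate_logistic(spec: GeneratorSpec, group_label: str = "") -> Cohort:
    """A cohort whose outcome is Bernoulli with a logit linear in age, age²
    and covariates (coefficients from ``logistic_truth``)."""
    if spec.logistic_truth is None:
        raise ValidationError("logistic_truth is required for logistic-mode generation")
    rng = np.random.default_rng(spec.seed)
    z = _draw_covariates(spec, rng)
    ages = _make_dist(spec.age_dist).rvs(size=spec.n, random_state=rng)
    truth = dict(spec.logistic_truth)
    eta = np.full(spec.n, float(truth.pop("intercept", 0.0)))
    eta += float(truth.pop("age", 0.0)) * ages
    eta += float(truth.pop("age2", 0.0)) * ages ** 2
    for name, beta in truth.items():
        if name not in z.columns:
            raise ValidationError(f"logistic_truth names unknown covariate {name!r}")
        eta += float(beta) * z[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    events = rng.uniform(size=spec.n) < p
    return _attach(spec, ages, events, z, rng, group_label)


def quadratic_age_spec(n: int = 1000, seed: int = 0, **overrides) -> GeneratorSpec:
    """Convenience: the default concave-quadratic logistic-mode recipe."""
    kw = dict(n=n, seed=seed, logistic_truth=dict(DEFAULT_LOGISTIC_TRUTH))
    kw.update(overrides)
    return GeneratorSpec(**kw)
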