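"""Maximum-likelihood fits of baseline hazards to current-status data.

Six parametric families are fit by maximizing the current-status likelihood
(case → ``log F(a)``, control → ``log S(a)``) over the family's parameter
domain, on log-transformed positive parameters with a small deterministic
multi-start (the generalized gamma is notoriously unstable; its convergence
flag is honest, never silent).

The nonparametric maximum-likelihood estimate (NPMLE) of the event-age
distribution under current-status observation is the weighted isotonic
(non-decreasing) regression of the event indicators on observation age —
the pool-adjacent-violators solution, whose block means maximize the
binomial likelihood over all monotone F.  Because the NPMLE maximizes over
every distribution, its -log-likelihood bounds every parametric family's
from below, which is the ranking-table pattern this module reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.isotonic import IsotonicRegression

from .errors import DegenerateDataError, ValidationError
from .hazards import PARAMETRIC_FAMILIES, ParametricHazard, _FAMILY_PARAMS

# parameters optimized on log scale except lognormal's mu (a free real)
_LOG_SCALE = {"rate", "shape", "scale", "sigma", "power"}


def _family_names(family):
    return _FAMILY_PARAMS[family]


def log_sf(family, params, t):
    """log S(t) for one family, evaluated directly through scipy.special
    ufuncs (no frozen-distribution overhead; used in the inner fit loop and
    verified against the distribution objects in tests)."""
    if family == "exponential":
        return -params["rate"] * t
    if family == "weibull":
        return -((t / params["scale"]) ** params["shape"])
    if family == "loglogistic":
        return -np.log1p((t / params["scale"]) ** params["shape"])
    if family == "lognormal":
        return special.log_ndtr(-(np.log(t) - params["mu"]) / params["sigma"])
    with np.errstate(divide="ignore"):
        if family == "gamma":
            return np.log(special.gammaincc(params["shape"], t / params["scale"]))
        if family == "generalized_gamma":
            return np.log(special.gammaincc(
                params["shape"], (t / params["scale"]) ** params["power"]))
    raise ValidationError(f"unknown family {family!r}")


def _from_internal(family, theta):
    names = _family_names(family)
    vals = [np.exp(v) if n in _LOG_SCALE else v for n, v in zip(names, theta)]
    return ParametricHazard(family, dict(zip(names, vals)))


@dataclass
class MLFit:
    """A fitted baseline hazard with its likelihood bookkeeping."""

    model: object
    neg_log_lik: float
    n_params: int
    converged: bool
    aic: float
    label: str = ""


def aic_of(fit: MLFit) -> float:
    """Akaike information criterion, ``2k + 2 * (-log L)``."""
    return 2.0 * fit.n_params + 2.0 * fit.neg_log_lik


def _check_mixed(cohort):
    ev = cohort.events
    if ev.all():
        raise DegenerateDataError("cohort has no controls")
    if not ev.any():
        raise DegenerateDataError("cohort has no cases")


def _starts(family, cohort):
    """Deterministic multi-start values on the natural parameter scale."""
    ages = cohort.observation_ages
    frac = cohort.events.mean()
    mean_age = float(np.mean(ages))
    # crude constant-hazard anchor: F(mean age) = frac -> rate
    rate0 = max(-np.log(max(1.0 - frac, 1e-3)) / max(mean_age, 1.0), 1e-5)
    scale0 = 1.0 / rate0
    mu0 = np.log(max(np.median(ages), 1.0))
    if family == "exponential":
        base = [(rate0,)]
        perturb = [(f,) for f in (0.25, 0.5, 2.0, 4.0)]
    elif family in ("weibull", "gamma", "loglogistic"):
        base = [(1.0, scale0)]
        perturb = [(0.7, 1.0), (1.5, 1.0), (3.0, 0.7), (1.0, 2.0)]
    elif family == "lognormal":
        base = [(mu0, 0.5)]
        perturb = [(1.0, 2.0), (1.0, 0.5), (0.9, 1.0), (1.1, 1.5)]
    elif family == "generalized_gamma":
        base = [(1.0, 1.0, scale0)]
        perturb = [(2.0, 0.7, 1.0), (0.5, 1.5, 1.0), (1.0, 2.0, 0.5), (3.0, 1.0, 1.0)]
    else:
        raise ValidationError(f"unknown family {family!r}")
    starts = [base[0]]
    for fac in perturb:
        if family == "lognormal":
            starts.append((base[0][0] * fac[0], base[0][1] * fac[1]))
        else:
            starts.append(tuple(b * f for b, f in zip(base[0], fac)))
    return starts


def fit_parametric(cohort, family: str, use_weights: bool = False,
                   n_starts: int = 5) -> MLFit:
    """Maximum-likelihood fit of one parametric family.

    Raises :class:`DegenerateDataError` on an all-case or all-control cohort.
    Non-convergence across every start is flagged (``converged=False``), not
    silenced.
    """
    if family not in PARAMETRIC_FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    _check_mixed(cohort)
    names = _family_names(family)

    ages = cohort.observation_ages
    events = cohort.events
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
    else:
        w = np.ones(cohort.n)
    ages_case, w_case = ages[events], w[events]
    ages_ctrl, w_ctrl = ages[~events], w[~events]

    def nll(theta):
        if np.any(np.abs(theta) > 50):
            return 1e12
        params = {n: (np.exp(v) if n in _LOG_SCALE else float(v))
                  for n, v in zip(names, theta)}
        ls_ctrl = log_sf(family, params, ages_ctrl)
        ls_case = log_sf(family, params, ages_case)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_f = np.log(-np.expm1(ls_case))
        ll = float(w_ctrl @ ls_ctrl) + float(w_case @ log_f)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # two-stage multi-start: short exploratory runs from each start, then a
    # full polish from the best point found
    best = None
    for vals in _starts(family, cohort)[:n_starts]:
        theta0 = np.array([np.log(v) if n in _LOG_SCALE else v
                           for n, v in zip(names, vals)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-6,
                                             "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polished = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                     options={"xatol": 1e-7, "fatol": 1e-9,
                                              "maxiter": 2000})
    if polished.fun <= best.fun:
        best = polished
    model = _from_internal(family, best.x)
    return MLFit(model=model, neg_log_lik=float(best.fun),
                 n_params=len(names), converged=bool(polished.success),
                 aic=2.0 * len(names) + 2.0 * float(best.fun),
                 label=family)


@dataclass
class NpmleFit:
    """NPMLE of the event-age distribution under current-status data."""

    jump_ages: np.ndarray   # distinct observation ages, sorted
    F_values: np.ndarray    # non-decreasing event probabilities in [0, 1]
    neg_log_lik: float

    def F(self, ages):
        """Step-function evaluation (right-continuous at jump ages)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        idx = np.searchsorted(self.jump_ages, ages, side="right") - 1
        out = np.where(idx >= 0, self.F_values[np.clip(idx, 0, None)], 0.0)
        return out


def _binomial_nll(F, events, weights):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(events, np.log(F), np.log1p(-F))
    term = np.where((events & (F == 0)) | (~events & (F == 1)), -np.inf, term)
    # 0*log0 conventions: a case at F=1 or control at F=0 contributes 0
    term = np.where(events & (F == 1), 0.0, term)
    term = np.where(~events & (F == 0), 0.0, term)
    return -float(np.sum(weights * term))


def npmle_current_status(cohort, use_weights: bool = False) -> NpmleFit:
    """Pool-adjacent-violators NPMLE of F from current-status data.

    Ties in observation age are pre-pooled; survey weights (when requested)
    enter as isotonic-regression weights.
    """
    ages = cohort.observation_ages
    events = cohort.events.astype(float)
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
    else:
        w = np.ones_like(ages)
    order = np.argsort(ages, kind="stable")
    ages, events, w = ages[order], events[order], w[order]
    # pre-pool tied ages
    uniq, inv = np.unique(ages, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    ev_mean = np.bincount(inv, weights=w * events) / wsum
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    F = iso.fit_transform(uniq, ev_mean, sample_weight=wsum)
    nll = _binomial_nll(F[inv], events.astype(bool), w)
    return NpmleFit(jump_ages=uniq, F_values=np.asarray(F), neg_log_lik=nll)


def rank_families(cohort, families=PARAMETRIC_FAMILIES,
                  use_weights: bool = False) -> pd.DataFrame:
    """Likelihood-ranking table: NPMLE plus each parametric family, sorted
    ascending by -log-likelihood (the NPMLE is always first or tied-first)."""
    rows = []
    np_fit = npmle_current_status(cohort, use_weights=use_weights)
    rows.append({"distribution": "Nonparametric",
                 "neg_log_lik": np_fit.neg_log_lik,
                 "n_params": np.nan, "converged": True, "aic": np.nan})
    for family in families:
        fit = fit_parametric(cohort, family, use_weights=use_weights)
        rows.append({"distribution": family, "neg_log_lik": fit.neg_log_lik,
                     "n_params": fit.n_params, "converged": fit.converged,
                     "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values("neg_log_lik", kind="stable")
    return table.reset_index(drop=True)
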