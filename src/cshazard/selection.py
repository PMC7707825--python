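"""Covariate screening for logistic case/control models.

Implements a four-step forward-backward selection over a candidate pool,
always retaining the base terms (age and age², since prevalence rises and
then flattens with age):

1. *single*: one logistic fit per candidate (base terms plus the lone
   candidate); candidates with Wald p < threshold advance;
2. *backward*: a joint fit of all advancing candidates, repeatedly dropping
   the least significant (largest p above the threshold, one at a time,
   refitting after each removal);
3. *forward*: each candidate not significant in step 1 is reconsidered
   against the step-2 model and kept if it now reaches significance;
4. *prune*: a final backward pass on the step-3 model.

Supporting statistics: a deviance-based pseudo-r²
``(1 - exp((D1 - D0)/n)) / (1 - exp(-D0/n))`` for variance accounting,
Welch's unequal-variance t-test for sex-dimorphism screens, and an AIC
screen that compares the selected model against versions augmented with one
age × covariate interaction at a time (a proxy for time-dependent effects).

Frequentist ML fits (statsmodels GLM) drive the selection; the selected
model is intended to be refit with :func:`cshazard.mcmc.fit_bayes_logistic`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

BASE_TERMS = ("age", "age2")


def pseudo_r2(d1: float, d0: float, n: int) -> float:
    """Deviance-based variance-explained analogue for binary outcomes:
    ``(1 - exp((d1 - d0)/n)) / (1 - exp(-d0/n))``.

    Equals 0 when the model deviance matches the null deviance and 1 when
    the model fits perfectly (d1 = 0).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if d0 <= 0:
        raise ValidationError("null deviance must be positive")
    num = 1.0 - math.exp((d1 - d0) / n)
    den = 1.0 - math.exp(-d0 / n)
    return num / den


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple:
    """Welch's unequal-variance t-test from group summaries.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite fractional degrees
    of freedom and a two-sided p-value.  Zero variance in both groups with
    equal means returns ``t = 0, p = 1`` by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValidationError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# logistic fitting helpers
# ---------------------------------------------------------------------------

def _design(cohort, terms):
    ages = cohort.observation_ages
    cols, names = [np.ones(cohort.n)], ["intercept"]
    for t in terms:
        if t == "age":
            cols.append(ages)
        elif t == "age2":
            cols.append(ages ** 2)
        elif "*" in t:  # interaction term "age*name"
            _, name = t.split("*", 1)
            cols.append(ages * cohort.covariate_array(name))
        else:
            cols.append(cohort.covariate_array(t))
        names.append(t)
    return np.column_stack(cols), names


@dataclass
class LogisticFit:
    terms: tuple
    deviance: float
    llf: float
    n_params: int
    aic: float
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    names: tuple


def fit_logistic_ml(cohort, terms: Sequence[str],
                    use_weights: bool = False) -> LogisticFit:
    """Frequentist ML logistic fit (GLM with binomial family)."""
    X, names = _design(cohort, terms)
    y = cohort.events.astype(float)
    kw = {}
    if use_weights:
        w = cohort.weights
        if w is None:
            raise ValidationError("cohort carries no survey weights")
        kw["freq_weights"] = w
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial(), **kw).fit()
    return LogisticFit(terms=tuple(terms), deviance=float(res.deviance),
                       llf=float(res.llf), n_params=X.shape[1],
                       aic=float(2 * X.shape[1] - 2 * res.llf),
                       params=np.asarray(res.params),
                       bse=np.asarray(res.bse),
                       pvalues=np.asarray(res.pvalues), names=tuple(names))


def _candidate_p(fit: LogisticFit, candidate: str) -> float:
    return float(fit.pvalues[list(fit.names).index(candidate)])


@dataclass
class SelectionStep:
    step: str          # single / backward / forward / prune
    candidate: str
    p_value: float
    action: str        # enter / remove / keep / skip


@dataclass
class SelectionTrace:
    """Audit trail of the four-phase selection."""

    steps: list = field(default_factory=list)
    final_terms: list = field(default_factory=list)
    base_terms: tuple = BASE_TERMS
    final_fit: Optional[LogisticFit] = None

    def log(self, step, candidate, p, action):
        self.steps.append(SelectionStep(step, candidate, p, action))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def _safe_fit(cohort, terms, use_weights):
    X, _ = _design(cohort, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None  # collinear / singular design
    try:
        fit = fit_logistic_ml(cohort, terms, use_weights)
    except Exception:
        return None
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e6):
        return None
    return fit


def forward_backward(cohort, candidate_pool: Sequence[str],
                     base_terms: Sequence[str] = BASE_TERMS,
                     threshold: float = 0.05,
                     adjust_base_in_single: bool = True,
                     use_weights: bool = False) -> SelectionTrace:
    """Four-step forward-backward covariate selection (see module docs).

    Deterministic given the candidate-pool ordering: step-1 screens run in
    pool order, backward removals drop the largest p first (one at a time,
    refitting), forward reconsideration runs in pool order.  Candidates
    whose fits are singular/collinear are skipped with a warning.
    """
    base = list(base_terms)
    trace = SelectionTrace(base_terms=tuple(base))
    usable, single_sig, single_nonsig = [], [], []

    for cand in candidate_pool:
        single_terms = (base + [cand]) if adjust_base_in_single else [cand]
        fit = _safe_fit(cohort, single_terms, use_weights)
        if fit is None:
            warnings.warn(f"candidate {cand!r} skipped: singular or "
                          "non-finite single fit", RuntimeWarning, stacklevel=2)
            trace.log("single", cand, math.nan, "skip")
            continue
        usable.append(cand)
        p = _candidate_p(fit, cand)
        if p < threshold:
            single_sig.append(cand)
            trace.log("single", cand, p, "enter")
        else:
            single_nonsig.append(cand)
            trace.log("single", cand, p, "keep")  # kept aside for step 3

    def backward(current, phase):
        while current:
            fit = _safe_fit(cohort, base + current, use_weights)
            if fit is None:
                # drop the last-entered candidate to restore identifiability
                dropped = current.pop()
                warnings.warn(f"candidate {dropped!r} dropped: joint fit is "
                              "singular or collinear", RuntimeWarning,
                              stacklevel=3)
                trace.log(phase, dropped, math.nan, "remove")
                continue
            ps = {c: _candidate_p(fit, c) for c in current}
            worst = max(ps, key=lambda c: ps[c])
            if ps[worst] >= threshold:
                trace.log(phase, worst, ps[worst], "remove")
                current.remove(worst)
            else:
                for c in current:
                    trace.log(phase, c, ps[c], "keep")
                return current, fit
        return current, _safe_fit(cohort, base, use_weights)

    current, fit = backward(list(single_sig), "backward")

    for cand in single_nonsig:
        fit_try = _safe_fit(cohort, base + current + [cand], use_weights)
        if fit_try is None:
            trace.log("forward", cand, math.nan, "skip")
            continue
        p = _candidate_p(fit_try, cand)
        if p < threshold:
            current.append(cand)
            trace.log("forward", cand, p, "enter")
        else:
            trace.log("forward", cand, p, "keep")

    current, fit = backward(current, "prune")
    trace.final_terms = base + current
    trace.final_fit = fit
    return trace


def variance_explained(cohort, term_sets: Sequence[Sequence[str]],
                       use_weights: bool = False) -> pd.DataFrame:
    """Pseudo-r² ledger along a nested sequence of term sets.

    Each set must contain the previous one.  The null deviance is the
    intercept-only deviance; rows report each model's deviance, pseudo-r²
    and the increment over the previous row.
    """
    for a, b in zip(term_sets, term_sets[1:]):
        if not set(a) <= set(b):
            raise ValidationError(f"term sets are not nested: {a} vs {b}")
    null = fit_logistic_ml(cohort, [], use_weights)
    d0 = null.deviance
    rows, prev = [], 0.0
    for terms in term_sets:
        fit = fit_logistic_ml(cohort, list(terms), use_weights)
        r2 = pseudo_r2(fit.deviance, d0, cohort.n) if terms else 0.0
        rows.append({"terms": "+".join(terms) if terms else "(null)",
                     "deviance": fit.deviance, "r2": r2,
                     "delta_r2": r2 - prev, "d0": d0, "n": cohort.n})
        prev = r2
    return pd.DataFrame(rows)


def interaction_aic_screen(cohort, final_terms: Sequence[str],
                           use_weights: bool = False) -> pd.DataFrame:
    """AIC comparison of the selected model against one-at-a-time age ×
    covariate augmentations (a time-dependence screen).

    The verdict column of the base row is ``"time-dependence unsupported"``
    when every interaction row's AIC exceeds the base AIC.
    """
    final_terms = list(final_terms)
    covs = [t for t in final_terms if t not in BASE_TERMS]
    base_fit = fit_logistic_ml(cohort, final_terms, use_weights)
    rows = [{"interaction": "none", "aic": base_fit.aic}]
    for cov in covs:
        fit = fit_logistic_ml(cohort, final_terms + [f"age*{cov}"], use_weights)
        rows.append({"interaction": f"age*{cov}", "aic": fit.aic})
    table = pd.DataFrame(rows)
    base_aic = table.loc[0, "aic"]
    supported = (table["aic"][1:] < base_aic).any()
    table["verdict"] = ""
    table.loc[0, "verdict"] = ("time-dependence unsupported" if not supported
                               else "some interaction improves AIC")
    return table
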