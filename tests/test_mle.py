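import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import golden

from cshazard.errors import DegenerateDataError
from cshazard.hazards import ParametricHazard, current_status_loglik
from cshazard.mle import (
    MLFit,
    aic_of,
    fit_parametric,
    npmle_current_status,
    rank_families,
)
from cshazard.simulate import GeneratorSpec, simulate_current_status
from conftest import make_cohort


def brute_force_npmle(ages, events):
    """Independent NPMLE oracle: enumerate contiguous-block partitions of the
    age-ordered points, assign each block its event fraction, keep monotone
    assignments, and maximize the binomial log-likelihood."""
    order = np.argsort(ages, kind="stable")
    srt_ages = np.asarray(ages, dtype=float)[order]
    ev = np.asarray(events, dtype=float)[order]
    n = len(ev)
    # cuts may fall only between distinct ages (tied ages share one F value)
    cut_ok = [srt_ages[i + 1] > srt_ages[i] for i in range(n - 1)]
    best_ll, best_F = -np.inf, None
    for cuts in itertools.product([0, 1], repeat=n - 1):
        if any(c and not ok for c, ok in zip(cuts, cut_ok)):
            continue
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [ev[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        F = np.concatenate([[m] * (b - a)
                            for (a, b), m in zip(zip(bounds, bounds[1:]), means)])
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(ev == 1, np.log(F), np.log1p(-F))
        ll = np.where((ev == 1) & (F == 1), 0.0, ll)
        ll = np.where((ev == 0) & (F == 0), 0.0, ll)
        total = ll.sum()
        if total > best_ll + 1e-12:
            best_ll, best_F = total, F
    return best_F, -best_ll


class TestFastLogSf:
    def test_matches_distribution_objects(self):
        """The ufunc-based log-survival used inside the fit loop agrees with
        the scipy distribution objects for every family."""
        from cshazard.mle import log_sf
        from test_hazards import random_model
        rng = np.random.default_rng(77)
        t = np.array([1.0, 10.0, 35.0, 60.0, 90.0, 130.0])
        from cshazard.hazards import PARAMETRIC_FAMILIES
        for family in PARAMETRIC_FAMILIES:
            for _ in range(3):
                m = random_model(family, rng)
                np.testing.assert_allclose(log_sf(family, m.params, t),
                                           m._dist().logsf(t),
                                           rtol=1e-9, atol=1e-12)


class TestNpmle:
    def test_separated_two_points(self):
        fit = npmle_current_status(make_cohort([1.0, 2.0], [False, True]))
        np.testing.assert_allclose(fit.F_values, [0.0, 1.0])
        assert fit.neg_log_lik == pytest.approx(0.0, abs=1e-12)

    def test_pooled_two_points(self):
        fit = npmle_current_status(make_cohort([1.0, 2.0], [True, False]))
        np.testing.assert_allclose(fit.F_values, [0.5, 0.5])
        assert fit.neg_log_lik == pytest.approx(-2 * math.log(0.5))

    def test_all_controls(self):
        fit = npmle_current_status(make_cohort([1.0, 2.0, 3.0], [False] * 3))
        assert np.all(fit.F_values == 0.0)

    def test_single_age_degenerate(self):
        fit = npmle_current_status(make_cohort([5.0, 5.0, 5.0, 5.0],
                                               [True, False, False, True]))
        np.testing.assert_allclose(fit.F_values, [0.5])

    @given(st.lists(st.tuples(st.integers(0, 9), st.booleans()),
                    min_size=2, max_size=6))
    @settings(max_examples=150, deadline=None)
    def test_pava_matches_exhaustive_oracle(self, recs):
        ages = np.array([float(a) for a, _ in recs])
        events = np.array([e for _, e in recs], dtype=bool)
        fit = npmle_current_status(make_cohort(ages, events))
        _, oracle_nll = brute_force_npmle(ages, events)
        assert fit.neg_log_lik == pytest.approx(oracle_nll, abs=1e-9)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        coh = make_cohort(rng.uniform(18, 85, 200), rng.random(200) < 0.5)
        fit = npmle_current_status(coh)
        assert np.all(np.diff(fit.F_values) >= -1e-12)
        assert np.all((fit.F_values >= 0) & (fit.F_values <= 1))


class TestParametricFits:
    def test_exponential_recovery_matches_1d_oracle(self, exp_cohort):
        fit = fit_parametric(exp_cohort, "exponential")
        lam_hat = fit.model.params["rate"]
        assert lam_hat == pytest.approx(0.02, rel=0.10)
        # oracle: golden-section search on the 1-D profile likelihood
        nll = lambda loglam: -current_status_loglik(
            ParametricHazard("exponential", {"rate": math.exp(loglam)}), exp_cohort)
        opt = golden(nll, brack=(math.log(0.001), math.log(0.1)), tol=1e-10)
        assert lam_hat == pytest.approx(math.exp(opt), rel=1e-3)
        assert fit.neg_log_lik == pytest.approx(nll(opt), abs=1e-4)

    def test_weibull_on_exponential_data_has_shape_near_one(self, exp_cohort):
        exp_fit = fit_parametric(exp_cohort, "exponential")
        weib_fit = fit_parametric(exp_cohort, "weibull")
        assert weib_fit.model.params["shape"] == pytest.approx(1.0, abs=0.15)
        # 1-df nesting: likelihoods within a likelihood-ratio bound
        assert exp_fit.neg_log_lik - weib_fit.neg_log_lik < 2.0
        assert weib_fit.neg_log_lik <= exp_fit.neg_log_lik + 1e-6

    def test_degenerate_cohorts_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_parametric(make_cohort([30.0, 40.0], [False, False]), "exponential")
        with pytest.raises(DegenerateDataError):
            fit_parametric(make_cohort([30.0, 40.0], [True, True]), "weibull")


class TestRanking:
    def test_npmle_first_and_sorted(self, default_cohort):
        table = rank_families(default_cohort,
                              families=("exponential", "weibull", "lognormal"))
        nll = table["neg_log_lik"].to_numpy()
        assert np.all(np.diff(nll) >= -1e-9)
        assert table.iloc[0]["distribution"] == "Nonparametric"

    def test_lognormal_data_ranks_lognormal_above_exponential(self, default_cohort):
        table = rank_families(default_cohort,
                              families=("exponential", "lognormal"))
        rows = {r["distribution"]: r["neg_log_lik"] for _, r in table.iterrows()}
        assert rows["lognormal"] < rows["exponential"]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_npmle_dominates_any_parametric_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        ages = rng.uniform(18, 85, n)
        events = rng.random(n) < np.clip((ages - 18) / 80, 0.05, 0.95)
        if events.all() or not events.any():
            return
        coh = make_cohort(ages, events)
        np_nll = npmle_current_status(coh).neg_log_lik
        # dominance holds against ANY distribution, fitted or not
        for model in (ParametricHazard("exponential", {"rate": rng.uniform(0.001, 0.1)}),
                      ParametricHazard("lognormal", {"mu": 3.8, "sigma": 0.6})):
            assert np_nll <= -current_status_loglik(model, coh) + 1e-9


class TestAic:
    def test_formula(self):
        fit = MLFit(model=None, neg_log_lik=100.0, n_params=2, converged=True,
                    aic=204.0)
        assert aic_of(fit) == 204.0

    def test_extra_parameter_raises_aic_on_average(self):
        # exponential truth: the weibull's extra df should cost AIC on average
        diffs = []
        for seed in range(8):
            spec = GeneratorSpec(
                n=1500, seed=seed,
                baseline=ParametricHazard("exponential", {"rate": 0.02}))
            coh = simulate_current_status(spec)
            diffs.append(aic_of(fit_parametric(coh, "weibull"))
                         - aic_of(fit_parametric(coh, "exponential")))
        assert np.mean(diffs) > 0
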