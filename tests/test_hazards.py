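import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cshazard.errors import NoMedianError, ValidationError
from cshazard.hazards import (
    PARAMETRIC_FAMILIES,
    CureMixture,
    ParametricHazard,
    PHModel,
    PiecewiseConstantHazard,
    current_status_loglik,
    median_event_age,
    model_from_dict,
    population_survival,
    survival_at,
)
from conftest import make_cohort

GRID = np.array([0.5, 1.0, 5.0, 20.0, 50.0, 80.0, 120.0])


def random_model(family, rng):
    draws = {
        "exponential": lambda: {"rate": rng.uniform(0.005, 0.1)},
        "weibull": lambda: {"shape": rng.uniform(0.5, 4), "scale": rng.uniform(20, 90)},
        "gamma": lambda: {"shape": rng.uniform(0.5, 5), "scale": rng.uniform(5, 60)},
        "lognormal": lambda: {"mu": rng.uniform(2.5, 4.5), "sigma": rng.uniform(0.2, 1.2)},
        "loglogistic": lambda: {"shape": rng.uniform(1, 6), "scale": rng.uniform(20, 90)},
        "generalized_gamma": lambda: {"shape": rng.uniform(0.5, 3),
                                      "power": rng.uniform(0.5, 2.5),
                                      "scale": rng.uniform(10, 80)},
    }
    return ParametricHazard(family, draws[family]())


class TestParametricFamilies:
    def test_exponential_closed_forms(self):
        m = ParametricHazard("exponential", {"rate": 0.01})
        assert m.cumulative_hazard(50.0) == pytest.approx(0.5)
        assert m.survival(50.0) == pytest.approx(math.exp(-0.5))
        assert np.allclose(m.hazard(GRID), 0.01)
        assert median_event_age(m) == pytest.approx(100 * math.log(2))

    @pytest.mark.parametrize("family", PARAMETRIC_FAMILIES)
    def test_survival_equals_exp_neg_cumhaz(self, family):
        rng = np.random.default_rng(abs(hash(family)) % 2**31)
        for _ in range(5):
            m = random_model(family, rng)
            np.testing.assert_allclose(m.survival(GRID),
                                       np.exp(-m.cumulative_hazard(GRID)),
                                       atol=1e-10)
            H = m.cumulative_hazard(GRID)
            assert np.all(np.diff(H) >= -1e-12)
            assert m.survival(0.0) == pytest.approx(1.0)

    def test_weibull_shape_one_is_exponential(self):
        w = ParametricHazard("weibull", {"shape": 1.0, "scale": 50.0})
        e = ParametricHazard("exponential", {"rate": 1 / 50.0})
        np.testing.assert_allclose(w.hazard(GRID), e.hazard(GRID), rtol=1e-9)

    def test_generalized_gamma_nests_gamma_and_weibull(self):
        gg_as_gamma = ParametricHazard("generalized_gamma",
                                       {"shape": 2.5, "power": 1.0, "scale": 30.0})
        g = ParametricHazard("gamma", {"shape": 2.5, "scale": 30.0})
        np.testing.assert_allclose(gg_as_gamma.survival(GRID), g.survival(GRID),
                                   rtol=1e-9)
        gg_as_weib = ParametricHazard("generalized_gamma",
                                      {"shape": 1.0, "power": 1.8, "scale": 40.0})
        w = ParametricHazard("weibull", {"shape": 1.8, "scale": 40.0})
        np.testing.assert_allclose(gg_as_weib.survival(GRID), w.survival(GRID),
                                   rtol=1e-9)

    def test_lognormal_hazard_is_unimodal(self):
        m = ParametricHazard("lognormal", {"mu": math.log(48), "sigma": 0.49})
        t = np.linspace(1, 150, 600)
        h = m.hazard(t)
        # oracle: numeric f/S from the density
        d = m._dist()
        np.testing.assert_allclose(h, d.pdf(t) / d.sf(t), rtol=1e-8)
        peak = np.argmax(h)
        assert np.all(np.diff(h[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(h[peak:]) <= 1e-12)

    def test_negative_age_rejected(self):
        m = ParametricHazard("exponential", {"rate": 0.01})
        with pytest.raises(ValidationError):
            m.cumulative_hazard(-1.0)

    def test_bad_params_rejected(self):
        with pytest.raises(ValidationError):
            ParametricHazard("weibull", {"shape": -1, "scale": 10})
        with pytest.raises(ValidationError):
            ParametricHazard("weibull", {"shape": 1.0})


class TestPiecewise:
    def test_constant_rates_sum(self):
        m = PiecewiseConstantHazard(0.0, [0.02] * 20)
        assert m.cumulative_hazard(10.0) == pytest.approx(0.2)
        assert m.survival(10.0) == pytest.approx(math.exp(-0.2))
        assert m.hazard(5.5) == pytest.approx(0.02)

    def test_partial_bin(self):
        m = PiecewiseConstantHazard(0.0, [0.1, 0.2, 0.3])
        assert m.cumulative_hazard(1.5) == pytest.approx(0.1 + 0.1)

    def test_tail_rules(self):
        ext = PiecewiseConstantHazard(0.0, [0.1, 0.2], tail_rule="extend")
        zero = PiecewiseConstantHazard(0.0, [0.1, 0.2], tail_rule="zero")
        assert ext.cumulative_hazard(4.0) == pytest.approx(0.3 + 2 * 0.2)
        assert zero.cumulative_hazard(4.0) == pytest.approx(0.3)
        assert zero.hazard(4.0) == 0.0

    def test_cumhaz_matches_quadrature(self):
        rng = np.random.default_rng(5)
        m = PiecewiseConstantHazard(18.0, rng.uniform(0, 0.1, size=10))
        for t in (18.0, 19.3, 23.7, 28.0, 31.5):
            num, _ = quad(lambda u: m.hazard(u), 0, t, limit=400,
                          points=np.arange(18, min(t, 28) + 1))
            assert m.cumulative_hazard(t) == pytest.approx(num, abs=1e-8)

    def test_quantile_inverts_cumhaz(self):
        m = PiecewiseConstantHazard(18.0, [0.0, 0.05, 0.0, 0.1, 0.2])
        for s in (0.99, 0.9, 0.7):
            t = m.quantile_event_age(s)
            assert m.survival(t) == pytest.approx(s, abs=1e-9)


class TestLayers:
    def test_ph_power_property(self):
        base = ParametricHazard("weibull", {"shape": 2.0, "scale": 60.0})
        m = PHModel(base, {"z": math.log(2)})
        z = {"z": 1.0}
        np.testing.assert_allclose(m.survival(GRID, z), base.survival(GRID) ** 2,
                                   rtol=1e-10)
        assert PHModel(base, {}).survival(40.0) == base.survival(40.0)

    def test_cure_plateau_and_reduction(self):
        base = ParametricHazard("exponential", {"rate": 0.05})
        cure = CureMixture(0.2, PHModel(base))
        assert cure.population_survival(1e6) == pytest.approx(0.2)
        assert CureMixture(0.0, PHModel(base)).population_survival(30.0) == \
            pytest.approx(base.survival(30.0))
        assert CureMixture(1.0, PHModel(base)).population_survival(50.0) == 1.0

    def test_median_with_cure(self):
        base = ParametricHazard("exponential", {"rate": 0.02})
        assert median_event_age(base) == pytest.approx(math.log(2) / 0.02)
        with pytest.raises(NoMedianError):
            median_event_age(CureMixture(0.6, PHModel(base)))

    def test_survival_at(self):
        m = ParametricHazard("exponential", {"rate": 0.02})
        assert survival_at(m, 85.0) == pytest.approx(math.exp(-1.7))

    def test_serialization_roundtrip(self):
        m = CureMixture(0.1, PHModel(
            PiecewiseConstantHazard(18.0, [0.01, 0.02]), {"w": 0.3}))
        back = model_from_dict(m.to_dict())
        assert population_survival(back, 19.5, {"w": 1.0}) == pytest.approx(
            population_survival(m, 19.5, {"w": 1.0}))


class TestCurrentStatusLoglik:
    def test_single_case_at_half(self):
        m = ParametricHazard("exponential", {"rate": math.log(2) / 50})
        coh = make_cohort([50.0], [True])
        assert current_status_loglik(m, coh) == pytest.approx(math.log(0.5))

    def test_all_controls_zero_hazard(self):
        m = PiecewiseConstantHazard(0.0, [0.0] * 100, tail_rule="zero")
        coh = make_cohort([20.0, 40.0, 60.0], [False] * 3)
        assert current_status_loglik(m, coh) == 0.0

    def test_hand_summed_toy(self):
        # oracle: per-record closed-form contributions summed by hand
        m = ParametricHazard("exponential", {"rate": 0.01})
        coh = make_cohort([30.0, 50.0, 70.0], [True, False, True])
        expected = (math.log(1 - math.exp(-0.3)) - 0.5
                    + math.log(1 - math.exp(-0.7)))
        assert current_status_loglik(m, coh) == pytest.approx(expected, rel=1e-12)

    def test_impossible_case_gives_neg_inf_with_warning(self):
        m = PiecewiseConstantHazard(0.0, [0.0] * 100, tail_rule="zero")
        coh = make_cohort([30.0], [True])
        with pytest.warns(RuntimeWarning):
            assert current_status_loglik(m, coh) == -math.inf

    def test_covariate_mismatch_errors(self):
        m = PHModel(ParametricHazard("exponential", {"rate": 0.01}), {"bmi": 0.1})
        coh = make_cohort([30.0], [True])
        with pytest.raises(ValidationError):
            current_status_loglik(m, coh)

    @given(pi=st.floats(0.0, 0.9), rate=st.floats(0.001, 0.2))
    @settings(max_examples=60, deadline=None)
    def test_cure_loglik_matches_direct_formula(self, pi, rate):
        m = CureMixture(pi, PHModel(ParametricHazard("exponential", {"rate": rate})))
        coh = make_cohort([40.0, 60.0], [True, False])
        sp = lambda t: pi + (1 - pi) * math.exp(-rate * t)
        expected = math.log(1 - sp(40.0)) + math.log(sp(60.0))
        assert current_status_loglik(m, coh) == pytest.approx(expected, rel=1e-10)
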