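import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ode_profile
from tacpk.core_model import (
    DoseEvent,
    PKParameters,
    PopulationModel,
    RandomEffects,
    apply_residual_error,
    concentration_profile,
    individual_params,
    residual_variance,
    typical_clearance,
    typical_volume,
)


class TestTypicalValues:
    def test_reference_weight_returns_typical(self, model):
        assert typical_clearance(model, 70.0) == pytest.approx(13.1)
        assert typical_volume(model, 70.0) == pytest.approx(10900.0)

    def test_per_kg_clearance_range(self, model):
        # 0.36 L/h/kg at 5 kg and 0.26 L/h/kg at 20 kg
        assert typical_clearance(model, 5.0) == pytest.approx(1.810, abs=5e-4)
        assert round(typical_clearance(model, 5.0) / 5.0, 2) == 0.36
        assert typical_clearance(model, 20.0) == pytest.approx(5.119, abs=5e-4)
        assert round(typical_clearance(model, 20.0) / 20.0, 2) == 0.26

    def test_volume_scales_linearly(self, model):
        assert typical_volume(model, 7.0) == pytest.approx(1090.0)
        assert typical_volume(model, 35.0) == pytest.approx(5450.0)

    @pytest.mark.parametrize("weight", [0.0, -1.0])
    def test_nonpositive_weight_rejected(self, model, weight):
        with pytest.raises(ValueError):
            typical_clearance(model, weight)
        with pytest.raises(ValueError):
            typical_volume(model, weight)

    @given(st.floats(min_value=1.0, max_value=69.0))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, w):
        m = PopulationModel()
        assert typical_clearance(m, w + 1.0) > typical_clearance(m, w)
        assert typical_volume(m, w + 1.0) > typical_volume(m, w)
        # per-kg clearance decreases with weight (0.36 -> 0.26 trend)
        assert typical_clearance(m, w) / w > typical_clearance(m, w + 1.0) / (w + 1.0)


class TestIndividualParams:
    def test_zero_eta_is_identity(self, model):
        p = individual_params(model, 70.0, RandomEffects(0.0, 0.0))
        assert (p.cl_f, p.v_f, p.ka) == pytest.approx((13.1, 10900.0, 4.48))

    def test_log2_eta_doubles_clearance(self, model):
        p = individual_params(model, 70.0, RandomEffects(math.log(2.0), 0.0))
        assert p.cl_f == pytest.approx(26.2)

    def test_lognormal_median(self, model, rng):
        # median of CL/F across eta draws equals the typical value
        etas = rng.normal(0.0, 0.451, size=100_000)
        cls = 13.1 * np.exp(etas)
        assert np.median(cls) == pytest.approx(13.1, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(cl_f=-1.0, v_f=100.0, ka=4.48)
        with pytest.raises(ValueError):
            PKParameters(cl_f=1.0, v_f=0.0, ka=4.48)
        with pytest.raises(ValueError):
            RandomEffects(float("nan"), 0.0)


class TestConcentrationProfile:
    def test_zero_before_first_dose(self):
        p = PKParameters(3.0, 1500.0, 4.48)
        doses = [DoseEvent(10.0, 5.0)]
        conc = concentration_profile(p, doses, [0.0, 5.0, 9.999, 10.0])
        assert np.all(conc == 0.0)

    def test_matches_ode_oracle_single_dose(self):
        p = PKParameters(3.044, 1557.0, 4.48)
        doses = [DoseEvent(0.0, 3.0)]
        times = [0.5, 1.0, 2.0, 6.0, 12.0, 24.0, 48.0, 96.0]
        closed = concentration_profile(p, doses, times)
        oracle = ode_profile(p, doses, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_linearity_in_dose(self):
        p = PKParameters(2.0, 900.0, 4.48)
        times = [3.0, 20.0, 50.0]
        d1 = [DoseEvent(0.0, 1.5), DoseEvent(12.0, 1.5)]
        d2 = [DoseEvent(0.0, 3.0), DoseEvent(12.0, 3.0)]
        np.testing.assert_allclose(
            concentration_profile(p, d2, times),
            2.0 * concentration_profile(p, d1, times),
            rtol=1e-12,
        )

    def test_split_dose_invariance(self):
        p = PKParameters(2.0, 900.0, 4.48)
        times = [5.0, 30.0]
        whole = concentration_profile(p, [DoseEvent(0.0, 4.0)], times)
        split = concentration_profile(
            p, [DoseEvent(0.0, 1.0), DoseEvent(0.0, 3.0)], times
        )
        np.testing.assert_allclose(whole, split, rtol=1e-12)

    def test_ka_equals_ke_limit(self):
        # flip-flop boundary: limit form must match the ODE solution
        v = 100.0
        ka = 0.5
        p = PKParameters(cl_f=ka * v, v_f=v, ka=ka)
        doses = [DoseEvent(0.0, 10.0)]
        times = [0.5, 1.0, 4.0, 10.0]
        closed = concentration_profile(p, doses, times)
        oracle = ode_profile(p, doses, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-5)

    def test_unit_conversion_contract(self):
        # at t >> 1/ka with no elimination-worth of time, nearly the whole
        # dose is in the central compartment: C ~ D/V mg/L = 1000*D/V ng/ml
        p = PKParameters(cl_f=1e-6, v_f=50.0, ka=20.0)
        conc = concentration_profile(p, [DoseEvent(0.0, 5.0)], [2.0])
        assert conc[0] == pytest.approx(1000.0 * 5.0 / 50.0, rel=1e-4)

    def test_empty_doses_gives_zero(self):
        p = PKParameters(3.0, 1500.0, 4.48)
        assert np.all(concentration_profile(p, [], [1.0, 2.0]) == 0.0)

    def test_negative_time_rejected(self):
        p = PKParameters(3.0, 1500.0, 4.48)
        with pytest.raises(ValueError):
            concentration_profile(p, [DoseEvent(0.0, 1.0)], [-1.0])

    def test_random_regimens_match_ode_oracle(self, rng):
        # randomized parameters/regimens vs independent numerical integration
        for _ in range(25):
            p = PKParameters(
                cl_f=float(rng.uniform(0.5, 20.0)),
                v_f=float(rng.uniform(50.0, 5000.0)),
                ka=float(rng.uniform(0.5, 8.0)),
            )
            n_dose = int(rng.integers(1, 8))
            doses = [
                DoseEvent(float(12.0 * k), float(rng.uniform(0.5, 10.0)))
                for k in range(n_dose)
            ]
            times = np.sort(rng.uniform(0.5, 12.0 * n_dose + 24.0, size=5))
            closed = concentration_profile(p, doses, times)
            oracle = ode_profile(p, doses, times)
            np.testing.assert_allclose(closed, oracle, rtol=1e-6, atol=1e-12)


class TestResidualError:
    def test_zero_eps_identity(self, model):
        assert apply_residual_error(model, 10.0, (0.0, 0.0)) == 10.0

    def test_direct_evaluation(self, model):
        assert apply_residual_error(model, 10.0, (0.1, -0.5)) == pytest.approx(10.5)

    def test_variance_formula(self, model):
        np.testing.assert_allclose(
            residual_variance(model, np.array([10.0])),
            [100.0 * 0.257**2 + 1.265**2],
        )

    def test_empirical_sd_matches_closed_form(self, model, rng):
        n = 1_000_000
        eps1 = rng.normal(0.0, 0.257, n)
        eps2 = rng.normal(0.0, 1.265, n)
        out = apply_residual_error(model, np.full(n, 10.0), (eps1, eps2))
        expected = math.sqrt(100.0 * 0.257**2 + 1.265**2)
        assert expected == pytest.approx(2.8645, abs=5e-4)
        assert np.std(out) == pytest.approx(expected, rel=0.01)

    def test_negative_prediction_rejected(self, model):
        with pytest.raises(ValueError):
            apply_residual_error(model, -1.0, (0.0, 0.0))


class TestPopulationModelValidation:
    def test_defaults_are_final_model(self, model):
        assert model.tv_cl == 13.1
        assert model.tv_v == 10900.0
        assert model.ka_fixed == 4.48
        assert model.ref_weight == 70.0
        assert (model.exp_cl, model.exp_v) == (0.75, 1.0)
        assert (model.omega_cl, model.omega_v) == (0.451, 0.592)
        assert (model.sigma_prop, model.sigma_add) == (0.257, 1.265)

    @pytest.mark.parametrize(
        "bad", [{"tv_cl": 0.0}, {"ref_weight": -1.0}, {"omega_cl": -0.1}]
    )
    def test_invalid_fields_rejected(self, bad):
        with pytest.raises(ValueError):
            PopulationModel(**bad)
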