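import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copkpd.model import (
    bis_model,
    co_profile,
    individual_from_population,
    pk_rhs,
    residual_loglik,
    scaled_clearances,
)
from copkpd.params import CovariateRecord


class TestCoProfile:
    def test_baseline_at_induction(self):
        assert co_profile(0.0, 5.59, 1.09) == pytest.approx(5.59)

    def test_plateau_after_300_min(self):
        assert co_profile(400.0, 5.59, 1.09) == co_profile(300.0, 5.59, 1.09)

    def test_value_at_breakpoint(self):
        # 5.59 + 1.09 L/min/h * 5 h
        assert co_profile(300.0, 5.59, 1.09) == pytest.approx(11.04)

    def test_affine_then_constant_and_continuous(self):
        t = np.linspace(0, 600, 1201)
        co = co_profile(t, 5.59, 1.09)
        rising = t <= 300
        slopes = np.diff(co) / np.diff(t)
        assert np.allclose(slopes[rising[:-1] & rising[1:]], 1.09 / 60)
        assert np.allclose(co[t > 300], co_profile(300.0, 5.59, 1.09))
        assert np.all(np.abs(np.diff(co)) < 1.0)  # no jumps

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="t >= 0"):
            co_profile(-1.0, 5.59, 1.09)

    def test_unphysical_negative_co_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            co_profile(300.0, 1.0, -60.0)


class TestIndividualFromPopulation:
    def test_reference_subject_is_identity_on_theta(self, pop, ref_cov):
        ind = individual_from_population(pop, ref_cov)
        assert ind.alpha_co == pytest.approx(1.09)
        assert ind.cl_p == pytest.approx(pop.cl_p)
        assert ind.ce50_f == pytest.approx(pop.ce50_f)

    def test_study2_covariate_factor(self, pop):
        cov = CovariateRecord(subject_id=1, age=64.0, study=2, weight=70.0)
        ind = individual_from_population(pop, cov)
        assert ind.alpha_co == pytest.approx(1.09 * (1 - 0.509), rel=1e-12)

    def test_eta_log2_doubles_clearance(self, pop, ref_cov):
        ind = individual_from_population(pop, ref_cov, eta={"cl_p": math.log(2)})
        assert ind.cl_p == pytest.approx(2 * 1.54)

    def test_age_effect_direction(self, pop):
        young = individual_from_population(
            pop, CovariateRecord(subject_id=1, age=50, study=1, weight=70))
        old = individual_from_population(
            pop, CovariateRecord(subject_id=2, age=80, study=1, weight=70))
        assert young.alpha_co > old.alpha_co > 0

    def test_covariate_floor_prevents_sign_flip(self, pop):
        # beta_age large enough to drive the raw factor negative at age 100
        pop2 = pop.replace(beta_age=-5.0)
        cov = CovariateRecord(subject_id=1, age=100, study=1, weight=70)
        ind = individual_from_population(pop2, cov)
        assert ind.alpha_co == pytest.approx(pop.alpha_co * 0.05)

    def test_eta_for_parameter_without_iiv_rejected(self, pop, ref_cov):
        with pytest.raises(ValueError, match="without IIV"):
            individual_from_population(pop, ref_cov, eta={"q2_p": 0.1})


class TestScaledClearances:
    def test_reference_co_returns_theta(self, pop, typical_ind):
        cls = scaled_clearances(typical_ind, 6.5)
        assert cls == pytest.approx((1.54, 1.89, 0.607, 0.569, 5.78, 1.48))

    def test_proportionality(self, typical_ind):
        assert scaled_clearances(typical_ind, 13.0)[0] == pytest.approx(3.08)
        assert scaled_clearances(typical_ind, 5.59)[0] == pytest.approx(1.324, abs=5e-4)

    def test_nonpositive_co_rejected(self, typical_ind):
        with pytest.raises(ValueError):
            scaled_clearances(typical_ind, 0.0)


class TestBisModel:
    def test_drug_free_baseline(self, pop):
        assert bis_model(0.0, 0.0, pop) == pytest.approx(88.6)

    def test_maintained_targets_give_bis_35(self, pop):
        assert bis_model(3.0, 1.5, pop) == pytest.approx(35.0, abs=1.0)

    def test_half_maximal_at_ce50(self, pop):
        assert bis_model(pop.ce50_p, 0.0, pop) == pytest.approx(44.3)

    def test_closed_form_at_fixed_exponents(self, pop):
        ce_p, ce_f = 1.7, 4.2
        u = ce_p / pop.ce50_p + ce_f / pop.ce50_f
        assert bis_model(ce_p, ce_f, pop) == pytest.approx(pop.bis0 / (1 + u))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.01, 20.0), st.floats(0.01, 50.0), st.floats(0.1, 5.0))
    def test_strictly_decreasing_in_each_drug(self, pop, cp, cf, delta):
        b0 = bis_model(cp, cf, pop)
        assert bis_model(cp + delta, cf, pop) < b0
        assert bis_model(cp, cf + delta, pop) < b0

    def test_negative_concentration_rejected(self, pop):
        with pytest.raises(ValueError):
            bis_model(-0.1, 0.0, pop)


class TestPkRhs:
    def test_zero_state_zero_input_is_equilibrium(self, typical_ind):
        dy = pk_rhs(np.zeros(8), 10.0, typical_ind)
        assert np.all(dy == 0)

    def test_mass_balance_excludes_only_elimination(self, typical_ind):
        # with a bolus on board, total drug change equals -CL*C (distribution cancels)
        y = np.array([10.0, 5.0, 2.0, 100.0, 40.0, 10.0, 1.0, 1.0])
        t = 30.0
        dy = pk_rhs(y, t, typical_ind)
        from copkpd.model import co_profile as cp_
        co = cp_(t, typical_ind.co0, typical_ind.alpha_co)
        cl_p = typical_ind.cl_p * co / 6.5
        cl_f = typical_ind.cl_f * co / 6.5
        assert dy[:3].sum() == pytest.approx(-cl_p * y[0] / typical_ind.vc_p)
        assert dy[3:6].sum() == pytest.approx(-cl_f * y[3] / typical_ind.vc_f)

    def test_effect_site_step_response_half_life(self, typical_ind):
        # dCe/dt = ke0 (C - Ce) with constant C: half-life ln2/ke0 ≈ 6.6 min
        from scipy.integrate import solve_ivp
        ke0 = typical_ind.ke0
        c_const = 3.0
        sol = solve_ivp(lambda t, y: [ke0 * (c_const - y[0])], (0, 6.6), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(c_const * (1 - math.exp(-ke0 * 6.6)), rel=1e-6)
        assert math.log(2) / ke0 == pytest.approx(6.6, abs=0.05)


class TestResidualLoglik:
    def test_zero_residual_additive(self, pop):
        ll = residual_loglik("BIS", 50.0, 50.0, pop)
        assert ll == pytest.approx(math.log(1.0 / (pop.sigma_bis * math.sqrt(2 * math.pi))))

    def test_one_sd_proportional(self, pop):
        y_pred = 2.0
        y_obs = y_pred * (1 + pop.sigma_prop_p)
        ll = residual_loglik("CP", y_obs, y_pred, pop)
        expected = -0.5 * (1 + math.log(2 * math.pi)) - math.log(pop.sigma_prop_p * y_pred)
        assert ll == pytest.approx(expected)

    def test_monte_carlo_mean_matches_gaussian_entropy(self, pop):
        # E[log density] = -1/2 - log(sd sqrt(2 pi)) for each stream
        rng = np.random.default_rng(3)
        y_pred = np.full(10_000, 55.0)
        y_obs = y_pred + rng.normal(0, pop.sigma_bis, size=y_pred.size)
        mean_ll = float(np.mean(residual_loglik("BIS", y_obs, y_pred, pop)))
        expected = -0.5 - math.log(pop.sigma_bis * math.sqrt(2 * math.pi))
        assert mean_ll == pytest.approx(expected, abs=0.03)

    def test_nonpositive_prediction_rejected_for_proportional(self, pop):
        with pytest.raises(ValueError):
            residual_loglik("CF", 1.0, 0.0, pop)

    def test_unknown_stream_rejected(self, pop):
        with pytest.raises(ValueError):
            residual_loglik("HR", 1.0, 1.0, pop)
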