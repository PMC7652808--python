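import math

import numpy as np
import pytest

from copkpd.events import DoseEvent, compile_events
from copkpd.model import individual_from_population
from copkpd.params import CovariateRecord
from copkpd.simulate import (
    PUBLISHED_DECREMENT_BIS,
    clamp_plasma_schedule,
    csdt,
    decrement_to_bis,
    matrix_exp_oracle,
    simulate_individual,
)


def _bolus(amount=100.0, t=0.0, drug="propofol"):
    return DoseEvent(t, drug, "bolus", amount=amount)


class TestEvents:
    def test_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, "propofol", "bolus")           # no amount
        with pytest.raises(ValueError):
            DoseEvent(0.0, "propofol", "infusion_start")  # no rate
        with pytest.raises(ValueError):
            DoseEvent(-10.0, "fentanyl", "bolus", amount=1.0)  # before -5 min
        with pytest.raises(ValueError):
            DoseEvent(0.0, "morphine", "bolus", amount=1.0)

    def test_bolus_under_clamp_rejected(self):
        evs = [DoseEvent(0.0, "propofol", "clamp_start", target=3.0),
               DoseEvent(5.0, "propofol", "bolus", amount=10.0)]
        with pytest.raises(ValueError, match="clamp"):
            compile_events(evs)

    def test_rate_steps_compile(self):
        evs = [DoseEvent(0.0, "propofol", "infusion_start", rate=5.0),
               DoseEvent(30.0, "propofol", "infusion_start", rate=8.0),
               DoseEvent(60.0, "propofol", "infusion_stop")]
        sched = compile_events(evs)
        assert sched.rate_at("propofol", 10.0) == 5.0
        assert sched.rate_at("propofol", 45.0) == 8.0
        assert sched.rate_at("propofol", 70.0) == 0.0


class TestSimulateIndividual:
    def test_closed_system_bolus_concentration_constant(self, pop, ref_cov):
        tiny = 1e-9
        ind = individual_from_population(pop, ref_cov)
        frozen = type(ind)(**{**ind.__dict__, "cl_p": tiny, "q1_p": tiny, "q2_p": tiny,
                              "alpha_co": tiny, "eta": {}})
        res = simulate_individual(frozen, [_bolus(100.0)], [1.0, 60.0, 240.0])
        assert np.allclose(res.cp, 100.0 / ind.vc_p, rtol=1e-6)

    def test_zero_events_gives_baseline(self, typical_ind):
        res = simulate_individual(typical_ind, [], [0.0, 50.0, 400.0])
        assert np.all(res.cp == 0) and np.all(res.cf == 0)
        assert np.allclose(res.bis, typical_ind.bis0)
        assert res.co[0] == pytest.approx(typical_ind.co0)
        assert res.co[-1] == pytest.approx(typical_ind.co0 + typical_ind.alpha_co * 5)

    def test_mass_conserved_without_elimination(self, pop, ref_cov):
        tiny = 1e-12
        ind = individual_from_population(pop, ref_cov)
        frozen = type(ind)(**{**ind.__dict__,
                              "cl_p": tiny, "q1_p": 1.89, "q2_p": 0.607,
                              "cl_f": tiny, "q1_f": 5.78, "q2_f": 1.48, "eta": {}})
        res = simulate_individual(frozen, [_bolus(100.0), _bolus(105.0, -5.0, "fentanyl")],
                                  np.linspace(1, 300, 25))
        total_p = res.states[:, :3].sum(axis=1)
        total_f = res.states[:, 3:6].sum(axis=1)
        assert np.allclose(total_p, 100.0, rtol=1e-8)
        assert np.allclose(total_f, 105.0, rtol=1e-8)

    def test_dose_linearity_and_superposition(self, typical_ind):
        obs = np.array([1.0, 5.0, 20.0, 60.0, 120.0])
        bolus = [_bolus(50.0)]
        inf = [DoseEvent(10.0, "propofol", "infusion_start", rate=4.0),
               DoseEvent(90.0, "propofol", "infusion_stop")]
        r_b = simulate_individual(typical_ind, bolus, obs)
        r_i = simulate_individual(typical_ind, inf, obs)
        r_bi = simulate_individual(typical_ind, bolus + inf, obs)
        r_2b = simulate_individual(typical_ind, [_bolus(100.0)], obs)
        assert np.allclose(r_2b.cp, 2 * r_b.cp, rtol=1e-7)         # linearity
        assert np.allclose(r_bi.cp, r_b.cp + r_i.cp, rtol=1e-6)    # superposition

    def test_deterministic(self, typical_ind):
        obs = np.linspace(0, 200, 21)
        ev = [_bolus(80.0), DoseEvent(5.0, "propofol", "infusion_start", rate=6.0)]
        a = simulate_individual(typical_ind, ev, obs)
        b = simulate_individual(typical_ind, ev, obs)
        assert np.array_equal(a.states, b.states)


class TestMatrixExpOracle:
    def test_matches_adaptive_solver_to_1e6(self, typical_ind):
        ev = [_bolus(100.0), _bolus(105.0, -5.0, "fentanyl"),
              DoseEvent(10.0, "propofol", "infusion_start", rate=8.0),
              DoseEvent(120.0, "propofol", "infusion_stop")]
        obs = np.array([1.0, 10.0, 60.0, 120.0, 180.0])
        ref = simulate_individual(typical_ind, ev, obs)
        ora = matrix_exp_oracle(typical_ind, ev, obs, step=0.05)
        rel = np.abs(ora.states - ref.states) / np.maximum(np.abs(ref.states), 1e-12)
        assert rel.max() < 1e-6

    def test_step_halving_reduces_discrepancy(self, typical_ind):
        ev = [_bolus(100.0)]
        obs = np.array([1.0, 10.0, 60.0])
        ref = simulate_individual(typical_ind, ev, obs)
        errs = []
        for step in (0.4, 0.2, 0.1):
            ora = matrix_exp_oracle(typical_ind, ev, obs, step=step)
            errs.append(np.abs(ora.states - ref.states).max())
        assert errs[0] > errs[1] > errs[2]

    def test_exact_for_constant_co(self, pop, ref_cov):
        ind = individual_from_population(pop.replace(alpha_co=1e-9), ref_cov)
        ev = [_bolus(100.0)]
        obs = np.array([1.0, 30.0, 120.0])
        ref = simulate_individual(ind, ev, obs)
        ora = matrix_exp_oracle(ind, ev, obs, step=5.0)  # any step: system is LTI
        rel = np.abs(ora.states - ref.states) / np.maximum(np.abs(ref.states), 1e-12)
        assert rel.max() < 1e-7

    def test_clamp_unsupported(self, typical_ind):
        ev = [DoseEvent(0.0, "propofol", "clamp_start", target=3.0)]
        with pytest.raises(NotImplementedError):
            matrix_exp_oracle(typical_ind, ev, [10.0])


class TestClamp:
    def test_plasma_held_at_target(self, typical_ind):
        ev = [DoseEvent(0.0, "propofol", "clamp_start", target=3.0),
              DoseEvent(0.0, "fentanyl", "clamp_start", target=1.5),
              DoseEvent(200.0, "propofol", "clamp_stop"),
              DoseEvent(200.0, "fentanyl", "clamp_stop")]
        res = simulate_individual(typical_ind, ev, np.linspace(1, 200, 40))
        assert np.allclose(res.cp, 3.0, rtol=1e-3)
        assert np.allclose(res.cf, 1.5, rtol=1e-3)
        # effect site equilibrates well before 200 min given ke0 = 0.105/min
        assert res.ce_p[-1] >= 0.99 * 3.0
        assert res.ce_f[-1] >= 0.99 * 1.5

    def test_initial_clamp_rate_matches_total_clearance(self, typical_ind):
        rate = clamp_plasma_schedule(typical_ind, (3.0, 1.5), 0.0, 120.0)
        from copkpd.model import scaled_clearances
        cl_p, q1_p, q2_p, cl_f, q1_f, q2_f = scaled_clearances(typical_ind, typical_ind.co0)
        rp, rf = rate(0.0)
        assert rp == pytest.approx(3.0 * (cl_p + q1_p + q2_p), rel=1e-6)
        assert rf == pytest.approx(1.5 * (cl_f + q1_f + q2_f), rel=1e-6)
        assert rate(150.0) == (0.0, 0.0)

    def test_recovered_rates_reproduce_clamp(self, typical_ind):
        # feed the recovered rate function back as a fine piecewise schedule
        rate = clamp_plasma_schedule(typical_ind, (3.0, 1.5), 0.0, 60.0)
        # the clamp itself fills the central compartment instantaneously, so
        # the equivalent open-loop dosing is a loading bolus plus the rates
        ev = [DoseEvent(0.0, "propofol", "bolus", amount=3.0 * typical_ind.vc_p),
              DoseEvent(0.0, "fentanyl", "bolus", amount=1.5 * typical_ind.vc_f)]
        for t in np.arange(0.0, 60.0, 0.25):
            rp, rf = rate(t + 0.125)  # midpoint sampling of the rate profile
            ev.append(DoseEvent(round(t, 4), "propofol", "infusion_start", rate=rp))
            ev.append(DoseEvent(round(t, 4), "fentanyl", "infusion_start", rate=rf))
        ev.append(DoseEvent(60.0, "propofol", "infusion_stop"))
        ev.append(DoseEvent(60.0, "fentanyl", "infusion_stop"))
        res = simulate_individual(typical_ind, ev, np.array([10.0, 30.0, 59.9]))
        assert np.allclose(res.cp, 3.0, rtol=2e-3)
        assert np.allclose(res.cf, 1.5, rtol=2e-3)


class TestCsdt:
    def test_zero_decrement_is_zero_minutes(self, pop):
        cov = CovariateRecord(subject_id=1, age=50, study=1, weight=70)
        res = csdt(pop, cov, decrements=(0.0,), definition="u")
        assert res.times[0.0] == 0.0

    def test_monotone_in_decrement_and_covariates(self, pop):
        times = {}
        for age, study in [(50, 1), (80, 1), (50, 2), (80, 2)]:
            cov = CovariateRecord(subject_id=1, age=age, study=study, weight=70)
            r = csdt(pop, cov, decrements=(0.3, 0.6, 0.8), definition="u")
            assert r.times[0.3] < r.times[0.6] < r.times[0.8]
            times[(age, study)] = r.times
        for d in (0.3, 0.6, 0.8):
            assert times[(80, 1)][d] >= times[(50, 1)][d]   # older: slower CO rise
            assert times[(50, 2)][d] >= times[(50, 1)][d]   # Study 2: slower CO rise

    def test_unreachable_decrement_censored(self, pop):
        cov = CovariateRecord(subject_id=1, age=50, study=1, weight=70)
        res = csdt(pop, cov, decrements=(0.99,), definition="u", horizon=30.0)
        assert math.isnan(res.times[0.99])
        assert 0.99 in res.censored

    def test_u_at_maintenance_matches_targets(self, pop):
        cov = CovariateRecord(subject_id=1, age=64, study=1, weight=70)
        res = csdt(pop, cov, decrements=(0.5,), definition="u")
        u_expected = 3.0 / pop.ce50_p + 1.5 / pop.ce50_f
        assert res.u_maintain == pytest.approx(u_expected, rel=1e-3)


class TestDecrementToBis:
    def test_limits_and_published_table(self, pop):
        assert decrement_to_bis(0.0, pop=pop) == pytest.approx(35.4, abs=0.1)
        assert decrement_to_bis(1.0, pop=pop) == pytest.approx(pop.bis0)
        assert decrement_to_bis(0.70, pop=pop) == pytest.approx(61.0, abs=0.1)
        # the printed mapping sits one 10% step off the additive Emax curve
        for d, bis in PUBLISHED_DECREMENT_BIS.items():
            assert decrement_to_bis(min(d + 0.1, 1.0), pop=pop) == pytest.approx(bis, abs=0.6)
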