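import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from copkpd.estimation import (
    FitSpec,
    FoceProblem,
    bootstrap,
    fit_population,
    foce_objective,
    individual_map,
    lrt,
)
from copkpd.events import DoseEvent
from copkpd.io import TrialDataset
from copkpd.model import individual_from_population
from copkpd.params import CovariateRecord
from copkpd.simulate import simulate_individual


def _toy_dataset(y_values, times=None):
    """One subject with only baseline-ish CO observations (no doses needed)."""
    times = times if times is not None else [0.0] * len(y_values)
    rows = [dict(ID=1, TIME=t, EVID=0, CMT=0, DVID=4, AMT=np.nan, RATE=np.nan,
                 DV=y, MDV=0, BLQ=0, AGE=64.0, STUDY=1, WT=70.0)
            for t, y in sorted(zip(times, y_values))]
    return TrialDataset(pd.DataFrame(rows))


class TestFoceObjective:
    def test_matches_quadrature_marginal_on_scalar_model(self, pop):
        # One CO observation at t=0: y = co0*exp(eta) + eps.  The Laplace
        # approximation is compared against the exact marginal computed by
        # numerical integration.
        toy = pop.replace(omega2={"co0": 0.04})
        s2 = toy.sigma_co**2
        w2 = 0.04
        for y, tol in ((5.7, 0.01), (6.4, 0.06)):
            # the tolerance grows with the residual: the Gauss-Newton curvature
            # drops the (y - f) f'' term of the exact Laplace Hessian
            ds = _toy_dataset([y])
            ofv = foce_objective(toy, ds, FitSpec(initial=toy))

            def integrand(eta):
                f = toy.co0 * math.exp(eta)
                return (math.exp(-0.5 * (y - f) ** 2 / s2) / math.sqrt(2 * math.pi * s2)
                        * math.exp(-0.5 * eta**2 / w2) / math.sqrt(2 * math.pi * w2))

            exact = -2 * math.log(quad(integrand, -2.0, 2.0, limit=200)[0])
            assert ofv == pytest.approx(exact, abs=tol)

    def test_duplicating_subject_doubles_ofv(self, pop, trial_small):
        spec = FitSpec(initial=pop)
        single = trial_small.resample_subjects([1])
        double = trial_small.resample_subjects([1, 1])
        o1 = foce_objective(pop, single, spec)
        o2 = foce_objective(pop, double, spec)
        assert o2 == pytest.approx(2 * o1, abs=1e-6)

    def test_invariant_to_relabeling_and_row_order(self, pop, trial_small):
        spec = FitSpec(initial=pop)
        base = foce_objective(pop, trial_small, spec)
        ids = trial_small.subject_ids
        permuted = trial_small.resample_subjects(ids[::-1])
        assert foce_objective(pop, permuted, spec) == pytest.approx(base, abs=1e-9)
        df = trial_small.df.sort_values(["ID", "TIME", "EVID", "DVID"],
                                        ascending=[True, True, False, False],
                                        kind="stable").reset_index(drop=True)
        reordered = TrialDataset(df)
        assert foce_objective(pop, reordered, spec) == pytest.approx(base, abs=1e-9)

    def test_observed_co_mode_changes_ofv(self, pop, trial_small):
        o_model = foce_objective(pop, trial_small, FitSpec(initial=pop))
        o_obs = foce_objective(pop, trial_small,
                               FitSpec(initial=pop, co_effect="observed"))
        o_none = foce_objective(pop, trial_small,
                                FitSpec(initial=pop, co_effect="none"))
        assert abs(o_model - o_obs) > 1e-3
        assert abs(o_model - o_none) > 1e-3


class TestIndividualMap:
    def _known_eta_subject(self, pop):
        eta = {"cl_p": 0.3, "vc_f": -0.2, "co0": 0.1, "ce50_p": 0.2, "alpha_co": -0.3}
        pop5 = pop.replace(omega2={k: pop.omega2[k] for k in eta})
        cov = CovariateRecord(subject_id=1, age=60.0, study=1, weight=70.0)
        ind = individual_from_population(pop5, cov, eta=eta)
        ev = [DoseEvent(-5.0, "fentanyl", "bolus", amount=105.0),
              DoseEvent(0.0, "propofol", "infusion_start", rate=4.0),
              DoseEvent(120.0, "propofol", "infusion_stop")]
        t_pk = np.array([1., 5., 15., 30., 60., 90., 120., 125., 135., 150., 180.])
        t_grid = np.arange(0.0, 180.1, 10.0)
        rows = []
        sim = simulate_individual(ind, ev, t_pk)
        for t, cp, cf in zip(t_pk, sim.cp, sim.cf):
            rows.append(dict(TIME=t, DVID=1, DV=cp))
            rows.append(dict(TIME=t, DVID=2, DV=cf))
        simg = simulate_individual(ind, ev, t_grid)
        for t, bis, co in zip(t_grid, simg.bis, simg.co):
            rows.append(dict(TIME=t, DVID=3, DV=bis))
            rows.append(dict(TIME=t, DVID=4, DV=co))
        recs = [dict(ID=1, TIME=-5.0, EVID=1, CMT=2, DVID=0, AMT=105.0, RATE=np.nan,
                     DV=np.nan, MDV=1, BLQ=0, AGE=60.0, STUDY=1, WT=70.0),
                dict(ID=1, TIME=0.0, EVID=1, CMT=1, DVID=0, AMT=480.0, RATE=4.0,
                     DV=np.nan, MDV=1, BLQ=0, AGE=60.0, STUDY=1, WT=70.0)]
        for r in sorted(rows, key=lambda r: r["TIME"]):
            recs.append(dict(ID=1, TIME=r["TIME"], EVID=0, CMT=0, DVID=r["DVID"],
                             AMT=np.nan, RATE=np.nan, DV=r["DV"], MDV=0, BLQ=0,
                             AGE=60.0, STUDY=1, WT=70.0))
        return pop5, eta, TrialDataset(pd.DataFrame(recs))

    def test_eta_recovered_at_vanishing_noise(self, pop):
        pop5, eta_true, ds = self._known_eta_subject(pop)
        quiet = pop5.replace(sigma_prop_p=3.86e-4, sigma_prop_f=3.1e-4,
                             sigma_bis=8.42e-3, sigma_co=1.41e-3)
        spec = FitSpec(initial=quiet, max_step=0.25, inner_gtol=1e-4,
                       inner_maxiter=200)
        eta_hat, H = individual_map(quiet, ds.subject(1), spec)
        for name, true in eta_true.items():
            assert eta_hat[name] == pytest.approx(true, abs=5e-3)
        assert np.all(np.linalg.eigvalsh(H) > 0)

    def test_degenerate_prior_pins_eta_to_zero(self, pop):
        pop5, _, ds = self._known_eta_subject(pop)
        tight = pop5.replace(omega2={k: 1e-10 for k in pop5.omega2})
        eta_hat, _ = individual_map(tight, ds.subject(1), FitSpec(initial=tight))
        assert max(abs(v) for v in eta_hat.values()) < 1e-3

    def test_uninformative_subject_returns_prior_mode(self, pop):
        pop5, _, ds = self._known_eta_subject(pop)
        df = ds.df.copy()
        df.loc[df.EVID == 0, "MDV"] = 1
        eta_hat, _ = individual_map(pop5, TrialDataset(df).subject(1),
                                    FitSpec(initial=pop5))
        assert all(v == 0.0 for v in eta_hat.values())


class TestFitPopulation:
    def test_evaluation_mode_returns_initials(self, pop, trial_small):
        res = fit_population(trial_small, FitSpec(initial=pop, estimate=()))
        assert res.estimates == pop
        assert math.isfinite(res.ofv)
        assert res.convergence["success"]
        assert set(res.ebe) == set(trial_small.subject_ids)
        assert set(res.eta_shrinkage) == set(pop.eta_names)

    def test_one_parameter_fit_recovers_and_is_stationary(self, pop, trial_small):
        start = pop.replace(cl_p=pop.cl_p * 1.4)
        spec = FitSpec(initial=start, estimate=("cl_p",), maxiter=30)
        res = fit_population(trial_small, spec)
        assert res.estimates.cl_p == pytest.approx(pop.cl_p, rel=0.35)
        spec2 = FitSpec(initial=res.estimates, estimate=("cl_p",), maxiter=30)
        res2 = fit_population(trial_small, spec2)
        assert abs(res2.ofv - res.ofv) < 0.01

    def test_standard_errors_on_toy_model(self, pop):
        # n i.i.d. CO observations, scalar fit of co0 with no IIV:
        # SE(log co0-ish) ~ sigma/(co0 sqrt(n)) by the delta method
        bare = pop.replace(omega2={})
        rng = np.random.default_rng(5)
        n = 80
        y = pop.co0 + rng.normal(0, pop.sigma_co, n)
        ds = _toy_dataset(y.tolist())
        spec = FitSpec(initial=bare, estimate=("co0",), compute_se=True)
        res = fit_population(ds, spec)
        assert res.estimates.co0 == pytest.approx(y.mean(), rel=1e-3)
        assert res.se["co0"] == pytest.approx(pop.sigma_co / math.sqrt(n), rel=0.05)
        assert res.rse_percent["co0"] == pytest.approx(
            100 * res.se["co0"] / res.estimates.co0)


class TestLrt:
    def test_published_significance_rule(self):
        assert lrt(3.84, 0.0, df=1) == pytest.approx(0.05, abs=2e-3)

    def test_zero_delta(self):
        assert lrt(10.0, 10.0, df=1) == 1.0

    def test_chi2_quantile(self):
        assert lrt(10.83, 0.0, df=1) == pytest.approx(0.001, abs=5e-5)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert lrt(5.0, 6.0, df=1) == 1.0


class TestBootstrap:
    def test_same_seed_reproduces(self, pop, trial_small):
        spec = FitSpec(initial=pop, estimate=("cl_p",), maxiter=5)
        a = bootstrap(trial_small, spec, n_resamples=2, seed=11)
        b = bootstrap(trial_small, spec, n_resamples=2, seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert a.n_failed == b.n_failed == 0

    def test_replicated_subject_gives_degenerate_ci(self, pop, trial_small):
        clones = trial_small.resample_subjects([1, 1, 1, 1])
        spec = FitSpec(initial=pop, estimate=("cl_p",), maxiter=5)
        res = bootstrap(clones, spec, n_resamples=3, seed=2)
        width = res.summary.loc["cl_p", "ci95"] - res.summary.loc["cl_p", "ci5"]
        assert width == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_subjects(self, pop, trial_small):
        single = trial_small.resample_subjects([1])
        with pytest.raises(ValueError):
            bootstrap(single, FitSpec(initial=pop), n_resamples=2, seed=0)
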