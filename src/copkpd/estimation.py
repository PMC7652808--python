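"""Population estimation: FOCE-type marginal likelihood, LRT, bootstrap.

The marginal likelihood of each subject's data is approximated by a Laplace
expansion about the conditional mode of the random effects (empirical-Bayes
estimate), with the curvature taken as the Gauss-Newton form J' W J + Ω⁻¹
evaluated at the conditional predictions — residual variances therefore
track the conditional (not population) predictions, the usual
"with interaction" behaviour for proportional error.  The objective is the
full -2 log-likelihood including 2π constants, so differences between nested
models are χ²-referenced directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from . import _engine
from .model import covariate_factor_alpha_co
from .params import PopulationParameters, STRUCTURAL_FIELDS
from .io import TrialDataset

__all__ = ["FitSpec", "FitResult", "FoceProblem", "foce_objective", "individual_map",
           "fit_population", "lrt", "bootstrap", "BootstrapResult"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class FitSpec:
    """What to estimate and how.

    ``estimate`` names population parameters: structural fixed effects
    (e.g. ``"cl_p"``), covariate coefficients (``"beta_age"``,
    ``"beta_study"``), IIV variances (``"omega2:cl_p"``) and residual scales
    (``"sigma_prop_p"`` etc.).  Positive parameters are optimized on the log
    scale, covariate coefficients on a percent/100 scale.
    """

    initial: PopulationParameters
    estimate: tuple = ()
    co_effect: str = "model"          # "model" | "observed" | "none"
    age_on_alpha: bool = True
    study_on_alpha: bool = True
    covariate_form: str = "proportional"
    drop_blq: bool = True
    max_step: float = 1.0             # engine grid refinement, min
    inner_gtol: float = 0.02
    inner_maxiter: int = 60
    multistart: bool = True
    maxiter: int = 60
    ftol: float = 1e-9
    eps: float = 1e-5                 # outer finite-difference step
    compute_se: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.co_effect not in ("model", "observed", "none"):
            raise ValueError("co_effect must be 'model', 'observed' or 'none'")
        known = set(STRUCTURAL_FIELDS) | {"beta_age", "beta_study",
                                          "sigma_prop_p", "sigma_prop_f",
                                          "sigma_bis", "sigma_co"}
        for name in self.estimate:
            base = name.split(":", 1)[1] if name.startswith("omega2:") else name
            if base not in known:
                raise ValueError(f"unknown parameter to estimate: {name}")


@dataclass
class FitResult:
    estimates: PopulationParameters
    ofv: float
    se: dict | None
    rse_percent: dict | None
    ebe: dict                      # subject id -> {eta name: value}
    eta_shrinkage: dict            # eta name -> percent
    convergence: dict
    n_obs: int
    spec: FitSpec = field(repr=False, default=None)


class _Workspace:
    """Per-subject compiled schedule and observation arrays."""

    def __init__(self, sub, spec: FitSpec):
        obs = sub.observations
        keep = obs["MDV"] == 0
        if spec.drop_blq:
            keep &= obs["BLQ"] == 0
        obs = obs[keep]
        self.cov = sub.covariates
        self.y = obs["DV"].to_numpy(dtype=float)
        self.dvid = obs["DVID"].to_numpy(dtype=np.int64)
        self.t = obs["TIME"].to_numpy(dtype=float)
        order = np.argsort(self.t, kind="stable")
        self.y, self.dvid, self.t = self.y[order], self.dvid[order], self.t[order]
        self.sched = _engine.build_schedule(sub.boluses, sub.infusions, self.t,
                                            max_step=spec.max_step)
        self.obs_idx = self.sched.obs_idx.astype(np.int64)
        self.masks = {d: self.dvid == d for d in (1, 2, 3, 4)}
        co_obs = obs[obs["DVID"] == 4].sort_values("TIME")
        self.locf_t = co_obs["TIME"].to_numpy(dtype=float)
        self.locf_v = co_obs["DV"].to_numpy(dtype=float)


class _Context:
    """Decoded population parameters for one objective evaluation."""

    def __init__(self, pop: PopulationParameters, spec: FitSpec, eta_names):
        self.pop = pop
        self.spec = spec
        self.eta_names = eta_names
        self.omega2 = np.array([pop.omega2[n] for n in eta_names])
        self.log_det_omega = float(np.sum(np.log(self.omega2))) if len(eta_names) else 0.0
        self.sigma = (pop.sigma_prop_p, pop.sigma_prop_f, pop.sigma_bis, pop.sigma_co)
        base = np.array([getattr(pop, p) for p in STRUCTURAL_FIELDS] + [pop.co_plateau_time])
        self.theta_vec = base
        self.eta_pos = np.array([STRUCTURAL_FIELDS.index(n) for n in eta_names], dtype=int)
        self._alpha_idx = STRUCTURAL_FIELDS.index("alpha_co")
        pop_eff = pop
        if not spec.age_on_alpha:
            pop_eff = replace(pop_eff, beta_age=0.0)
        if not spec.study_on_alpha:
            pop_eff = replace(pop_eff, beta_study=0.0)
        self._pop_eff = pop_eff

    def cov_factor(self, ws: _Workspace) -> float:
        return covariate_factor_alpha_co(self._pop_eff, ws.cov,
                                         form=self.spec.covariate_form)

    def _param_vec(self, ws: _Workspace, eta: np.ndarray) -> np.ndarray:
        pv = self.theta_vec.copy()
        if eta.size:
            pv[self.eta_pos] *= np.exp(eta)
        pv[self._alpha_idx] *= self.cov_factor(ws)
        return pv

    def _tau_arrays(self, ws: _Workspace, pv: np.ndarray):
        mode = self.spec.co_effect
        s = ws.sched
        if mode == "model":
            apm = pv[self._alpha_idx] / 60.0
            args = (pv[19], apm, pv[21], self.pop.co_ref)
            return (_engine.tau_linear_plateau(s.nodes, *args),
                    _engine.tau_linear_plateau(s.g1, *args),
                    _engine.tau_linear_plateau(s.g2, *args))
        if mode == "none":
            return s.nodes, s.g1, s.g2
        args = (ws.locf_t, ws.locf_v, self.pop.co_ref, pv[19])
        return (_engine.tau_locf(s.nodes, *args),
                _engine.tau_locf(s.g1, *args),
                _engine.tau_locf(s.g2, *args))

    def predict(self, ws: _Workspace, eta: np.ndarray) -> np.ndarray:
        pv = self._param_vec(ws, eta)
        tn, tg1, tg2 = self._tau_arrays(ws, pv)
        s = ws.sched
        return _engine._predict_obs(s.nodes, s.rate_p, s.rate_f, s.bolus_p, s.bolus_f,
                                    tn, tg1, tg2, ws.obs_idx, ws.dvid, pv)

    def neg2ll_residual(self, ws: _Workspace, f: np.ndarray) -> float:
        """-2 log residual density; +inf if a proportional prediction is <= 0."""
        return float(_engine._neg2ll(ws.y, ws.dvid, f, *self.sigma))

    def inner_objective(self, ws: _Workspace, eta: np.ndarray) -> float:
        """g(eta) = -log p(y|eta) - log p(eta) up to the |2πΩ| constant."""
        r = self.neg2ll_residual(ws, self.predict(ws, eta))
        if not np.isfinite(r):
            return 1e12
        prior = float(np.sum(eta * eta / self.omega2)) if eta.size else 0.0
        return 0.5 * (r + prior)


def _jacobian(ctx: _Context, ws: _Workspace, eta: np.ndarray, f0: np.ndarray,
              step: float = 1e-4) -> np.ndarray:
    J = np.empty((f0.size, eta.size))
    for i in range(eta.size):
        e = eta.copy()
        e[i] += step
        J[:, i] = (ctx.predict(ws, e) - f0) / step
    return J


def _grad_pieces(ctx: _Context, ws: _Workspace, f: np.ndarray):
    """(dg/df, weights 1/sd^2) of the residual part at predictions f."""
    u = np.empty_like(f)
    w = np.empty_like(f)
    for d in (1, 2, 3, 4):
        m = ws.masks[d]
        if not m.any():
            continue
        fd = f[m]
        yd = ws.y[m]
        if d in (1, 2):
            sd = ctx.sigma[d - 1] * fd
            z = (yd - fd) / sd
            u[m] = -z * yd / (ctx.sigma[d - 1] * fd * fd) + 1.0 / fd
        else:
            sd = ctx.sigma[d - 1]
            z = (yd - fd) / sd
            u[m] = -z / sd
        w[m] = 1.0 / (sd * sd)
    return u, w


def _fit_eta(ctx: _Context, ws: _Workspace, multistart: bool):
    """Damped Gauss-Newton search for the conditional mode.

    Deterministic (cold start from the fixed grid every call), so the outer
    objective is a pure function of the population parameters.  Returns
    (eta_hat, g(eta_hat), H) with H the Gauss-Newton curvature
    J' W J + Ω⁻¹ at the mode (the Laplace/FOCE curvature).
    """
    q = len(ctx.eta_names)
    if q == 0:
        return np.zeros(0), ctx.inner_objective(ws, np.zeros(0)), np.zeros((0, 0))
    s = ws.sched
    co_mode = {"model": 0, "none": 1, "observed": 2}[ctx.spec.co_effect]
    try:
        eta, g, H = _engine._inner_lm(
            s.nodes, s.rate_p, s.rate_f, s.bolus_p, s.bolus_f, s.g1, s.g2,
            ws.obs_idx, ws.dvid, ws.y, ctx.theta_vec, ctx.cov_factor(ws),
            ctx.eta_pos, ctx.omega2, *ctx.sigma, co_mode, ws.locf_t, ws.locf_v,
            ctx.pop.co_ref, multistart, ctx.spec.inner_gtol,
            ctx.spec.inner_maxiter, 1e-4,
        )
    except np.linalg.LinAlgError:
        # numerically degenerate corner of parameter space (e.g. an extreme
        # outer line-search probe): report a huge objective so the optimizer
        # backs off rather than aborting the whole fit
        return np.zeros(q), 5e11, np.eye(q)
    if not np.isfinite(g) or g >= 1e12:
        return np.zeros(q), 5e11, np.eye(q)
    return eta, g, H


def _logdet_pd(H: np.ndarray) -> float:
    if not np.all(np.isfinite(H)):
        return 0.0
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        # fall back to the diagonal if GN curvature is numerically indefinite
        return float(np.sum(np.log(np.abs(np.diag(H)))))
    return float(logdet)


def _subject_ofv(ctx: _Context, ws: _Workspace, multistart: bool):
    eta_hat, g, H = _fit_eta(ctx, ws, multistart)
    if not len(ctx.eta_names):
        return 2.0 * g, eta_hat
    return 2.0 * g + ctx.log_det_omega + _logdet_pd(H), eta_hat


def _subject_ofv_frozen(ctx: _Context, ws: _Workspace, eta: np.ndarray) -> float:
    """OFV contribution with the conditional mode held fixed.

    Used for cheap finite-difference gradients of the outer objective: by the
    envelope property the mode's own displacement contributes only at second
    order, so freezing it barely changes the directional derivatives while
    avoiding a full inner re-optimization per probe.
    """
    try:
        f0 = ctx.predict(ws, eta)
        r = ctx.neg2ll_residual(ws, f0)
        if not np.isfinite(r):
            return 1e12
        if not len(ctx.eta_names):
            return r
        prior = float(np.sum(eta * eta / ctx.omega2))
        J = _jacobian(ctx, ws, eta, f0)
        _, w = _grad_pieces(ctx, ws, f0)
        H = (J * w[:, None]).T @ J + np.diag(1.0 / ctx.omega2)
        return r + prior + ctx.log_det_omega + _logdet_pd(H)
    except np.linalg.LinAlgError:
        return 1e12


class FoceProblem:
    """Estimation problem: dataset compiled once, evaluated many times."""

    def __init__(self, dataset: TrialDataset, spec: FitSpec):
        self.spec = spec
        self.eta_names = spec.initial.eta_names
        self.workspaces = [_Workspace(sub, spec) for sub in dataset.subjects()]
        if not all(len(ws.y) for ws in self.workspaces):
            warnings.warn("subject with no usable observations: eta pinned to prior mode")

    # -- parameter vector <-> population parameters -------------------------
    def _encode(self, pop: PopulationParameters) -> np.ndarray:
        x = []
        for name in self.spec.estimate:
            if name.startswith("omega2:"):
                x.append(math.log(pop.omega2[name.split(":", 1)[1]]))
            elif name in ("beta_age", "beta_study"):
                x.append(getattr(pop, name) / 100.0)
            else:
                x.append(math.log(getattr(pop, name)))
        return np.array(x)

    def _decode(self, x: np.ndarray) -> PopulationParameters:
        pop = self.spec.initial
        changes = {}
        omega2 = dict(pop.omega2)
        for name, xi in zip(self.spec.estimate, x):
            if name.startswith("omega2:"):
                omega2[name.split(":", 1)[1]] = math.exp(xi)
            elif name in ("beta_age", "beta_study"):
                changes[name] = 100.0 * xi
            else:
                changes[name] = math.exp(xi)
        return pop.replace(omega2=omega2, **changes)

    def _bounds(self, x0: np.ndarray):
        """Generous box bounds on the transformed scale (keeps the line
        search inside the parameter space's validity region)."""
        bounds = []
        for name, x in zip(self.spec.estimate, x0):
            if name == "bis0":
                bounds.append((math.log(1.0), math.log(100.0)))
            elif name == "beta_age":
                bounds.append((-0.5, 0.5))       # percent/100 per year
            elif name == "beta_study":
                bounds.append((-0.99, 2.0))      # percent/100
            else:
                bounds.append((x - 3.0, x + 3.0))  # log scale: ~20x each way
        return bounds

    def objective(self, pop: PopulationParameters) -> float:
        return self._objective_with_modes(pop)[0]

    def _objective_with_modes(self, pop: PopulationParameters):
        ctx = _Context(pop, self.spec, self.eta_names)
        total = 0.0
        etas = []
        for ws in self.workspaces:
            ofv_i, eta_i = _subject_ofv(ctx, ws, self.spec.multistart)
            total += ofv_i
            etas.append(eta_i)
        return total, etas

    def objective_x(self, x: np.ndarray) -> float:
        return self.objective(self._decode(x))

    def _value_and_grad(self, x: np.ndarray):
        """Objective plus finite-difference gradient at frozen modes."""
        total, etas = self._objective_with_modes(self._decode(x))
        h = self.spec.eps
        grad = np.empty_like(x)
        for i in range(x.size):
            xp = x.copy()
            xp[i] += h
            ctx = _Context(self._decode(xp), self.spec, self.eta_names)
            fp = sum(_subject_ofv_frozen(ctx, ws, eta)
                     for ws, eta in zip(self.workspaces, etas))
            grad[i] = (fp - total) / h
        return total, grad

    def fit(self) -> FitResult:
        spec = self.spec
        if spec.estimate:
            x0 = self._encode(spec.initial)
            res = minimize(self._value_and_grad, x0, jac=True, method="L-BFGS-B",
                           bounds=self._bounds(x0),
                           options=dict(maxiter=spec.maxiter, ftol=spec.ftol,
                                        gtol=1e-3))
            x_hat, ofv = res.x, float(res.fun)
            convergence = dict(success=bool(res.success), nit=int(res.nit),
                               nfev=int(res.nfev), message=str(res.message))
        else:  # evaluation-only mode
            x_hat = np.zeros(0)
            ofv = self.objective(spec.initial)
            convergence = dict(success=True, nit=0, nfev=1, message="evaluation only")
        pop_hat = self._decode(x_hat)
        se = rse = None
        if spec.compute_se and spec.estimate:
            se, rse = self._standard_errors(x_hat, pop_hat)
        ebe, shrink = self._empirical_bayes(pop_hat)
        return FitResult(estimates=pop_hat, ofv=ofv, se=se, rse_percent=rse,
                         ebe=ebe, eta_shrinkage=shrink, convergence=convergence,
                         n_obs=int(sum(len(ws.y) for ws in self.workspaces)), spec=spec)

    def _standard_errors(self, x: np.ndarray, pop_hat: PopulationParameters):
        """Inverse-Hessian (central differences) SEs, delta-method to natural scale."""
        m = x.size
        h = 5e-4
        H = np.empty((m, m))
        f0 = self.objective_x(x)
        fp = np.empty(m)
        fm = np.empty(m)
        for i in range(m):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fp[i] = self.objective_x(xp)
            fm[i] = self.objective_x(xm)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for i in range(m):
            for j in range(i + 1, m):
                xpp = x.copy(); xpp[[i, j]] += h
                xmm = x.copy(); xmm[[i, j]] -= h
                H[i, j] = H[j, i] = (self.objective_x(xpp) - fp[i] - fp[j] + 2 * f0
                                     - fm[i] - fm[j] + self.objective_x(xmm)) / (2 * h**2)
        cov = 2.0 * np.linalg.pinv(H)  # OFV = -2 log L
        se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se, rse = {}, {}
        for name, s in zip(self.spec.estimate, se_x):
            if name.startswith("omega2:"):
                val = pop_hat.omega2[name.split(":", 1)[1]]
                se[name] = s * val
            elif name in ("beta_age", "beta_study"):
                val = getattr(pop_hat, name)
                se[name] = s * 100.0
            else:
                val = getattr(pop_hat, name)
                se[name] = s * val
            rse[name] = 100.0 * se[name] / abs(val) if val else math.inf
        return se, rse

    def _empirical_bayes(self, pop_hat: PopulationParameters):
        ctx = _Context(pop_hat, self.spec, self.eta_names)
        ebe = {}
        for ws in self.workspaces:
            eta_hat, _, _ = _fit_eta(ctx, ws, multistart=False)
            ebe[ws.cov.subject_id] = dict(zip(self.eta_names, eta_hat))
        shrink = {}
        if len(ebe) >= 2:
            for k, name in enumerate(self.eta_names):
                sd = np.std([e[name] for e in ebe.values()], ddof=1)
                shrink[name] = 100.0 * (1.0 - sd / math.sqrt(pop_hat.omega2[name]))
        return ebe, shrink


def foce_objective(pop: PopulationParameters, dataset: TrialDataset,
                   spec: FitSpec | None = None) -> float:
    """-2 log approximate marginal likelihood of the dataset under ``pop``."""
    spec = spec or FitSpec(initial=pop)
    spec = replace(spec, initial=pop)
    return FoceProblem(dataset, spec).objective(pop)


def individual_map(pop: PopulationParameters, subject, spec: FitSpec | None = None):
    """Conditional mode and curvature of one subject's random effects.

    ``subject`` is a :class:`copkpd.io.SubjectData`.  Returns
    ``(eta_hat, hessian)`` with eta ordered as ``pop.eta_names``.
    """
    spec = spec or FitSpec(initial=pop)
    spec = replace(spec, initial=pop)
    ws = _Workspace(subject, spec)
    if not len(ws.y):
        q = len(pop.eta_names)
        return dict(zip(pop.eta_names, np.zeros(q))), np.diag(
            1.0 / np.array([pop.omega2[n] for n in pop.eta_names])) if q else np.zeros((0, 0))
    ctx = _Context(pop, spec, pop.eta_names)
    eta_hat, _, H = _fit_eta(ctx, ws, multistart=spec.multistart)
    return dict(zip(pop.eta_names, eta_hat)), H


def fit_population(dataset: TrialDataset, spec: FitSpec) -> FitResult:
    """Minimize the FOCE objective over the parameters named in ``spec``."""
    return FoceProblem(dataset, spec).fit()


def lrt(ofv_reduced: float, ofv_full: float, df: int = 1) -> float:
    """Likelihood-ratio p-value for nested models (χ² with ``df`` d.o.f.)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < 0:
        warnings.warn("negative ΔOFV: full model fit worse than reduced; p = 1")
        return 1.0
    return float(chi2.sf(delta, df))


@dataclass
class BootstrapResult:
    samples: pd.DataFrame          # one row per successful resample
    summary: pd.DataFrame          # median, ci5, ci95 per parameter
    n_failed: int
    seed: int


def _natural_values(pop: PopulationParameters, names) -> dict:
    out = {}
    for name in names:
        if name.startswith("omega2:"):
            out[name] = pop.omega2[name.split(":", 1)[1]]
        else:
            out[name] = getattr(pop, name)
    return out


def bootstrap(dataset: TrialDataset, spec: FitSpec, n_resamples: int = 300,
              seed: int = 0) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of the population fit.

    Subjects are resampled with replacement (same n); each resample is
    refitted and the empirical parameter distribution summarized as the
    median with the 5th-95th percentile interval.  Failed fits are excluded
    and counted; more than 50% failures is an error.
    """
    ids = dataset.subject_ids
    if len(ids) < 2:
        raise ValueError("bootstrap needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for b in range(n_resamples):
        pick = [ids[i] for i in rng.integers(0, len(ids), size=len(ids))]
        try:
            res = fit_population(dataset.resample_subjects(pick), spec)
            if not np.isfinite(res.ofv):
                raise RuntimeError("non-finite OFV")
            rows.append(_natural_values(res.estimates, spec.estimate))
        except Exception:
            n_failed += 1
    if n_failed > 0.5 * n_resamples:
        raise RuntimeError(f"bootstrap failed for {n_failed}/{n_resamples} resamples")
    samples = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "median": samples.median(),
        "ci5": samples.quantile(0.05),
        "ci95": samples.quantile(0.95),
    })
    return BootstrapResult(samples=samples, summary=summary, n_failed=n_failed, seed=seed)
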