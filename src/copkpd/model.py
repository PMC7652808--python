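"""Structural and stochastic model components.

State vector convention used throughout the package (8 states)::

    y = [a_c_p, a_t1_p, a_t2_p,   # propofol amounts, mg
         a_c_f, a_t1_f, a_t2_f,   # fentanyl amounts, µg
         ce_p, ce_f]              # effect-site concentrations, mg/L / ng/mL

Central concentrations are amount/volume; effect compartments are
concentration states driven by first-order equilibration with the central
concentration (they carry no mass).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .params import CovariateRecord, IndividualParameters, PopulationParameters, STRUCTURAL_FIELDS

__all__ = [
    "co_profile",
    "covariate_factor_alpha_co",
    "individual_from_population",
    "scaled_clearances",
    "pk_rhs",
    "bis_model",
    "residual_loglik",
    "OBS_TYPES",
]

#: Observation streams: propofol conc, fentanyl conc, BIS, cardiac output.
OBS_TYPES = ("CP", "CF", "BIS", "CO")

_LOG_2PI = math.log(2.0 * math.pi)


def co_profile(t, co0_i: float, alpha_co_i: float, plateau_time: float = 300.0):
    """Cardiac output (L/min) at time ``t`` minutes since induction.

    CO rises linearly at ``alpha_co_i`` (L/min per *hour*) from its baseline
    ``co0_i`` until ``plateau_time`` and is constant afterwards.  Scalar or
    array ``t``; negative times are rejected (the surgery clock starts at
    induction).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("co_profile is defined for t >= 0 (minutes since induction)")
    co = co0_i + alpha_co_i * np.minimum(t, plateau_time) / 60.0
    if np.any(co <= 0):
        raise ValueError(
            "co_profile produced CO <= 0; unphysical (co0, alpha_co) parameterization"
        )
    return co if co.ndim else float(co)


def covariate_factor_alpha_co(
    pop: PopulationParameters,
    cov: CovariateRecord,
    form: str = "proportional",
    floor: float = 0.05,
) -> float:
    """Multiplicative covariate factor on the CO slope ``alpha_co``.

    ``proportional`` (default): ``(1 + beta_age/100*(age - age_ref)) *
    (1 + beta_study/100 * 1{study == 2})``, floored at ``floor`` to prevent
    sign flips for extreme extrapolated ages.  ``exponential`` uses
    ``exp(beta/100 * ...)`` factors instead.
    """
    d_age = cov.age - pop.age_ref
    is2 = 1.0 if cov.study == 2 else 0.0
    if form == "proportional":
        factor = (1.0 + pop.beta_age / 100.0 * d_age) * (1.0 + pop.beta_study / 100.0 * is2)
    elif form == "exponential":
        factor = math.exp(pop.beta_age / 100.0 * d_age) * math.exp(pop.beta_study / 100.0 * is2)
    else:
        raise ValueError(f"unknown covariate form {form!r}")
    factor = max(factor, floor)
    if factor <= 0:
        raise ValueError(
            f"covariate factor on alpha_co is non-positive for age={cov.age}, "
            f"study={cov.study} (floor={floor})"
        )
    return factor


def individual_from_population(
    pop: PopulationParameters,
    cov: CovariateRecord,
    eta: Mapping[str, float] | None = None,
    covariate_form: str = "proportional",
    covariate_floor: float = 0.05,
) -> IndividualParameters:
    """Realize subject-level parameters: ``P_i = theta_P * exp(eta_P)``.

    ``alpha_co`` additionally receives the age/study covariate factor
    (applied multiplicatively, hence commuting with ``exp(eta)``).  Missing
    eta keys are treated as 0; keys must be a subset of the parameters that
    carry IIV.
    """
    eta = dict(eta or {})
    extra = set(eta) - set(pop.omega2)
    if extra:
        raise ValueError(f"eta supplied for parameters without IIV: {sorted(extra)}")
    values = {}
    for name in STRUCTURAL_FIELDS:
        theta = getattr(pop, name)
        values[name] = theta * math.exp(eta.get(name, 0.0))
    values["alpha_co"] *= covariate_factor_alpha_co(
        pop, cov, form=covariate_form, floor=covariate_floor
    )
    return IndividualParameters(
        co_ref=pop.co_ref, co_plateau_time=pop.co_plateau_time, eta=eta, **values
    )


def scaled_clearances(ind: IndividualParameters, co_t: float):
    """All six clearances at cardiac output ``co_t``: proportional scaling.

    Returns ``(cl_p, q1_p, q2_p, cl_f, q1_f, q2_f)`` in L/min.  Volumes are
    never scaled.
    """
    if co_t <= 0:
        raise ValueError(f"cardiac output must be > 0, got {co_t}")
    s = co_t / ind.co_ref
    return (
        ind.cl_p * s, ind.q1_p * s, ind.q2_p * s,
        ind.cl_f * s, ind.q1_f * s, ind.q2_f * s,
    )


def pk_rhs(
    y,
    t: float,
    ind: IndividualParameters,
    input_rates=(0.0, 0.0),
    co_t: float | None = None,
):
    """Time derivative of the 8-state vector at time ``t``.

    ``input_rates`` are central-compartment infusion rates (mg/min propofol,
    µg/min fentanyl).  Clearances are evaluated at ``co_t`` (defaults to the
    individual's CO profile; pre-induction times use the baseline CO).
    """
    if co_t is None:
        co_t = co_profile(max(t, 0.0), ind.co0, ind.alpha_co, ind.co_plateau_time)
    cl_p, q1_p, q2_p, cl_f, q1_f, q2_f = scaled_clearances(ind, co_t)
    rp, rf = input_rates
    ac_p, at1_p, at2_p, ac_f, at1_f, at2_f, ce_p, ce_f = y
    cp = ac_p / ind.vc_p
    cf = ac_f / ind.vc_f
    return np.array(
        [
            rp - (cl_p + q1_p + q2_p) * cp + q1_p * at1_p / ind.vt1_p + q2_p * at2_p / ind.vt2_p,
            q1_p * cp - q1_p * at1_p / ind.vt1_p,
            q2_p * cp - q2_p * at2_p / ind.vt2_p,
            rf - (cl_f + q1_f + q2_f) * cf + q1_f * at1_f / ind.vt1_f + q2_f * at2_f / ind.vt2_f,
            q1_f * cf - q1_f * at1_f / ind.vt1_f,
            q2_f * cf - q2_f * at2_f / ind.vt2_f,
            ind.ke0 * (cp - ce_p),
            ind.ke0 * (cf - ce_f),
        ]
    )


def bis_model(ce_p, ce_f, params) -> float:
    """BIS from effect-site concentrations via the additive Emax link.

    ``U = ce_p/ce50_p + ce_f/ce50_f + alpha_int * (ce_p/ce50_p)(ce_f/ce50_f)``
    and ``BIS = bis0 * (1 - emax * U^gamma / (1 + U^gamma))``.  At the final
    fixed values (emax = gamma = 1, alpha_int = 0) this is ``bis0 / (1 + U)``.
    ``params`` may be population or individual parameters (any object with
    the PD fields).
    """
    ce_p = np.asarray(ce_p, dtype=float)
    ce_f = np.asarray(ce_f, dtype=float)
    if np.any(ce_p < 0) or np.any(ce_f < 0):
        raise ValueError("effect-site concentrations must be >= 0")
    up = ce_p / params.ce50_p
    uf = ce_f / params.ce50_f
    u = up + uf + params.alpha_int * up * uf
    ug = np.power(u, params.gamma, where=u > 0, out=np.zeros_like(u))
    bis = params.bis0 * (1.0 - params.emax * ug / (1.0 + ug))
    return bis if bis.ndim else float(bis)


def residual_loglik(obs_type: str, y_obs, y_pred, pop: PopulationParameters):
    """Gaussian log-density of one observation under the residual model.

    CP/CF carry proportional error (SD = sigma * prediction); BIS and CO
    carry additive error.  Vectorized over ``y_obs``/``y_pred``.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if obs_type == "CP":
        if np.any(y_pred <= 0):
            raise ValueError("proportional residual model requires y_pred > 0 (CP)")
        sd = pop.sigma_prop_p * y_pred
    elif obs_type == "CF":
        if np.any(y_pred <= 0):
            raise ValueError("proportional residual model requires y_pred > 0 (CF)")
        sd = pop.sigma_prop_f * y_pred
    elif obs_type == "BIS":
        sd = np.broadcast_to(pop.sigma_bis, y_pred.shape)
    elif obs_type == "CO":
        sd = np.broadcast_to(pop.sigma_co, y_pred.shape)
    else:
        raise ValueError(f"unknown observation type {obs_type!r}")
    z = (y_obs - y_pred) / sd
    ll = -0.5 * (z * z + _LOG_2PI) - np.log(sd)
    return ll if ll.ndim else float(ll)
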