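"""Parameter containers for the joint propofol-fentanyl-CO-BIS model.

The model couples two three-compartment mammillary PK models (propofol in
mg, fentanyl in µg) whose elimination and distribution clearances scale
proportionally with cardiac output, a shared-``ke0`` effect compartment per
drug, an additive Emax link from normalized effect-site concentrations to
BIS, and a piecewise-linear intra-operative cardiac output trajectory.

Inter-individual variability is log-normal and diagonal; residual error is
proportional for the two concentration streams and additive for BIS and CO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "STRUCTURAL_FIELDS",
    "PopulationParameters",
    "CovariateRecord",
    "IndividualParameters",
    "cv_to_omega2",
    "omega2_to_cv",
    "load_parameters",
    "dump_parameters",
    "table3_parameters",
]

#: Structural (subject-level) parameters, in canonical order.  Everything a
#: simulated individual needs; variances, residual scales and covariate
#: coefficients live only at the population level.
STRUCTURAL_FIELDS = (
    "vc_p", "cl_p", "q1_p", "q2_p", "vt1_p", "vt2_p",
    "vc_f", "cl_f", "q1_f", "q2_f", "vt1_f", "vt2_f",
    "bis0", "emax", "gamma", "alpha_int",
    "ce50_p", "ce50_f", "ke0", "co0", "alpha_co",
)

_POSITIVE = (
    "vc_p", "cl_p", "q1_p", "q2_p", "vt1_p", "vt2_p",
    "vc_f", "cl_f", "q1_f", "q2_f", "vt1_f", "vt2_f",
    "ce50_p", "ce50_f", "ke0", "co0",
)


def cv_to_omega2(cv_percent: float) -> float:
    """Convert a log-normal %CV to the variance of the underlying normal."""
    return math.log1p((cv_percent / 100.0) ** 2)


def omega2_to_cv(omega2: float) -> float:
    """Inverse of :func:`cv_to_omega2`."""
    return 100.0 * math.sqrt(math.expm1(omega2))


@dataclass
class PopulationParameters:
    """Population fixed effects, variability and residual-error scales.

    Volumes in L, clearances in L/min at the reference cardiac output
    ``co_ref``, ``ce50_p`` in mg/L, ``ce50_f`` in ng/mL, ``ke0`` in 1/min
    (shared by both drugs), ``co0`` in L/min, ``alpha_co`` in (L/min)/h,
    covariate coefficients ``beta_age`` (%/year, centered at ``age_ref``)
    and ``beta_study`` (% for Study 2) acting on ``alpha_co``.
    """

    vc_p: float
    cl_p: float
    q1_p: float
    q2_p: float
    vt1_p: float
    vt2_p: float
    vc_f: float
    cl_f: float
    q1_f: float
    q2_f: float
    vt1_f: float
    vt2_f: float
    bis0: float
    ce50_p: float
    ce50_f: float
    ke0: float
    co0: float
    alpha_co: float
    emax: float = 1.0
    gamma: float = 1.0
    alpha_int: float = 0.0
    co_ref: float = 6.5
    co_plateau_time: float = 300.0
    beta_age: float = 0.0
    beta_study: float = 0.0
    age_ref: float = 64.0
    omega2: dict[str, float] = field(default_factory=dict)
    sigma_prop_p: float = 0.386
    sigma_prop_f: float = 0.310
    sigma_bis: float = 8.42
    sigma_co: float = 1.41

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0 < self.bis0 <= 100):
            raise ValueError(f"bis0 must lie in (0, 100], got {self.bis0}")
        if not (0 < self.emax <= 1):
            raise ValueError(f"emax must lie in (0, 1], got {self.emax}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.co_ref <= 0:
            raise ValueError(f"co_ref must be > 0, got {self.co_ref}")
        unknown = set(self.omega2) - set(STRUCTURAL_FIELDS)
        if unknown:
            raise ValueError(f"omega2 keys are not structural parameters: {sorted(unknown)}")
        for key, val in self.omega2.items():
            if val < 0:
                raise ValueError(f"omega2[{key}] must be >= 0, got {val}")
        for name in ("sigma_prop_p", "sigma_prop_f", "sigma_bis", "sigma_co"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **changes) -> "PopulationParameters":
        return replace(self, **changes)

    @property
    def eta_names(self) -> tuple[str, ...]:
        """Structural parameters carrying nonzero IIV, in canonical order."""
        return tuple(p for p in STRUCTURAL_FIELDS if self.omega2.get(p, 0.0) > 0.0)


@dataclass(frozen=True)
class CovariateRecord:
    """Per-subject covariates: age (years), study arm (1/2), weight (kg)."""

    subject_id: int | str
    age: float
    study: int
    weight: float

    def __post_init__(self) -> None:
        if not (18.0 <= self.age <= 100.0):
            raise ValueError(f"age must lie in [18, 100] years, got {self.age}")
        if self.study not in (1, 2):
            raise ValueError(f"study must be 1 or 2, got {self.study}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0 kg, got {self.weight}")


@dataclass
class IndividualParameters:
    """Realized subject-level parameters (covariates and eta applied)."""

    vc_p: float
    cl_p: float
    q1_p: float
    q2_p: float
    vt1_p: float
    vt2_p: float
    vc_f: float
    cl_f: float
    q1_f: float
    q2_f: float
    vt1_f: float
    vt2_f: float
    bis0: float
    ce50_p: float
    ce50_f: float
    ke0: float
    co0: float
    alpha_co: float
    emax: float = 1.0
    gamma: float = 1.0
    alpha_int: float = 0.0
    co_ref: float = 6.5
    co_plateau_time: float = 300.0
    eta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def load_parameters(source) -> PopulationParameters:
    """Read a population parameter set from a YAML mapping or file path.

    The ``iiv_cv_percent`` block (per-parameter %CV) is converted to
    ``omega2`` variances; an explicit ``omega2`` block is also accepted.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    omega2 = dict(raw.pop("omega2", {}))
    for key, cv in raw.pop("iiv_cv_percent", {}).items():
        omega2[key] = cv_to_omega2(cv)
    return PopulationParameters(omega2=omega2, **raw)


def dump_parameters(pop: PopulationParameters, path) -> None:
    """Serialize a parameter set to YAML (omega2 stored as variances)."""
    data = {name: getattr(pop, name) for name in STRUCTURAL_FIELDS}
    data.update(
        co_ref=pop.co_ref,
        co_plateau_time=pop.co_plateau_time,
        beta_age=pop.beta_age,
        beta_study=pop.beta_study,
        age_ref=pop.age_ref,
        omega2={k: float(v) for k, v in pop.omega2.items()},
        sigma_prop_p=pop.sigma_prop_p,
        sigma_prop_f=pop.sigma_prop_f,
        sigma_bis=pop.sigma_bis,
        sigma_co=pop.sigma_co,
    )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def table3_parameters() -> PopulationParameters:
    """The packaged final population estimates of the model."""
    ref = resources.files("copkpd.data").joinpath("table3_final.yaml")
    with ref.open() as fh:
        return load_parameters(yaml.safe_load(fh))
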