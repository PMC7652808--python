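"""Virtual propofol-fentanyl trials with the design the analysis assumes.

Each virtual subject receives a 1.5 µg/kg fentanyl bolus 5 min before the
propofol infusion starts (time 0 = induction = start of the surgery clock),
a BIS-titrated propofol infusion, and intermittent 2-3 µg/kg fentanyl
boluses at random surgical-stimulus times.  Arterial PK samples follow the
study sampling rules (dense early samples, every 30 min during anesthesia,
and a study-specific post-cessation washout schedule); BIS and CO are
recorded on a regular grid.  Residual noise is proportional for the drug
concentrations and additive for BIS and CO; concentrations under the assay
limits of quantification are flagged, not dropped.

The clinical titration is emulated by a deliberately simple proportional
rule: every 10 min the infusion rate steps ±20% whenever the noise-free
model BIS leaves the target band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .model import covariate_factor_alpha_co
from .params import CovariateRecord, IndividualParameters, PopulationParameters, STRUCTURAL_FIELDS
from .io import TrialDataset

__all__ = ["TrialDesign", "default_designs", "sample_population", "bis_feedback_dosing",
           "generate_trial", "LOQ_PROPOFOL", "LOQ_FENTANYL"]

#: Assay limits of quantification: propofol 10 ng/mL = 0.01 mg/L, fentanyl 0.05 ng/mL.
LOQ_PROPOFOL = 0.01
LOQ_FENTANYL = 0.05


@dataclass(frozen=True)
class TrialDesign:
    """Design of one study arm."""

    n_subjects: int = 11
    study: int = 2
    age_range: tuple[float, float] = (51.0, 80.0)
    weight_range: tuple[float, float] = (57.5, 105.0)
    fentanyl_loading: float = 1.5            # µg/kg at t = -5 min
    fentanyl_topup: tuple[float, float] = (2.0, 3.0)   # µg/kg, uniform
    topup_rate_per_h: float = 2.0            # mean surgical-stimulus rate
    bis_band: tuple[float, float] = (40.0, 60.0)
    surgery_duration: tuple[float, float] = (150.0, 300.0)  # min
    initial_propofol_rate: float = 4.0       # mg/min: holds the typical
    # subject near mid-band BIS 50 at steady state under the final estimates
    adjust_interval: float = 10.0            # min between titration steps
    adjust_fraction: float = 0.2             # ±20% proportional step
    bis_co_interval: float = 5.0             # recording grid, min
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.bis_band[0] < self.bis_band[1]:
            raise ValueError("bis target band must be (low, high) with low < high")
        for name in ("age_range", "weight_range", "fentanyl_topup", "surgery_duration"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be a nonempty range")

    def replace(self, **kw):
        return replace(self, **kw)


def default_designs(n_subjects: int = 22) -> list[TrialDesign]:
    """The pooled two-arm design: subjects split between Study 1 and 2."""
    n1 = n_subjects // 2
    return [TrialDesign(n_subjects=n1, study=1),
            TrialDesign(n_subjects=n_subjects - n1, study=2)]


def pk_sampling_times(study: int, t_stop: float) -> np.ndarray:
    """Arterial sampling rule: dense early, every 30 min, study-specific washout."""
    during = [1.0, 3.0, 5.0, 10.0, 15.0, 30.0]
    t = 60.0
    while t < t_stop:
        during.append(t)
        t += 30.0
    post = [1, 3, 5, 10, 15, 30, 60] if study == 1 else [1, 3, 5, 10, 15, 30, 60, 90, 120, 240]
    return np.array(during + [t_stop + o for o in post])


def sample_population(designs, pop: PopulationParameters, seed: int,
                      covariate_form: str = "proportional"):
    """Draw subjects: uniform covariates over design ranges, log-normal IIV.

    ``designs`` is one TrialDesign or a list (arms concatenated, subject ids
    sequential).  Returns a list of (CovariateRecord, IndividualParameters).
    """
    if isinstance(designs, TrialDesign):
        designs = [designs]
    rng = np.random.default_rng(seed)
    out = []
    sid = 0
    for design in designs:
        for _ in range(design.n_subjects):
            sid += 1
            age = round(rng.uniform(*design.age_range), 1)
            wt = round(rng.uniform(*design.weight_range), 1)
            cov = CovariateRecord(subject_id=sid, age=age, study=design.study, weight=wt)
            eta = {k: rng.normal(0.0, np.sqrt(v)) for k, v in pop.omega2.items() if v > 0}
            values = {p: getattr(pop, p) * np.exp(eta.get(p, 0.0)) for p in STRUCTURAL_FIELDS}
            values["alpha_co"] *= covariate_factor_alpha_co(pop, cov, form=covariate_form)
            ind = IndividualParameters(co_ref=pop.co_ref, co_plateau_time=pop.co_plateau_time,
                                       eta=eta, **values)
            out.append((cov, ind))
    return out


def _struct_dict(ind: IndividualParameters) -> dict:
    sp = {f: getattr(ind, f) for f in STRUCTURAL_FIELDS}
    sp["co_plateau_time"] = ind.co_plateau_time
    sp["co_ref"] = ind.co_ref
    return sp


def bis_feedback_dosing(ind: IndividualParameters, cov: CovariateRecord,
                        design: TrialDesign, seed: int):
    """Dosing history for one subject under the simplified titration rule.

    Returns (boluses, infusion_segments, t_stop): fentanyl loading bolus at
    -5 min, Poisson-timed top-ups, and a propofol infusion whose rate steps
    ±(adjust_fraction) at each adjustment time the noise-free BIS lies
    outside the target band (clamped at zero).
    """
    rng = np.random.default_rng(seed)
    t_stop = rng.uniform(*design.surgery_duration)
    # candidate surgical-stimulus times: Poisson process on (0, t_stop); a
    # top-up is actually given only if the patient is not already deep
    # (noise-free BIS at or above the band floor) - thinning that mimics the
    # clinical 'inadequate analgesia' trigger
    n_stim = rng.poisson(design.topup_rate_per_h * t_stop / 60.0)
    stim_times = np.sort(rng.uniform(0.0, t_stop, size=n_stim))
    topup_amt = {float(t): rng.uniform(*design.fentanyl_topup) * cov.weight
                 for t in stim_times}
    boluses = [(-5.0, "fentanyl", design.fentanyl_loading * cov.weight)]

    sp = _struct_dict(ind)
    lo, hi = design.bis_band
    rate = design.initial_propofol_rate
    segments = []   # (t0, t1, 'propofol', rate)
    t_seg = 0.0

    def bis_at(t):
        trial_segments = segments + [(t_seg, t, "propofol", rate)]
        sched = _engine.build_schedule(boluses, trial_segments, np.array([t]), max_step=2.0)
        return float(_engine.predict_schedule(sched, sp)["bis"][0])

    adjust_times = np.arange(design.adjust_interval, t_stop, design.adjust_interval)
    decisions = sorted([(float(t), "adjust") for t in adjust_times]
                       + [(float(t), "topup") for t in stim_times])
    for t, what in decisions:
        bis = bis_at(t)
        if what == "topup":
            if bis >= lo:
                boluses.append((t, "fentanyl", topup_amt[t]))
        elif bis > hi or bis < lo:
            segments.append((t_seg, t, "propofol", rate))
            rate = rate * (1.0 + design.adjust_fraction) if bis > hi \
                else rate * (1.0 - design.adjust_fraction)
            rate = max(rate, 0.0)
            t_seg = t
    segments.append((t_seg, t_stop, "propofol", rate))
    return boluses, segments, float(t_stop)


def generate_trial(designs, pop: PopulationParameters, seed: int,
                   covariate_form: str = "proportional",
                   max_step: float = 1.0) -> TrialDataset:
    """Simulate a full virtual trial and return the flat-dialect dataset.

    Reproducible from (designs, pop, seed).  Observation noise follows the
    residual model (proportional CP/CF, additive BIS/CO); BIS is clipped to
    [0, 100]; concentrations below the assay limits are flagged BLQ.
    """
    if isinstance(designs, TrialDesign):
        designs = [designs]
    subjects = sample_population(designs, pop, seed, covariate_form=covariate_form)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7041]))
    design_of = []
    for d in designs:
        design_of += [d] * d.n_subjects
    rows = []
    for (cov, ind), design in zip(subjects, design_of):
        dose_seed = int(rng.integers(0, 2**31 - 1))
        boluses, segments, t_stop = bis_feedback_dosing(ind, cov, design, dose_seed)
        t_pk = pk_sampling_times(design.study, t_stop)
        t_grid = np.arange(0.0, t_stop + 60.0 + 1e-9, design.bis_co_interval)
        obs_times = np.unique(np.concatenate([t_pk, t_grid]))
        sched = _engine.build_schedule(boluses, segments, obs_times, max_step=max_step)
        pred = _engine.predict_schedule(sched, _struct_dict(ind))
        is_pk = np.isin(obs_times, t_pk)
        is_grid = np.isin(obs_times, t_grid)

        base = dict(ID=cov.subject_id, AGE=cov.age, STUDY=cov.study, WT=cov.weight)
        for t, _, amt in boluses:
            rows.append(dict(base, TIME=t, EVID=1, CMT=2, DVID=0, AMT=amt,
                             RATE=np.nan, DV=np.nan, MDV=1, BLQ=0))
        for t0, t1, _, r in segments:
            if r > 0 and t1 > t0:
                rows.append(dict(base, TIME=t0, EVID=1, CMT=1, DVID=0,
                                 AMT=r * (t1 - t0), RATE=r, DV=np.nan, MDV=1, BLQ=0))
        for i, t in enumerate(obs_times):
            if is_pk[i]:
                cp = pred["cp"][i] * (1.0 + rng.normal(0.0, pop.sigma_prop_p))
                rows.append(dict(base, TIME=t, EVID=0, CMT=0, DVID=1, AMT=np.nan,
                                 RATE=np.nan, DV=cp, MDV=0,
                                 BLQ=int(cp < LOQ_PROPOFOL)))
                cf = pred["cf"][i] * (1.0 + rng.normal(0.0, pop.sigma_prop_f))
                rows.append(dict(base, TIME=t, EVID=0, CMT=0, DVID=2, AMT=np.nan,
                                 RATE=np.nan, DV=cf, MDV=0,
                                 BLQ=int(cf < LOQ_FENTANYL)))
            if is_grid[i]:
                bis = np.clip(pred["bis"][i] + rng.normal(0.0, pop.sigma_bis), 0.0, 100.0)
                rows.append(dict(base, TIME=t, EVID=0, CMT=0, DVID=3, AMT=np.nan,
                                 RATE=np.nan, DV=bis, MDV=0, BLQ=0))
                co = pred["co"][i] + rng.normal(0.0, pop.sigma_co)
                rows.append(dict(base, TIME=t, EVID=0, CMT=0, DVID=4, AMT=np.nan,
                                 RATE=np.nan, DV=co, MDV=0, BLQ=0))
    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                        kind="stable").reset_index(drop=True)
    cols = ["ID", "TIME", "EVID", "CMT", "DVID", "AMT", "RATE", "DV", "MDV", "BLQ",
            "AGE", "STUDY", "WT"]
    return TrialDataset(df[cols])
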