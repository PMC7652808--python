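"""Multi-stage analysis pipeline with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import CovariateRecord, PopulationParameters, STRUCTURAL_FIELDS, \
    load_parameters, table3_parameters
from .io import TrialDataset, read_dataset, write_dataset
from .synth import TrialDesign, generate_trial
from .simulate import csdt
from .estimation import FitSpec, FitResult, fit_population, bootstrap

__all__ = ["run_pipeline", "fit_result_to_dict", "load_fit_spec"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _resolve_params(value) -> PopulationParameters:
    if value in (None, "table3", "table3_final"):
        return table3_parameters()
    if isinstance(value, PopulationParameters):
        return value
    return load_parameters(value)


def fit_result_to_dict(res: FitResult) -> dict:
    est = {name: getattr(res.estimates, name) for name in STRUCTURAL_FIELDS}
    est.update(beta_age=res.estimates.beta_age, beta_study=res.estimates.beta_study,
               omega2={k: float(v) for k, v in res.estimates.omega2.items()},
               sigma_prop_p=res.estimates.sigma_prop_p,
               sigma_prop_f=res.estimates.sigma_prop_f,
               sigma_bis=res.estimates.sigma_bis, sigma_co=res.estimates.sigma_co)
    return dict(estimates=est, ofv=res.ofv, se=res.se, rse_percent=res.rse_percent,
                eta_shrinkage=res.eta_shrinkage, convergence=res.convergence,
                n_obs=res.n_obs,
                ebe={str(k): v for k, v in res.ebe.items()})


def load_fit_spec(source, default_params=None) -> FitSpec:
    """Build a FitSpec from a YAML mapping/file (keys mirror FitSpec fields)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    source = dict(source or {})
    initial = source.pop("initial", None)
    pop = _resolve_params(initial) if initial is not None else (
        default_params or table3_parameters())
    source["estimate"] = tuple(source.get("estimate", ()))
    return FitSpec(initial=pop, **source)


def run_pipeline(config, outdir=None) -> dict:
    """Execute the configured stages in order and write a manifest.

    ``config`` is a mapping (or YAML path) with optional ``outdir``,
    ``params`` and a ``stages`` list; each stage is a mapping with a
    ``stage`` key among generate | fit | vpc | bootstrap | csdt plus stage
    parameters.  Later stages read the artifacts of earlier ones; a missing
    upstream artifact is an error before any computation.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    pop = _resolve_params(config.get("params"))
    stages = config.get("stages", [])

    # fail fast on missing upstream artifacts
    produced = set()
    for st in stages:
        name = st["stage"]
        if name in ("fit", "vpc", "bootstrap") and "data" not in st and "generate" not in produced:
            raise ValueError(f"stage {name!r} needs a dataset: add a generate stage "
                             "or a 'data' path")
        if name == "vpc" and "fit" not in produced and "fit" not in st:
            raise ValueError("stage 'vpc' needs an upstream fit stage or a 'fit' path")
        produced.add(name)

    manifest = {"package": "copkpd", "version": __version__, "stages": []}
    dataset: TrialDataset | None = None
    fit_res: FitResult | None = None

    for st in stages:
        name = st["stage"]
        entry = {"stage": name, "seed": st.get("seed")}
        if name == "generate":
            designs = [TrialDesign(**d) for d in st.get("designs", [{}])]
            dataset = generate_trial(designs, pop, seed=int(st.get("seed", 0)))
            path = outdir / st.get("out", "trial.csv")
            write_dataset(dataset, path)
            entry["outputs"] = {str(path): _sha256(path)}
        elif name == "fit":
            if "data" in st:
                dataset = read_dataset(st["data"])
            spec = load_fit_spec(st.get("spec", {}), default_params=pop)
            fit_res = fit_population(dataset, spec)
            path = outdir / st.get("out", "fit.json")
            path.write_text(json.dumps(fit_result_to_dict(fit_res), indent=1,
                                       default=float))
            entry["outputs"] = {str(path): _sha256(path)}
        elif name == "vpc":
            from .diagnostics import pcvpc

            res = pcvpc(dataset, fit_res, n_sim=int(st.get("n_sim", 1000)),
                        n_bins=int(st.get("n_bins", 10)), seed=int(st.get("seed", 0)))
            payload = {
                label: dict(bin_edges=r.bin_edges.tolist(), n_obs=r.n_obs.tolist(),
                            obs_pct=r.obs_pct.tolist(), sim_lo=r.sim_lo.tolist(),
                            sim_med=r.sim_med.tolist(), sim_hi=r.sim_hi.tolist(),
                            n_sim=r.n_sim)
                for label, r in res.items()
            }
            path = outdir / st.get("out", "vpc.json")
            path.write_text(json.dumps(payload, indent=1))
            entry["outputs"] = {str(path): _sha256(path)}
        elif name == "bootstrap":
            spec = load_fit_spec(st.get("spec", {}), default_params=pop)
            bres = bootstrap(dataset, spec, n_resamples=int(st.get("n_resamples", 300)),
                             seed=int(st.get("seed", 0)))
            path = outdir / st.get("out", "bootstrap.csv")
            bres.summary.to_csv(path)
            entry["outputs"] = {str(path): _sha256(path)}
            entry["n_failed"] = bres.n_failed
        elif name == "simulate":
            from .events import DoseEvent
            from .model import individual_from_population
            from .simulate import simulate_individual

            cov = CovariateRecord(subject_id=0, age=float(st.get("age", 64.0)),
                                  study=int(st.get("study", 1)),
                                  weight=float(st.get("weight", 70.0)))
            ind = individual_from_population(pop, cov)
            ev = [DoseEvent(**e) for e in st["events"]]
            t_end = float(st.get("until", max(e.time for e in ev) + 120.0))
            grid = np.arange(min(0.0, min(e.time for e in ev)), t_end + 1e-9,
                             float(st.get("dt", 1.0)))
            sim = simulate_individual(ind, ev, grid)
            path = outdir / st.get("out", "sim.csv")
            pd.DataFrame({"TIME": sim.t, "CP": sim.cp, "CF": sim.cf,
                          "CEP": sim.ce_p, "CEF": sim.ce_f, "BIS": sim.bis,
                          "CO": sim.co}).to_csv(path, index=False)
            entry["outputs"] = {str(path): _sha256(path)}
        elif name == "csdt":
            rows = []
            for age in st.get("ages", (50, 65, 80)):
                for study in st.get("studies", (1, 2)):
                    cov = CovariateRecord(subject_id=0, age=age, study=study, weight=70.0)
                    r = csdt(pop, cov,
                             decrements=tuple(st.get("decrements",
                                                     (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8))),
                             maintain=float(st.get("maintain", 200.0)),
                             definition=st.get("definition", "bis"))
                    for d, tmin in r.times.items():
                        rows.append(dict(age=age, study=study, decrement=d,
                                         minutes=tmin))
            path = outdir / st.get("out", "csdt.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            entry["outputs"] = {str(path): _sha256(path)}
        else:
            raise ValueError(f"unknown stage {name!r}")
        manifest["stages"].append(entry)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
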