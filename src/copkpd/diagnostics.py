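"""Predictive-check and residual diagnostics.

The prediction-corrected VPC rescales observed and simulated values by the
ratio of the bin-median population prediction to each record's own
population prediction (additive shift for the bounded BIS scale), then
compares observed 10th/50th/90th percentiles per time bin against the
2.5-97.5% envelope of the same percentiles across replicate simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .estimation import FitSpec, FitResult, FoceProblem, _Context, _jacobian
from .params import PopulationParameters
from .io import TrialDataset, DVID_LABEL

__all__ = ["VpcResult", "prediction_correct", "pcvpc", "cwres", "plot_vpc"]

_PERCENTILES = (10.0, 50.0, 90.0)


@dataclass
class VpcResult:
    """Per-stream pcVPC summary."""

    stream: str
    bin_edges: np.ndarray          # len nbins+1, on the time axis
    n_obs: np.ndarray              # observations per bin
    obs_pct: np.ndarray            # (nbins, 3) observed corrected percentiles
    sim_lo: np.ndarray             # (nbins, 3) 2.5% envelope of simulated percentiles
    sim_med: np.ndarray            # (nbins, 3)
    sim_hi: np.ndarray             # (nbins, 3) 97.5% envelope
    n_sim: int

    def fraction_outside(self) -> float:
        out = (self.obs_pct < self.sim_lo) | (self.obs_pct > self.sim_hi)
        return float(np.mean(out))


def prediction_correct(values, pred_pop, bin_ids, mode: str = "ratio"):
    """Prediction-correct ``values`` by the bin-median population prediction.

    ``ratio``: value * median(PRED in bin) / PRED; ``additive``: value +
    (median(PRED in bin) - PRED), for bounded scales where ratio correction
    distorts.
    """
    values = np.asarray(values, dtype=float)
    pred_pop = np.asarray(pred_pop, dtype=float)
    bin_ids = np.asarray(bin_ids)
    out = np.empty_like(values)
    for b in np.unique(bin_ids):
        m = bin_ids == b
        med = np.median(pred_pop[m])
        if mode == "ratio":
            if np.any(pred_pop[m] <= 0):
                raise ValueError("ratio prediction correction needs positive predictions")
            out[m] = values[m] * med / pred_pop[m]
        elif mode == "additive":
            out[m] = values[m] + (med - pred_pop[m])
        else:
            raise ValueError(f"unknown correction mode {mode!r}")
    return out


def _equal_count_bins(t: np.ndarray, n_bins: int, min_per_bin: int = 5):
    """Quantile bin edges on time; under-filled bins merged with neighbors."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(t, qs))
    while len(edges) > 2:
        ids = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(ids, minlength=len(edges) - 1)
        small = np.where(counts < min_per_bin)[0]
        if small.size == 0:
            break
        j = small[0]
        edges = np.delete(edges, j + 1 if j + 1 < len(edges) - 1 else j)
    ids = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    return edges, ids


def _as_pop_and_spec(fit, dataset) -> tuple[PopulationParameters, FitSpec]:
    if isinstance(fit, FitResult):
        spec = fit.spec if fit.spec is not None else FitSpec(initial=fit.estimates)
        return fit.estimates, replace(spec, initial=fit.estimates)
    return fit, FitSpec(initial=fit)


def pcvpc(dataset: TrialDataset, fit, n_sim: int = 1000, n_bins: int = 10,
          seed: int = 0, bis_mode: str = "additive") -> dict[str, VpcResult]:
    """Prediction-corrected visual predictive check, per observation stream.

    Replicate datasets are simulated under the fitted model with the original
    designs and covariates (new random effects and residual errors per
    replicate); observed and simulated records are corrected identically
    using the population predictions, then summarized per equal-count time
    bin.  Seed-reproducible.
    """
    pop, spec = _as_pop_and_spec(fit, dataset)
    problem = FoceProblem(dataset, spec)
    ctx = _Context(pop, spec, pop.eta_names)
    rng = np.random.default_rng(seed)
    q = len(pop.eta_names)
    omega_sd = np.sqrt(ctx.omega2)
    sig = dict(zip((1, 2, 3, 4), ctx.sigma))

    preds0, rows = [], []
    for si, ws in enumerate(problem.workspaces):
        pred = ctx.predict(ws, np.zeros(q))
        preds0.append(pred)
        rows.append(pd.DataFrame({"subject": si, "t": ws.t, "dvid": ws.dvid,
                                  "y": ws.y, "pred": pred}))
    obs = pd.concat(rows, ignore_index=True)

    results = {}
    for d, label in DVID_LABEL.items():
        sel = obs[obs["dvid"] == d]
        if sel.empty:
            continue
        mode = "additive" if (d == 3 and bis_mode == "additive") else "ratio"
        edges, bin_ids = _equal_count_bins(sel["t"].to_numpy(), n_bins)
        nb = len(edges) - 1
        corr = prediction_correct(sel["y"].to_numpy(), sel["pred"].to_numpy(),
                                  bin_ids, mode)
        obs_pct = np.full((nb, 3), np.nan)
        for b in range(nb):
            m = bin_ids == b
            obs_pct[b] = np.percentile(corr[m], _PERCENTILES)
        results[label] = dict(edges=edges, bin_ids=bin_ids, sel=sel, mode=mode,
                              obs_pct=obs_pct,
                              n_obs=np.bincount(bin_ids, minlength=nb),
                              sim=np.empty((n_sim, nb, 3)))

    for r in range(n_sim):
        sim_rows = []
        for si, ws in enumerate(problem.workspaces):
            eta = rng.normal(0.0, omega_sd) if q else np.zeros(0)
            f = ctx.predict(ws, eta)
            eps = rng.standard_normal(f.size)
            y = f.copy()
            for d in (1, 2):
                m = ws.masks[d]
                y[m] = f[m] * (1.0 + sig[d] * eps[m])
            m = ws.masks[3]
            y[m] = np.clip(f[m] + sig[3] * eps[m], 0.0, 100.0)
            m = ws.masks[4]
            y[m] = f[m] + sig[4] * eps[m]
            sim_rows.append(pd.DataFrame({"dvid": ws.dvid, "y": y,
                                          "pred": preds0[si]}))
        sim = pd.concat(sim_rows, ignore_index=True)
        for d, label in DVID_LABEL.items():
            if label not in results:
                continue
            res = results[label]
            ys = sim[sim["dvid"] == d]["y"].to_numpy()
            ps = sim[sim["dvid"] == d]["pred"].to_numpy()
            corr = prediction_correct(ys, ps, res["bin_ids"], res["mode"])
            nb = len(res["edges"]) - 1
            for b in range(nb):
                m = res["bin_ids"] == b
                res["sim"][r, b] = np.percentile(corr[m], _PERCENTILES)

    out = {}
    for label, res in results.items():
        sim = res["sim"]
        out[label] = VpcResult(
            stream=label, bin_edges=res["edges"], n_obs=res["n_obs"],
            obs_pct=res["obs_pct"],
            sim_lo=np.percentile(sim, 2.5, axis=0),
            sim_med=np.percentile(sim, 50.0, axis=0),
            sim_hi=np.percentile(sim, 97.5, axis=0),
            n_sim=n_sim,
        )
    return out


def cwres(fit: FitResult, dataset: TrialDataset) -> pd.DataFrame:
    """Conditional weighted residuals (FOCE linearization about the EBEs).

    The model is linearized in eta about each subject's conditional mode:
    E[y] ≈ f(η̂) - J η̂, Cov[y] ≈ J Ω J' + Σ(f(η̂)); residuals are whitened
    with the Cholesky factor of the covariance, so on well-specified data
    they have mean ≈ 0 and SD ≈ 1.
    """
    pop, spec = _as_pop_and_spec(fit, dataset)
    problem = FoceProblem(dataset, spec)
    ctx = _Context(pop, spec, pop.eta_names)
    frames = []
    for ws in problem.workspaces:
        ebe = fit.ebe.get(ws.cov.subject_id, {}) if isinstance(fit, FitResult) else {}
        eta = np.array([ebe.get(n, 0.0) for n in pop.eta_names])
        f0 = ctx.predict(ws, eta)
        J = _jacobian(ctx, ws, eta, f0)
        sd = np.empty_like(f0)
        for d in (1, 2, 3, 4):
            m = ws.masks[d]
            if m.any():
                s = ctx.sigma[d - 1]
                sd[m] = s * f0[m] if d in (1, 2) else s
        mean = f0 - J @ eta
        cov = J @ np.diag(ctx.omega2) @ J.T + np.diag(sd * sd)
        L = np.linalg.cholesky(cov)
        w = solve_triangular(L, ws.y - mean, lower=True)
        frames.append(pd.DataFrame({"ID": ws.cov.subject_id, "TIME": ws.t,
                                    "DVID": ws.dvid, "CWRES": w,
                                    "PRED": f0}))
    return pd.concat(frames, ignore_index=True)


def plot_vpc(results: dict[str, VpcResult], path) -> None:
    """Panel per stream: observed percentiles over simulation envelopes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
    for ax, (label, r) in zip(axes[0], results.items()):
        mid = 0.5 * (r.bin_edges[:-1] + r.bin_edges[1:])
        for k, c in zip(range(3), ("gray", "tab:blue", "gray")):
            ax.fill_between(mid, r.sim_lo[:, k], r.sim_hi[:, k], alpha=0.3, color=c,
                            step="mid")
            ax.plot(mid, r.obs_pct[:, k], "k-", lw=1.2)
        ax.set_title(f"pcVPC: {label}")
        ax.set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
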