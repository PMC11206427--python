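"""Model validation: goodness-of-fit tables, CWRES, bootstrap, pcVPC.

CWRES follows the FOCE-with-interaction linearisation: for each subject the
observation vector is approximated as linear in eta around the
empirical-Bayes mode, giving marginal mean ``f(eta_hat) - G eta_hat`` and
covariance ``G Omega G' + diag(v)``; the residual vector is whitened by the
Cholesky factor of that covariance.  Under a correct model CWRES are
approximately standard normal.

The nonparametric bootstrap resamples subjects with replacement to the
original count and refits each resample from the point estimates.  The
prediction-corrected VPC scales observations and simulations by
(bin-median PRED / own PRED) before comparing percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventDataset, SubjectRecord
from .foce import eb_estimate_all
from .kinetics import CompiledDesign
from .params import PopulationModel

__all__ = ["cwres", "gof_table", "bootstrap", "BootstrapResult",
           "pcvpc", "VpcResult"]

_log = logging.getLogger(__name__)


def cwres(results_or_dataset, model: PopulationModel | None = None,
          etas: np.ndarray | None = None) -> np.ndarray:
    """Conditional weighted residuals, one per non-BLQ observation.

    Accepts either a :class:`~voripk.model.PopPKResults` or an explicit
    (dataset, model[, etas]) triple.
    """
    if model is None:
        res = results_or_dataset
        dataset, model, etas = res.model.dataset, res.params, res.eb_etas
        design = res.model.design
    else:
        dataset = results_or_dataset
        design = CompiledDesign(dataset, include_blq=False)
    if etas is None:
        etas, _ = eb_estimate_all(design, model)
    _, info = eb_estimate_all(design, model, etas0=etas, maxiter=0)
    f, G, v, active = info["f"], info["G"], info["v"], info["active"]
    na = int(active.sum())
    out = np.empty(design.n_obs)
    om_var = model.omega.variances[active]
    for si in range(design.n_subjects):
        m = design.obs_subj == si
        if not m.any():
            continue
        fi, vi = f[m], v[m]
        yi = design.y[m]
        if na:
            Gi = G[m]
            ei = fi - Gi @ etas[si, active]
            Vi = (Gi * om_var) @ Gi.T + np.diag(vi)
        else:
            ei = fi
            Vi = np.diag(vi)
        try:
            L = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance for subject {design.subject_ids[si]}"
            ) from exc
        out[m] = np.linalg.solve(L, yi - ei)
    return out


def gof_table(results) -> pd.DataFrame:
    """GOF records: DV, PRED, IPRED and CWRES per non-BLQ observation."""
    design = results.model.design
    model = results.params
    pred = design.predict(model.theta, np.zeros((design.n_subjects, 3)))
    ipred = design.predict(model.theta, results.eb_etas)
    return pd.DataFrame({
        "id": [design.subject_ids[i] for i in design.obs_subj],
        "time": design.obs_time,
        "dv": design.y,
        "pred": pred,
        "ipred": ipred,
        "cwres": cwres(results),
    })


@dataclass
class BootstrapResult:
    """Percentile summary of bootstrap refits."""

    table: pd.DataFrame          # index: parameter; cols: median, ci_lo, ci_hi
    n_converged: int
    n_failed: int
    seed: int
    estimates: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_total(self) -> int:
        return self.n_converged + self.n_failed


def bootstrap_indices(n_subjects: int, n_resamples: int, seed: int) -> np.ndarray:
    """Deterministic resample index matrix (n_resamples, n_subjects)."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_subjects, size=(n_resamples, n_subjects))


def bootstrap(dataset: EventDataset, model: PopulationModel,
              n_resamples: int = 1000, seed: int = 0, fixed=(),
              maxiter: int = 60, method: str = "lbfgs",
              compute_rse: bool = False) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, summarise.

    Each resample draws subjects with replacement to the original count and
    is refit starting from the point estimates ``model``.  Non-converged or
    failed fits are excluded from the percentiles and counted.
    """
    from .model import PopPKModel

    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    idx = bootstrap_indices(len(dataset), n_resamples, seed)
    rows, n_failed = [], 0
    for k in range(n_resamples):
        subs = []
        for j, i in enumerate(idx[k]):
            src = dataset.subjects[i]
            subs.append(SubjectRecord(
                id=f"B{j}", doses=src.doses, observations=src.observations,
                covariates=src.covariates))
        ds_k = EventDataset(subjects=subs)
        try:
            mod = PopPKModel(ds_k, start=model, fixed=fixed)
            res = mod.fit(method=method, maxiter=maxiter,
                          compute_rse=compute_rse)
        except Exception as exc:  # noqa: BLE001 - resample fits may fail
            _log.warning("bootstrap resample %d failed: %s", k, exc)
            n_failed += 1
            continue
        if not np.isfinite(res.ofv):
            n_failed += 1
            continue
        rows.append(res.param_dict)
    if n_failed > 0.2 * n_resamples:
        _log.warning("bootstrap: %d/%d resample fits failed", n_failed,
                     n_resamples)
    est = pd.DataFrame(rows)
    table = pd.DataFrame({
        "median": est.median(),
        "ci_lo": est.quantile(0.025),
        "ci_hi": est.quantile(0.975),
    })
    return BootstrapResult(table=table, n_converged=len(rows),
                           n_failed=n_failed, seed=seed, estimates=est)


@dataclass
class VpcResult:
    """Prediction-corrected VPC summary.

    ``observed`` holds the 5/50/95th percentiles of prediction-corrected
    observations per bin; ``sim_lo``/``sim_hi`` the 95% CI of the same
    percentiles across simulated replicates.
    """

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    observed: np.ndarray   # (n_bins, 3)
    sim_lo: np.ndarray     # (n_bins, 3)
    sim_hi: np.ndarray     # (n_bins, 3)
    percentiles: tuple = (5.0, 50.0, 95.0)
    seed: int = 0
    n_sim: int = 0

    def plot(self, ax=None):  # pragma: no cover - visual
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, (p, style) in enumerate(zip(self.percentiles, ("--", "-", "--"))):
            ax.fill_between(self.bin_mid, self.sim_lo[:, j], self.sim_hi[:, j],
                            alpha=0.25)
            ax.plot(self.bin_mid, self.observed[:, j], style, color="k",
                    label=f"obs P{p:g}")
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("prediction-corrected concentration (mg/L)")
        ax.legend()
        return ax


def _time_after_dose(design: CompiledDesign) -> np.ndarray:
    tad = np.full(design.n_obs, np.inf)
    np.minimum.at(tad, design.pair_obs, design.pair_dt)
    tad[~np.isfinite(tad)] = 0.0
    return tad


def pcvpc(dataset: EventDataset, model: PopulationModel, n_sim: int = 1000,
          bins: int = 8, seed: int = 0, min_bin: int = 5) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Bins observations on time after the most recent dose (quantile bins,
    small bins merged into their neighbour), scales each observed and
    simulated concentration by (bin-median PRED / own PRED), and compares
    observed percentiles with the simulation CI.
    """
    design = CompiledDesign(dataset, include_blq=False)
    theta, sigma, omega_sd = model.theta, model.sigma, model.omega.sd
    pred = design.predict(theta, np.zeros((design.n_subjects, 3)))
    tad = _time_after_dose(design)

    qs = np.linspace(0, 1, bins + 1)
    edges = np.unique(np.quantile(tad, qs))
    if len(edges) < 2:  # all observations share one time after dose
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
    # merge undersized bins leftwards
    counts = np.bincount(bin_idx, minlength=len(edges) - 1)
    keep = []
    for b, c in enumerate(counts):
        if c and c < min_bin and keep:
            _log.info("merging VPC bin %d (%d obs) into neighbour", b, c)
            bin_idx[bin_idx == b] = keep[-1]
        elif c:
            keep.append(b)
    labels = {b: i for i, b in enumerate(sorted(set(bin_idx)))}
    bin_idx = np.array([labels[b] for b in bin_idx])
    n_bins = bin_idx.max() + 1

    bin_med_pred = np.array([np.median(pred[bin_idx == b]) for b in range(n_bins)])
    safe_pred = np.maximum(pred, 1e-12)
    factor = bin_med_pred[bin_idx] / safe_pred
    pc_obs = design.y * factor

    pcts = (5.0, 50.0, 95.0)
    observed = np.stack([
        np.percentile(pc_obs[bin_idx == b], pcts) for b in range(n_bins)])

    rng = np.random.default_rng(seed)
    sim_stats = np.empty((n_sim, n_bins, 3))
    for k in range(n_sim):
        etas = rng.normal(0.0, 1.0, size=(design.n_subjects, 3)) * omega_sd
        f = design.predict(theta, etas)
        y = f * (1.0 + rng.normal(0.0, sigma.prop_cv, design.n_obs)) \
            + rng.normal(0.0, sigma.add_sd, design.n_obs)
        pc = np.maximum(y, 0.0) * factor
        for b in range(n_bins):
            sim_stats[k, b] = np.percentile(pc[bin_idx == b], pcts)
    sim_lo = np.percentile(sim_stats, 2.5, axis=0)
    sim_hi = np.percentile(sim_stats, 97.5, axis=0)
    mids = np.array([tad[bin_idx == b].mean() for b in range(n_bins)])
    return VpcResult(bin_edges=edges, bin_mid=mids,
                     n_per_bin=np.bincount(bin_idx, minlength=n_bins),
                     observed=observed, sim_lo=sim_lo, sim_hi=sim_hi,
                     percentiles=pcts, seed=seed, n_sim=n_sim)
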