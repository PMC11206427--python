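"""Stepwise covariate search on clearance.

Forward inclusion adds, one per cycle, the candidate with the largest drop
in OFV provided the drop exceeds 3.84 (chi-square, 1 df, p < 0.05);
backward elimination then removes any covariate whose removal raises the
OFV by less than 7.88 (p < 0.005), smallest increase first.  Continuous
candidates enter as median-normalised power terms, categorical candidates
as factors.  A post-hoc rule flags retained effects with a relative
standard error above a threshold (default 50%) for explicit removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import EventDataset
from .params import CovariateEffect, PopulationModel

__all__ = ["SelectionTrace", "screen_etas", "forward_step", "backward_step",
           "apply_rse_rule", "stepwise_search",
           "FORWARD_THRESHOLD", "BACKWARD_THRESHOLD"]

_log = logging.getLogger(__name__)

FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 7.88


@dataclass
class SelectionTrace:
    """Replayable record of a stepwise covariate search."""

    steps: list = field(default_factory=list)  # dicts: step/covariate/delta_ofv/decision
    final_model: PopulationModel | None = None
    final_ofv: float | None = None

    def add(self, step: str, covariate: str | None, delta_ofv: float | None,
            decision: str) -> None:
        self.steps.append({"step": step, "covariate": covariate,
                           "delta_ofv": delta_ofv, "decision": decision})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _subject_covariate(dataset: EventDataset, name: str) -> np.ndarray:
    vals = []
    for s in dataset.subjects:
        occ = min(s.covariates)
        vals.append(s.covariates[occ].get(name, np.nan))
    return np.asarray(vals, dtype=float)


def _is_categorical(values: np.ndarray) -> bool:
    v = values[np.isfinite(values)]
    return np.all(np.isin(v, (0.0, 1.0)))


def screen_etas(results, dataset: EventDataset | None = None) -> pd.DataFrame:
    """Covariate vs eta_CL association table (reporting only, not a gate).

    Continuous covariates: Pearson correlation of eta_CL with log covariate.
    Categorical: mean eta_CL shift between groups.  Constant covariates are
    reported with association 0 and a note.
    """
    if dataset is None:
        dataset = results.model.dataset
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    eta_cl = np.asarray(results.eb_etas)[:, 0]
    names = sorted({c for s in dataset.subjects
                    for occ in s.covariates.values() for c in occ})
    rows = []
    for name in names:
        vals = _subject_covariate(dataset, name)
        ok = np.isfinite(vals)
        v, e = vals[ok], eta_cl[ok]
        if np.ptp(v) == 0:
            rows.append({"covariate": name, "type": "constant",
                         "association": 0.0, "note": "constant covariate"})
            continue
        if _is_categorical(v):
            shift = e[v == 1].mean() - e[v == 0].mean() \
                if (v == 1).any() and (v == 0).any() else 0.0
            rows.append({"covariate": name, "type": "categorical",
                         "association": float(shift), "note": ""})
        else:
            assoc = float(np.corrcoef(np.log(np.maximum(v, 1e-12)), e)[0, 1])
            rows.append({"covariate": name, "type": "continuous",
                         "association": assoc, "note": ""})
    return pd.DataFrame(rows)


def _candidate_effect(dataset: EventDataset, name: str) -> CovariateEffect:
    vals = _subject_covariate(dataset, name)
    vals = vals[np.isfinite(vals)]
    if _is_categorical(vals):
        return CovariateEffect(name, "factor", 1.0)
    ref = float(np.median(vals))
    return CovariateEffect(name, "power", 0.0, ref)


def _fit(dataset: EventDataset, start: PopulationModel, fixed, fit_kw):
    from .model import PopPKModel
    mod = PopPKModel(dataset, start=start, fixed=fixed)
    return mod.fit(compute_rse=fit_kw.pop("compute_rse", False), **fit_kw)


def forward_step(dataset: EventDataset, current: PopulationModel,
                 candidates, base_ofv: float | None = None, fixed=(),
                 threshold: float = FORWARD_THRESHOLD, **fit_kw):
    """One forward-inclusion cycle.

    Returns ``(best_name | None, delta_ofv, per_candidate_drops)``.  Ties on
    the OFV drop break alphabetically for determinism; candidates whose fit
    fails are skipped with a log entry.
    """
    present = {e.covariate for e in current.theta.cov_effects}
    candidates = [c for c in candidates if c not in present]
    if base_ofv is None:
        base_ofv = _fit(dataset, current, fixed, dict(fit_kw)).ofv
    drops: dict[str, float] = {}
    for name in sorted(candidates):
        eff = _candidate_effect(dataset, name)
        start = replace(current, theta=replace(
            current.theta, cov_effects=current.theta.cov_effects + (eff,)))
        try:
            res = _fit(dataset, start, fixed, dict(fit_kw))
        except Exception as exc:  # noqa: BLE001 - candidate fits may fail
            _log.warning("forward candidate %s failed: %s", name, exc)
            continue
        drops[name] = base_ofv - res.ofv
    if not drops:
        return None, 0.0, drops
    best = max(sorted(drops), key=lambda k: drops[k])
    if drops[best] > threshold:
        return best, drops[best], drops
    return None, drops[best], drops


def backward_step(dataset: EventDataset, full: PopulationModel,
                  full_ofv: float | None = None, fixed=(),
                  threshold: float = BACKWARD_THRESHOLD, **fit_kw):
    """One backward-elimination cycle.

    Refits with each covariate removed; the covariate with the smallest OFV
    increase is removed if that increase is below the retention threshold.
    Returns ``(removed_name | None, delta_ofv, per_covariate_increases)``.
    """
    effects = full.theta.cov_effects
    if not effects:
        raise ValueError("model has no covariates to eliminate")
    if full_ofv is None:
        full_ofv = _fit(dataset, full, fixed, dict(fit_kw)).ofv
    increases: dict[str, float] = {}
    for eff in effects:
        reduced = replace(full, theta=replace(
            full.theta,
            cov_effects=tuple(e for e in effects if e.covariate != eff.covariate)))
        try:
            res = _fit(dataset, reduced, fixed, dict(fit_kw))
        except Exception as exc:  # noqa: BLE001
            _log.warning("backward removal of %s failed: %s", eff.covariate, exc)
            continue
        increases[eff.covariate] = res.ofv - full_ofv
    if not increases:
        return None, 0.0, increases
    worst = min(sorted(increases), key=lambda k: increases[k])
    if increases[worst] < threshold:
        return worst, increases[worst], increases
    return None, increases[worst], increases


def apply_rse_rule(results, threshold_pct: float = 50.0) -> list[str]:
    """Covariate effects whose RSE exceeds ``threshold_pct`` (flag only)."""
    flagged = []
    for nm, rse in results.rse.items():
        if nm.startswith("beta_") and rse > threshold_pct:
            flagged.append(nm.removeprefix("beta_"))
            _log.info("covariate %s flagged: RSE %.1f%% > %.1f%%",
                      flagged[-1], rse, threshold_pct)
    return flagged


def stepwise_search(dataset: EventDataset, base: PopulationModel,
                    candidates, fixed=(),
                    forward_threshold: float = FORWARD_THRESHOLD,
                    backward_threshold: float = BACKWARD_THRESHOLD,
                    **fit_kw) -> SelectionTrace:
    """Full forward-inclusion / backward-elimination search on clearance."""
    trace = SelectionTrace()
    current = base
    res = _fit(dataset, current, fixed, dict(fit_kw))
    current, ofv = res.params, res.ofv
    remaining = list(candidates)
    while remaining:
        name, delta, _ = forward_step(dataset, current, remaining,
                                      base_ofv=ofv, fixed=fixed,
                                      threshold=forward_threshold, **fit_kw)
        if name is None:
            trace.add("forward", None, delta, "stop")
            break
        trace.add("forward", name, delta, "added")
        remaining.remove(name)
        eff = _candidate_effect(dataset, name)
        current = replace(current, theta=replace(
            current.theta, cov_effects=current.theta.cov_effects + (eff,)))
        res = _fit(dataset, current, fixed, dict(fit_kw))
        current, ofv = res.params, res.ofv
    while current.theta.cov_effects:
        name, delta, _ = backward_step(dataset, current, full_ofv=ofv,
                                       fixed=fixed,
                                       threshold=backward_threshold, **fit_kw)
        if name is None:
            trace.add("backward", None, delta, "stop")
            break
        trace.add("backward", name, delta, "removed")
        current = replace(current, theta=replace(
            current.theta,
            cov_effects=tuple(e for e in current.theta.cov_effects
                              if e.covariate != name)))
        res = _fit(dataset, current, fixed, dict(fit_kw))
        current, ofv = res.params, res.ofv
    trace.final_model = current
    trace.final_ofv = ofv
    return trace
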