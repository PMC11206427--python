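"""Reading, writing and validating NONMEM-style event-record CSV files.

Dialect
-------
One row per event.  Columns (header required):

``ID, TIME, EVID, AMT, RATE, DUR, SS, II, ROUTE, DV, MDV, OCC`` plus any
number of covariate columns (``QCRP, CLCR, CRRT, PLT, PT, AGE, WT, SEX,
ECMO, AST, ...``).  ``EVID=1`` marks a dose row (AMT in mg, required > 0),
``EVID=0`` an observation row (DV in mg/L unless ``MDV=1``).  Infusion
duration comes from ``DUR`` if present, else ``AMT/RATE``, else a 1 h
default.  ``SS=1`` with ``II`` marks a steady-state dose.  ``ROUTE`` codes:
``iv`` (or ``iv_infusion``), ``oral``, ``ng`` (or ``nasogastric``).  Sex
coding: 0 = male, 1 = female.  Serum creatinine is in umol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import LLOQ, DoseEvent, EventDataset, ObservationEvent, SubjectRecord

__all__ = [
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "Violation",
    "cockcroft_gault",
]

_ROUTE_CODES = {
    "iv": "iv_infusion", "iv_infusion": "iv_infusion",
    "oral": "oral",
    "ng": "nasogastric", "nasogastric": "nasogastric",
}
_ROUTE_OUT = {"iv_infusion": "iv", "oral": "oral", "nasogastric": "ng"}

_EVENT_COLS = ["ID", "TIME", "EVID", "AMT", "RATE", "DUR", "SS", "II",
               "ROUTE", "DV", "MDV", "OCC"]


class ParseError(ValueError):
    pass


def _num(row, col, default=np.nan):
    v = row.get(col, default)
    try:
        v = float(v)
    except (TypeError, ValueError):
        return np.nan
    return v


def read_dataset(path, default_infusion_duration: float = 1.0) -> EventDataset:
    """Read an event-record CSV into an :class:`EventDataset`.

    Raises :class:`ParseError` (with the offending 1-based data row number)
    for dose rows without a positive AMT, unknown route codes,
    non-monotone times within a subject, or a subject id appearing in
    non-contiguous blocks (duplicate id).
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else \
        pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.upper() for c in df.columns]
    if "ID" not in df or "TIME" not in df or "EVID" not in df:
        raise ParseError("file must have ID, TIME and EVID columns")
    cov_cols = [c for c in df.columns if c not in _EVENT_COLS]

    # duplicate-id check: each id must occupy one contiguous block
    ids = df["ID"].astype(str).to_numpy()
    block_starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    if len(set(ids[block_starts])) != len(block_starts):
        raise ParseError("duplicate subject id in non-contiguous blocks")

    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        rec = SubjectRecord(id=str(sid))
        last_time = -math.inf
        for idx, row in g.iterrows():
            rowno = idx + 1
            t = float(row["TIME"])
            if t < last_time:
                raise ParseError(
                    f"row {rowno}: non-monotone time for subject {sid}")
            last_time = t
            occ = int(_num(row, "OCC", 0)) if not math.isnan(_num(row, "OCC", 0)) else 0
            evid = int(row["EVID"])
            if evid == 1:
                amt = _num(row, "AMT")
                if math.isnan(amt) or amt <= 0:
                    raise ParseError(f"row {rowno}: dose row with missing/zero AMT")
                code = str(row.get("ROUTE", "iv")).strip().lower()
                if code in ("", "nan"):
                    code = "iv"
                if code not in _ROUTE_CODES:
                    raise ParseError(f"row {rowno}: unknown route code {code!r}")
                route = _ROUTE_CODES[code]
                dur = None
                if route == "iv_infusion":
                    dur = _num(row, "DUR")
                    if math.isnan(dur):
                        rate = _num(row, "RATE")
                        dur = amt / rate if rate and not math.isnan(rate) and rate > 0 \
                            else default_infusion_duration
                ss = int(_num(row, "SS", 0) or 0) == 1
                ii = _num(row, "II")
                rec.doses.append(DoseEvent(
                    time=t, amount=amt, route=route, duration=dur,
                    steady_state=ss, interval=None if math.isnan(ii) else ii,
                    occasion=occ,
                ))
            elif evid == 0:
                mdv = int(_num(row, "MDV", 0) or 0)
                if mdv == 1:
                    continue
                dv = _num(row, "DV")
                if math.isnan(dv):
                    raise ParseError(f"row {rowno}: observation with missing DV")
                rec.observations.append(ObservationEvent(
                    time=t, concentration=dv, occasion=occ))
            else:
                raise ParseError(f"row {rowno}: unsupported EVID {evid}")
            covs = {}
            for c in cov_cols:
                v = _num(row, c)
                if not math.isnan(v):
                    covs[c] = v
            if covs:
                prev = rec.covariates.get(occ)
                if prev is not None and any(
                        c in prev and prev[c] != v for c, v in covs.items()):
                    raise ParseError(
                        f"row {rowno}: conflicting covariates for subject "
                        f"{sid} occasion {occ}")
                rec.covariates.setdefault(occ, {}).update(covs)
        subjects.append(rec)
    return EventDataset(subjects=subjects, provenance={"source": str(path)})


def write_dataset(dataset: EventDataset, path) -> None:
    """Write an :class:`EventDataset` back to the CSV dialect (lossless)."""
    cov_names = sorted({c for s in dataset.subjects
                        for occ in s.covariates.values() for c in occ})
    rows = []
    for s in dataset.subjects:
        events = [("d", d.time, d) for d in s.doses] + \
                 [("o", o.time, o) for o in s.observations]
        events.sort(key=lambda e: (e[1], e[0]))  # dose before obs at a tie
        for kind, t, ev in events:
            row = {c: "" for c in _EVENT_COLS}
            row["ID"] = s.id
            row["TIME"] = t
            row["OCC"] = ev.occasion
            if kind == "d":
                row.update(EVID=1, AMT=ev.amount, ROUTE=_ROUTE_OUT[ev.route],
                           MDV=1, SS=int(ev.steady_state))
                if ev.duration is not None:
                    row["DUR"] = ev.duration
                if ev.interval is not None:
                    row["II"] = ev.interval
            else:
                row.update(EVID=0, DV=ev.concentration, MDV=0)
            covs = s.covariates.get(ev.occasion, s.covariates_at(ev.occasion)
                                    if s.covariates else {})
            for c in cov_names:
                if c in covs:
                    row[c] = covs[c]
            rows.append(row)
    pd.DataFrame(rows, columns=_EVENT_COLS + cov_names).to_csv(path, index=False)


@dataclass(frozen=True)
class Violation:
    level: str          # "error" | "warning"
    subject: str
    occasion: int | None
    message: str


def validate_dataset(dataset: EventDataset) -> list[Violation]:
    """Rule check on a dataset; returns a list of violations (empty = valid).

    Pure reporting: the dataset is never mutated.
    """
    out: list[Violation] = []
    seen = set()
    for s in dataset.subjects:
        if s.id in seen:
            out.append(Violation("error", s.id, None, "duplicate subject id"))
        seen.add(s.id)
        for ev in list(s.doses) + list(s.observations):
            if ev.time < 0:
                out.append(Violation("error", s.id, ev.occasion, "negative event time"))
        first_dose = min((d.time for d in s.doses), default=math.inf)
        for o in s.observations:
            if o.time < first_dose:
                out.append(Violation("warning", s.id, o.occasion,
                                     "observation before any dose"))
            if o.concentration < 0:
                out.append(Violation("error", s.id, o.occasion,
                                     "negative concentration"))
        for occ, covs in s.covariates.items():
            for flag in ("CRRT", "ECMO", "SEX"):
                v = covs.get(flag)
                if v is not None and v not in (0, 1):
                    out.append(Violation(
                        "error", s.id, occ,
                        f"{flag} must be 0/1 (got {v}) at occasion {occ}"))
            for name in ("QCRP", "CLCR", "PLT", "PT", "AGE", "WT"):
                v = covs.get(name)
                if v is not None and v <= 0:
                    out.append(Violation("error", s.id, occ,
                                         f"non-positive covariate {name}"))
        for occ in {o.occasion for o in s.observations}:
            try:
                s.covariates_at(occ)
            except KeyError:
                out.append(Violation("error", s.id, occ,
                                     "no covariates available for occasion"))
    return out


def cockcroft_gault(age: float, weight: float, scr_umol_l: float, sex) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min).

    ``scr_umol_l`` is serum creatinine in umol/L (converted internally to
    mg/dL with the 88.4 factor).  ``sex``: 0/"male" or 1/"female"; the
    female result is scaled by 0.85.
    """
    if age <= 0 or weight <= 0 or scr_umol_l <= 0:
        raise ValueError("age, weight and creatinine must be > 0")
    female = sex in (1, "female", "F", "f")
    if not female and sex not in (0, "male", "M", "m"):
        raise ValueError(f"unknown sex code {sex!r}")
    clcr = ((140.0 - age) * weight) / (72.0 * (scr_umol_l / 88.4))
    if female:
        clcr *= 0.85
    if clcr <= 0:
        raise ValueError("non-positive creatinine clearance (check age)")
    return clcr
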