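"""NONMEM-style event-record data model.

A subject's history is a sorted sequence of dose events and observation
events plus occasion-indexed covariate vectors.  Times are hours from the
subject's first record (no calendar dates); amounts mg; concentrations mg/L.

A dose event may carry a steady-state flag with an inter-dose interval, in
which case it represents an infinite train of identical doses ending at the
event time (the usual NONMEM ``SS=1`` semantics: prior history is
superseded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "DoseEvent",
    "ObservationEvent",
    "SubjectRecord",
    "EventDataset",
    "LLOQ",
    "ROUTES",
]

#: lower limit of quantification of the assay, mg/L
LLOQ = 0.097

ROUTES = ("iv_infusion", "oral", "nasogastric")


@dataclass(frozen=True)
class DoseEvent:
    time: float
    amount: float
    route: str = "iv_infusion"
    duration: float | None = 1.0   # h, IV only
    steady_state: bool = False
    interval: float | None = None  # h, required when steady_state
    occasion: int = 0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "iv_infusion":
            if self.duration is None or self.duration <= 0:
                raise ValueError("iv infusion requires duration > 0")
        else:
            object.__setattr__(self, "duration", None)
        if self.steady_state and (self.interval is None or self.interval <= 0):
            raise ValueError("steady-state dose requires interval > 0")


@dataclass(frozen=True)
class ObservationEvent:
    time: float
    concentration: float
    occasion: int = 0

    @property
    def blq(self) -> bool:
        """Below the assay's lower limit of quantification (0.097 mg/L)."""
        return self.concentration < LLOQ


@dataclass
class SubjectRecord:
    id: str
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[ObservationEvent] = field(default_factory=list)
    #: occasion index -> covariate name -> value
    covariates: dict[int, dict[str, float]] = field(default_factory=dict)

    def covariates_at(self, occasion: int) -> Mapping[str, float]:
        """Covariate vector for an occasion, carrying the last one forward."""
        if not self.covariates:
            raise KeyError(f"subject {self.id}: no covariates recorded")
        keys = sorted(k for k in self.covariates if k <= occasion)
        if not keys:
            keys = [min(self.covariates)]
        return self.covariates[keys[-1]]

    def sorted_times_ok(self) -> bool:
        times = [e.time for e in self.doses] + [o.time for o in self.observations]
        return all(t >= 0 for t in times)


@dataclass
class EventDataset:
    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in dataset")

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_blq(self) -> int:
        return sum(1 for s in self.subjects for o in s.observations if o.blq)

    def subject(self, sid: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def routes(self) -> set[str]:
        return {d.route for s in self.subjects for d in s.doses}

    @property
    def iv_only(self) -> bool:
        return self.routes <= {"iv_infusion"}
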