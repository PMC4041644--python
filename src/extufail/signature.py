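"""Temporal search signatures for extubation failure.

Extubation failure is the need for endotracheal reintubation within 72
hours of a prior extubation.  The detector expresses this as a declarative
rule ("signature") over a patient's normalized airway-event stream:

* ``initial``  — an extubation followed within the window by any
  intubation/insertion charting;
* ``final``    — the same, plus the requirement that the reintubation's
  "Airway Tube Type" be an endotracheal tube (which removes nasal-trumpet
  and tracheostomy insertions from the positives).

Both signatures restrict the paired events to the ICU and to a single
admission, mirroring the location restriction placed on intubations
charted in the operating room or emergency department.  The verdict is
patient-level: any qualifying event pair makes the patient positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import AirwayEvent, EventClass, PatientRecord, TubeType, normalize_events

logger = logging.getLogger(__name__)

#: hours in the failure window; the field's standard definition
DEFAULT_WINDOW_H = 72.0

Evidence = tuple[AirwayEvent, AirwayEvent, float]  # (extubation, reintubation, delta_h)


@dataclass(frozen=True)
class Signature:
    """A temporal detection rule over airway events.

    ``final`` differs from ``initial`` only by ``require_endotracheal=True``;
    it is a pure conjunctive restriction.
    """

    name: str
    window_h: float = DEFAULT_WINDOW_H
    require_endotracheal: bool = False
    icu_only: bool = True

    def __post_init__(self):
        if self.window_h <= 0:
            raise ValueError("window_h must be positive")

    @classmethod
    def initial(cls, window_h: float = DEFAULT_WINDOW_H, icu_only: bool = True) -> "Signature":
        return cls("initial", window_h=window_h, require_endotracheal=False, icu_only=icu_only)

    @classmethod
    def final(cls, window_h: float = DEFAULT_WINDOW_H, icu_only: bool = True) -> "Signature":
        return cls("final", window_h=window_h, require_endotracheal=True, icu_only=icu_only)

    @classmethod
    def by_name(cls, name: str, window_h: float = DEFAULT_WINDOW_H) -> "Signature":
        name = name.strip().lower()
        if name == "initial":
            return cls.initial(window_h=window_h)
        if name == "final":
            return cls.final(window_h=window_h)
        raise ValueError(f"unknown signature {name!r}; expected 'initial' or 'final'")


@dataclass(frozen=True)
class FailureCall:
    """Per-patient detector verdict with the qualifying evidence pair, if any."""

    patient_id: str
    admission_id: str
    positive: bool
    evidence: Optional[Evidence]
    signature_name: str


def hours_between(earlier, later) -> float:
    return (later - earlier).total_seconds() / 3600.0


def qualifying_pairs(events: Sequence[AirwayEvent], sig: Signature) -> list[Evidence]:
    """All (extubation, reintubation) pairs satisfying the signature.

    A reintubation pairs with the most recent prior extubation (no other
    extubation strictly between), with 0 < delta <= ``sig.window_h`` hours
    — simultaneous chartings never pair.  With ``icu_only`` both events
    must be ICU-located; with ``require_endotracheal`` the reintubation's
    tube type must be ENDOTRACHEAL.  Input must be time-sorted.
    """
    for a, b in zip(events, events[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError("qualifying_pairs requires a time-sorted event stream")

    considered = [
        ev for ev in events
        if ev.event_class in (EventClass.EXTUBATION, EventClass.INTUBATION)
        and (not sig.icu_only or ev.location == "ICU")
    ]
    pairs: list[Evidence] = []
    last_extubation: Optional[AirwayEvent] = None
    for ev in considered:
        if ev.event_class is EventClass.EXTUBATION:
            last_extubation = ev
            continue
        if last_extubation is None:
            continue
        delta_h = hours_between(last_extubation.timestamp, ev.timestamp)
        if not (0.0 < delta_h <= sig.window_h):
            continue
        if sig.require_endotracheal and ev.tube_type is not TubeType.ENDOTRACHEAL:
            continue
        pairs.append((last_extubation, ev, delta_h))
    pairs.sort(key=lambda p: (p[0].timestamp, p[1].timestamp))
    return pairs


def detect(
    record: PatientRecord, sig: Signature, assoc_window_min: float = 60.0
) -> FailureCall:
    """Classify one patient: positive iff any qualifying pair exists.

    Evidence is the first qualifying pair (earliest extubation).
    """
    events = normalize_events(record, assoc_window_min=assoc_window_min)
    pairs = qualifying_pairs(events, sig)
    return FailureCall(
        patient_id=record.patient_id,
        admission_id=record.admission_id,
        positive=bool(pairs),
        evidence=pairs[0] if pairs else None,
        signature_name=sig.name,
    )


def classify_cohort(
    records: Sequence[PatientRecord], sig: Signature, assoc_window_min: float = 60.0
) -> list[FailureCall]:
    """One verdict per record, order-preserving."""
    calls = [detect(rec, sig, assoc_window_min=assoc_window_min) for rec in records]
    n_pos = sum(c.positive for c in calls)
    logger.info(
        "signature %r: %d of %d patients positive", sig.name, n_pos, len(calls)
    )
    return calls


def evidence_satisfies(call: FailureCall, sig: Signature) -> bool:
    """Check a positive call's evidence against every active filter of ``sig``."""
    if not call.positive:
        return call.evidence is None
    if call.evidence is None:
        return False
    ext, reint, delta_h = call.evidence
    if ext.event_class is not EventClass.EXTUBATION:
        return False
    if reint.event_class is not EventClass.INTUBATION:
        return False
    if not (0.0 < delta_h <= sig.window_h):
        return False
    if abs(hours_between(ext.timestamp, reint.timestamp) - delta_h) > 1e-9:
        return False
    if sig.icu_only and (ext.location != "ICU" or reint.location != "ICU"):
        return False
    if sig.require_endotracheal and reint.tube_type is not TubeType.ENDOTRACHEAL:
        return False
    return ext.admission_id == reint.admission_id == call.admission_id
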