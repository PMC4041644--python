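"""Domain model for ICU flow-sheet charting data.

The raw material is the nurse-charted flow sheet: timestamped rows such as
"Airway Tube Status" (Intubated / Extubated / Inserted / ...) and
"Airway Tube Type" (Endotracheal tube / Tracheostomy / Nasal trumpet / ...).
This module turns those rows into normalized :class:`AirwayEvent` streams,
applies cohort eligibility rules (adults ventilated >= 48 h), and draws
reproducible random patient subsets.

Matching against the controlled vocabularies is case-insensitive and
whole-token: flow-sheet fields are picklist-like designations, so
"re-intubated" deliberately does not match "intubated".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Controlled vocabularies for the "Airway Tube Status" row.
EXTUBATION_TOKENS = frozenset({"extubation", "extubated"})
INTUBATION_TOKENS = frozenset({"intubation", "intubated", "inserted"})

STATUS_ROW = "airway tube status"
TUBE_TYPE_ROW = "airway tube type"

KNOWN_LOCATIONS = frozenset({"ICU", "ED", "OR", "PACU", "WARD", "OTHER"})

# Tokens keep internal hyphens so "re-intubated" is a single token that
# fails the whole-token match against "intubated".
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(value: str) -> list[str]:
    """Lower-case whole tokens of a charted value (hyphenated words stay whole)."""
    return _TOKEN_RE.findall(value.lower())


class EventClass(str, Enum):
    EXTUBATION = "EXTUBATION"
    INTUBATION = "INTUBATION"
    OTHER = "OTHER"


class TubeType(str, Enum):
    ENDOTRACHEAL = "ENDOTRACHEAL"
    TRACHEOSTOMY = "TRACHEOSTOMY"
    NASOTRACHEAL = "NASOTRACHEAL"
    NASAL_TRUMPET = "NASAL_TRUMPET"
    UNKNOWN = "UNKNOWN"


def normalize_location(raw: str) -> str:
    """Map a location string onto the controlled set; unknown -> OTHER with a warning."""
    loc = raw.strip().upper()
    if loc not in KNOWN_LOCATIONS:
        logger.warning("unknown location %r mapped to OTHER", raw)
        return "OTHER"
    return loc


def classify_status(value: str) -> EventClass:
    """Classify an "Airway Tube Status" value against the closed vocabularies."""
    tokens = set(tokenize(value))
    if tokens & EXTUBATION_TOKENS:
        return EventClass.EXTUBATION
    if tokens & INTUBATION_TOKENS:
        return EventClass.INTUBATION
    return EventClass.OTHER


def classify_tube_type(value: str) -> TubeType:
    """Classify an "Airway Tube Type" value; unrecognized values are UNKNOWN."""
    tokens = set(tokenize(value))
    if "endotracheal" in tokens:
        return TubeType.ENDOTRACHEAL
    if "tracheostomy" in tokens or "tracheotomy" in tokens:
        return TubeType.TRACHEOSTOMY
    if "nasotracheal" in tokens:
        return TubeType.NASOTRACHEAL
    if "trumpet" in tokens or "nasopharyngeal" in tokens:
        return TubeType.NASAL_TRUMPET
    return TubeType.UNKNOWN


@dataclass(frozen=True)
class FlowsheetEntry:
    """One raw charted flow-sheet row: who / when / which row / what value / where."""

    patient_id: str
    admission_id: str
    timestamp: datetime
    row_name: str
    value: str
    location: str

    @property
    def is_status_row(self) -> bool:
        return self.row_name.strip().lower() == STATUS_ROW

    @property
    def is_tube_type_row(self) -> bool:
        return self.row_name.strip().lower() == TUBE_TYPE_ROW


@dataclass(frozen=True)
class AirwayEvent:
    """A normalized airway event derived from a status row.

    ``source_row_index`` points back to the position of the originating
    entry in ``PatientRecord.entries`` (provenance).
    """

    patient_id: str
    admission_id: str
    timestamp: datetime
    event_class: EventClass
    tube_type: TubeType
    location: str
    source_row_index: int


@dataclass
class PatientRecord:
    """One patient-admission: metadata, charted entries, optional gold label.

    Metadata fields are ``None`` until a metadata file is attached; records
    with missing eligibility metadata are excluded by :func:`filter_cohort`.
    ``gold_label`` is the manual-review reference standard for extubation
    failure (endotracheal reintubation within 72 h of a prior extubation).
    """

    patient_id: str
    admission_id: str
    age_years: Optional[float] = None
    vent_duration_h: Optional[float] = None
    icu_interval: Optional[tuple[datetime, datetime]] = None
    entries: list[FlowsheetEntry] = field(default_factory=list)
    gold_label: Optional[bool] = None

    def copy_with(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


def normalize_events(
    record: PatientRecord, assoc_window_min: float = 60.0
) -> list[AirwayEvent]:
    """Normalize a patient's flow-sheet entries into a sorted airway-event stream.

    Every "Airway Tube Status" entry yields one event: EXTUBATION or
    INTUBATION when its value token-matches the controlled vocabularies,
    OTHER otherwise.  Each INTUBATION event is assigned the tube type of
    the "Airway Tube Type" entry charted at the identical timestamp, else
    the nearest such entry within ``assoc_window_min`` minutes (ties go to
    the earlier entry), else UNKNOWN.

    The output is sorted by timestamp, stable by source row order for
    same-timestamp events, so entry order within the input never matters.
    """
    tube_entries: list[tuple[int, FlowsheetEntry]] = [
        (i, e) for i, e in enumerate(record.entries) if e.is_tube_type_row
    ]

    def associate_tube_type(ts: datetime) -> TubeType:
        best_key: Optional[tuple] = None
        best_entry: Optional[FlowsheetEntry] = None
        for idx, entry in tube_entries:
            delta_min = abs((entry.timestamp - ts).total_seconds()) / 60.0
            if delta_min > assoc_window_min:
                continue
            # prefer smaller distance; on a tie the earlier-charted entry wins
            key = (delta_min, entry.timestamp, idx)
            if best_key is None or key < best_key:
                best_key, best_entry = key, entry
        if best_entry is None:
            return TubeType.UNKNOWN
        return classify_tube_type(best_entry.value)

    events: list[AirwayEvent] = []
    for idx, entry in enumerate(record.entries):
        if not entry.is_status_row:
            continue
        event_class = classify_status(entry.value)
        tube_type = TubeType.UNKNOWN
        if event_class is EventClass.INTUBATION:
            tube_type = associate_tube_type(entry.timestamp)
        events.append(
            AirwayEvent(
                patient_id=entry.patient_id,
                admission_id=entry.admission_id,
                timestamp=entry.timestamp,
                event_class=event_class,
                tube_type=tube_type,
                location=normalize_location(entry.location),
                source_row_index=idx,
            )
        )
    events.sort(key=lambda ev: (ev.timestamp, ev.source_row_index))
    return events


def filter_cohort(
    records: Sequence[PatientRecord],
    min_age: float = 18.0,
    min_vent_h: float = 48.0,
) -> list[PatientRecord]:
    """Apply the eligibility funnel: age >= ``min_age`` and ventilation >= ``min_vent_h``.

    Thresholds are inclusive.  Records with missing age or ventilation
    metadata are excluded conservatively, with a warning.
    """
    retained: list[PatientRecord] = []
    n_missing = n_age = n_vent = 0
    for rec in records:
        if rec.age_years is None or rec.vent_duration_h is None:
            logger.warning(
                "patient %s: missing eligibility metadata, excluded", rec.patient_id
            )
            n_missing += 1
            continue
        if rec.age_years < min_age:
            n_age += 1
            continue
        if rec.vent_duration_h < min_vent_h:
            n_vent += 1
            continue
        retained.append(rec)
    logger.info(
        "cohort funnel: %d in, %d excluded by age, %d excluded by ventilation, "
        "%d missing metadata, %d retained",
        len(records), n_age, n_vent, n_missing, len(retained),
    )
    return retained


def sample_subset(
    records: Sequence[PatientRecord], n: int = 100, seed: int = 0
) -> list[PatientRecord]:
    """Draw ``n`` patients uniformly without replacement; same seed, same subset."""
    if n > len(records):
        raise ValueError(
            f"cannot sample {n} patients from a population of {len(records)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in idx]
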