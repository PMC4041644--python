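from datetime import datetime, timedelta

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from extufail import (
    FlowsheetEntry,
    PatientRecord,
    fixture_derivation,
    fixture_validation,
)

T0 = datetime(2010, 3, 1, 8, 0)


def ts(hours: float) -> datetime:
    return T0 + timedelta(hours=hours)


def entry(
    hours: float,
    row_name: str = "Airway Tube Status",
    value: str = "Extubated",
    location: str = "ICU",
    pid: str = "P1",
) -> FlowsheetEntry:
    return FlowsheetEntry(
        patient_id=pid,
        admission_id=f"{pid}-A1",
        timestamp=ts(hours),
        row_name=row_name,
        value=value,
        location=location,
    )


def record(entries, pid: str = "P1", gold=None) -> PatientRecord:
    times = [e.timestamp for e in entries] or [T0]
    return PatientRecord(
        patient_id=pid,
        admission_id=f"{pid}-A1",
        age_years=60.0,
        vent_duration_h=96.0,
        icu_interval=(min(times) - timedelta(hours=1), max(times) + timedelta(hours=1)),
        entries=list(entries),
        gold_label=gold,
    )


@pytest.fixture(scope="session")
def derivation_cohort():
    return fixture_derivation()


@pytest.fixture(scope="session")
def validation_cohort():
    return fixture_validation()


@pytest.fixture(scope="session")
def derivation_gold(derivation_cohort):
    records, _ = derivation_cohort
    return {r.patient_id: r.gold_label for r in records}


@pytest.fixture(scope="session")
def validation_gold(validation_cohort):
    records, _ = validation_cohort
    return {r.patient_id: r.gold_label for r in records}
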