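"""CSV readers and writers for the flow-sheet and patient-metadata dialects.

Flow-sheet CSV: header ``patient_id,admission_id,timestamp,row_name,value,location``,
UTF-8, timestamps ``YYYY-MM-DDTHH:MM`` (minute resolution, one implicit
timezone).  Metadata CSV: ``patient_id,admission_id,age_years,vent_duration_h,
icu_start,icu_end,gold_label`` with ``gold_label`` in {0, 1, NA}.
"""

from __future__ import annotations

import csv
import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError, FlowsheetParseError
from .model import FlowsheetEntry, PatientRecord, normalize_location

logger = logging.getLogger(__name__)

FLOWSHEET_COLUMNS = [
    "patient_id", "admission_id", "timestamp", "row_name", "value", "location",
]
METADATA_COLUMNS = [
    "patient_id", "admission_id", "age_years", "vent_duration_h",
    "icu_start", "icu_end", "gold_label",
]
CALLS_COLUMNS = [
    "patient_id", "admission_id", "signature", "positive",
    "extubation_time", "reintubation_time", "delta_h", "tube_type",
]

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"


def _parse_timestamp(raw: str, row_number: int, path: Path) -> datetime:
    try:
        return datetime.strptime(raw.strip(), TIMESTAMP_FMT)
    except (ValueError, AttributeError) as exc:
        raise FlowsheetParseError(
            f"{path}: row {row_number}: malformed timestamp {raw!r} "
            f"(expected YYYY-MM-DDTHH:MM)"
        ) from exc


def read_flowsheet(path: str | Path) -> list[PatientRecord]:
    """Read a flow-sheet CSV into one :class:`PatientRecord` per patient-admission.

    Entries are kept verbatim in file order; metadata fields stay unset
    until :func:`attach_metadata` supplies them.  Malformed timestamps and
    missing columns raise :class:`FlowsheetParseError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FLOWSHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FlowsheetParseError(f"{path}: missing required column(s) {missing}")

    records: dict[tuple[str, str], PatientRecord] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        row_number = pos + 2  # 1-based, after the header line
        ts = _parse_timestamp(row.timestamp, row_number, path)
        entry = FlowsheetEntry(
            patient_id=row.patient_id,
            admission_id=row.admission_id,
            timestamp=ts,
            row_name=row.row_name,
            value=row.value,
            location=normalize_location(row.location),
        )
        key = (entry.patient_id, entry.admission_id)
        if key not in records:
            records[key] = PatientRecord(
                patient_id=entry.patient_id, admission_id=entry.admission_id
            )
        records[key].entries.append(entry)
    logger.info("%s: parsed %d rows into %d patient records", path, len(df), len(records))
    return list(records.values())


def write_flowsheet(records: Iterable[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FLOWSHEET_COLUMNS)
        for rec in records:
            for e in rec.entries:
                writer.writerow([
                    e.patient_id, e.admission_id,
                    e.timestamp.strftime(TIMESTAMP_FMT),
                    e.row_name, e.value, e.location,
                ])


def read_metadata(path: str | Path) -> dict[tuple[str, str], dict]:
    """Read the metadata CSV keyed by (patient_id, admission_id)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FlowsheetParseError(f"{path}: missing required column(s) {missing}")
    meta: dict[tuple[str, str], dict] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        row_number = pos + 2
        gold_raw = row.gold_label.strip().upper()
        if gold_raw in ("", "NA", "NAN"):
            gold = None
        elif gold_raw in ("0", "1"):
            gold = bool(int(gold_raw))
        else:
            raise FlowsheetParseError(
                f"{path}: row {row_number}: gold_label must be 0, 1 or NA, "
                f"got {row.gold_label!r}"
            )
        try:
            age = float(row.age_years) if row.age_years.strip() else None
            vent = float(row.vent_duration_h) if row.vent_duration_h.strip() else None
        except ValueError as exc:
            raise FlowsheetParseError(
                f"{path}: row {row_number}: non-numeric age or ventilation duration"
            ) from exc
        meta[(row.patient_id, row.admission_id)] = {
            "age_years": age,
            "vent_duration_h": vent,
            "icu_interval": (
                _parse_timestamp(row.icu_start, row_number, path),
                _parse_timestamp(row.icu_end, row_number, path),
            ),
            "gold_label": gold,
        }
    return meta


def attach_metadata(
    records: Sequence[PatientRecord], meta: dict[tuple[str, str], dict]
) -> list[PatientRecord]:
    """Return records with metadata fields filled in where available."""
    out = []
    for rec in records:
        m = meta.get((rec.patient_id, rec.admission_id))
        if m is None:
            logger.warning(
                "patient %s/%s: no metadata row", rec.patient_id, rec.admission_id
            )
            out.append(rec)
        else:
            out.append(rec.copy_with(**m))
    return out


def load_cohort(
    flowsheet_path: str | Path, metadata_path: str | Path
) -> list[PatientRecord]:
    """Read flow-sheet and metadata CSVs and join them into patient records."""
    return attach_metadata(read_flowsheet(flowsheet_path), read_metadata(metadata_path))


def write_metadata(records: Iterable[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for rec in records:
            if rec.icu_interval is None:
                raise DataError(
                    f"patient {rec.patient_id}: cannot write metadata without ICU interval"
                )
            writer.writerow([
                rec.patient_id, rec.admission_id,
                "" if rec.age_years is None else f"{rec.age_years:g}",
                "" if rec.vent_duration_h is None else f"{rec.vent_duration_h:g}",
                rec.icu_interval[0].strftime(TIMESTAMP_FMT),
                rec.icu_interval[1].strftime(TIMESTAMP_FMT),
                "NA" if rec.gold_label is None else int(rec.gold_label),
            ])


def write_calls(calls, path: str | Path) -> None:
    """Write detector verdicts (``FailureCall``) to the calls CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALLS_COLUMNS)
        for call in calls:
            if call.evidence is not None:
                ext, reint, delta_h = call.evidence
                ev = [
                    ext.timestamp.strftime(TIMESTAMP_FMT),
                    reint.timestamp.strftime(TIMESTAMP_FMT),
                    f"{delta_h:.3f}",
                    reint.tube_type.value,
                ]
            else:
                ev = ["", "", "", ""]
            writer.writerow([
                call.patient_id, call.admission_id, call.signature_name,
                int(call.positive), *ev,
            ])


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls CSV back as a DataFrame (positive as bool)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CALLS_COLUMNS if c not in df.columns]
    if missing:
        raise FlowsheetParseError(f"{path}: missing required column(s) {missing}")
    df["positive"] = df["positive"].astype(int).astype(bool)
    return df
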