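"""Flow-sheet parsing, event normalization and cohort filtering."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extufail import (
    CohortConfig,
    EventClass,
    FlowsheetParseError,
    PatientRecord,
    TubeType,
    filter_cohort,
    generate_cohort,
    load_cohort,
    normalize_events,
    read_flowsheet,
    sample_subset,
    write_flowsheet,
    write_metadata,
)

from conftest import entry, record


class TestReadFlowsheet:
    def test_single_patient_three_rows(self, tmp_path):
        p = tmp_path / "fs.csv"
        p.write_text(
            "patient_id,admission_id,timestamp,row_name,value,location\n"
            "P1,A1,2010-03-01T08:00,Airway Tube Status,Intubated,ICU\n"
            "P1,A1,2010-03-03T09:30,Airway Tube Status,Extubated,ICU\n"
            "P1,A1,2010-03-04T10:00,Airway Tube Status,Intubated,ICU\n"
        )
        records = read_flowsheet(p)
        assert len(records) == 1
        assert len(records[0].entries) == 3
        assert records[0].patient_id == "P1"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "fs.csv"
        p.write_text("patient_id,admission_id,timestamp,row_name,value,location\n")
        assert read_flowsheet(p) == []

    def test_malformed_timestamp_names_row(self, tmp_path):
        p = tmp_path / "fs.csv"
        p.write_text(
            "patient_id,admission_id,timestamp,row_name,value,location\n"
            "P1,A1,2010-03-01T08:00,Airway Tube Status,Intubated,ICU\n"
            "P1,A1,not-a-time,Airway Tube Status,Extubated,ICU\n"
        )
        with pytest.raises(FlowsheetParseError, match="row 3"):
            read_flowsheet(p)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "fs.csv"
        p.write_text("patient_id,timestamp,row_name,value\nP1,2010-03-01T08:00,x,y\n")
        with pytest.raises(FlowsheetParseError, match="missing required column"):
            read_flowsheet(p)

    def test_unknown_location_maps_to_other(self, tmp_path, caplog):
        p = tmp_path / "fs.csv"
        p.write_text(
            "patient_id,admission_id,timestamp,row_name,value,location\n"
            "P1,A1,2010-03-01T08:00,Airway Tube Status,Intubated,HELIPAD\n"
        )
        with caplog.at_level(logging.WARNING):
            records = read_flowsheet(p)
        assert records[0].entries[0].location == "OTHER"
        assert any("HELIPAD" in m for m in caplog.messages)

    def test_roundtrip_reproduces_records(self, tmp_path, derivation_cohort):
        """Write-then-read of a full cohort reproduces every field."""
        records, _ = derivation_cohort
        fs, meta = tmp_path / "fs.csv", tmp_path / "meta.csv"
        write_flowsheet(records, fs)
        write_metadata(records, meta)
        back = load_cohort(fs, meta)
        assert len(back) == len(records)
        by_id = {r.patient_id: r for r in back}
        for orig in records:
            got = by_id[orig.patient_id]
            assert got == orig


class TestNormalizeEvents:
    @pytest.mark.parametrize(
        "value, expected",
        [
            ("Extubated", EventClass.EXTUBATION),
            ("extubation", EventClass.EXTUBATION),
            ("Intubated", EventClass.INTUBATION),
            ("INSERTED", EventClass.INTUBATION),
            ("Removed", EventClass.OTHER),
            ("re-intubated", EventClass.OTHER),  # whole-token, not substring
            ("patient was extubated today", EventClass.EXTUBATION),
        ],
    )
    def test_status_vocabulary(self, value, expected):
        rec = record([entry(0, value=value)])
        (ev,) = normalize_events(rec)
        assert ev.event_class is expected

    def test_tube_type_exact_timestamp(self):
        rec = record([
            entry(2, value="Inserted"),
            entry(2, row_name="Airway Tube Type", value="Nasal trumpet"),
        ])
        (ev,) = normalize_events(rec)
        assert ev.event_class is EventClass.INTUBATION
        assert ev.tube_type is TubeType.NASAL_TRUMPET

    def test_tube_type_absent_within_window_is_unknown(self):
        rec = record([
            entry(2, value="Inserted"),
            entry(4, row_name="Airway Tube Type", value="Endotracheal tube"),
        ])
        (ev,) = normalize_events(rec)
        assert ev.tube_type is TubeType.UNKNOWN

    def test_tube_type_nearest_within_window(self):
        rec = record([
            entry(2, value="Intubated"),
            entry(2.75, row_name="Airway Tube Type", value="Tracheostomy"),
            entry(2.25, row_name="Airway Tube Type", value="Endotracheal tube"),
        ])
        (ev,) = normalize_events(rec)
        assert ev.tube_type is TubeType.ENDOTRACHEAL

    def test_tube_type_tie_goes_to_earlier_entry(self):
        rec = record([
            entry(2, value="Intubated"),
            entry(1.5, row_name="Airway Tube Type", value="Nasotracheal tube"),
            entry(2.5, row_name="Airway Tube Type", value="Tracheostomy"),
        ])
        (ev,) = normalize_events(rec)
        assert ev.tube_type is TubeType.NASOTRACHEAL

    def test_event_count_matches_vocabulary_matches(self):
        values = ["Intubated", "Removed", "Extubated", "Suctioned", "Inserted"]
        rec = record([entry(i, value=v) for i, v in enumerate(values)])
        events = normalize_events(rec)
        matched = [
            e for e in events
            if e.event_class in (EventClass.EXTUBATION, EventClass.INTUBATION)
        ]
        assert len(events) == len(values)
        assert len(matched) == 3

    @given(perm=st.permutations(list(range(6))))
    @settings(max_examples=40, deadline=None)
    def test_entry_order_is_irrelevant(self, perm):
        """Shuffling charting order never changes the normalized stream."""
        base = [
            entry(0, value="Intubated"),
            entry(0, row_name="Airway Tube Type", value="Endotracheal tube"),
            entry(50, value="Extubated"),
            entry(60, value="Inserted"),
            entry(60, row_name="Airway Tube Type", value="Nasal trumpet"),
            entry(70, value="Suctioned"),
        ]
        reference = normalize_events(record(base))
        shuffled = normalize_events(record([base[i] for i in perm]))
        key = lambda e: (e.timestamp, e.event_class, e.tube_type, e.location)
        assert [key(e) for e in shuffled] == [key(e) for e in reference]


class TestFilterCohort:
    @pytest.mark.parametrize(
        "age, vent, kept",
        [
            (17.9, 100.0, False),
            (18.0, 48.0, True),   # thresholds are inclusive
            (18.0, 47.9, False),
            (90.0, 48.1, True),
        ],
    )
    def test_eligibility_boundaries(self, age, vent, kept):
        rec = record([entry(0)]).copy_with(age_years=age, vent_duration_h=vent)
        assert (filter_cohort([rec]) == [rec]) is kept

    def test_missing_metadata_excluded_with_warning(self, caplog):
        rec = PatientRecord(patient_id="P9", admission_id="P9-A1")
        with caplog.at_level(logging.WARNING):
            assert filter_cohort([rec]) == []
        assert any("missing eligibility metadata" in m for m in caplog.messages)

    def test_planted_ineligible_patients_are_removed(self):
        config = CohortConfig(n_patients=40, seed=11, n_ineligible=10)
        records, _ = generate_cohort(config)
        assert len(records) == 50
        assert len(filter_cohort(records)) == 40


class TestSampleSubset:
    def _population(self, n):
        return [record([entry(0)], pid=f"P{i}") for i in range(n)]

    def test_full_population_sample(self):
        pop = self._population(7)
        sub = sample_subset(pop, n=7, seed=3)
        assert sorted(r.patient_id for r in sub) == sorted(r.patient_id for r in pop)

    def test_same_seed_same_subset(self):
        pop = self._population(200)
        a = sample_subset(pop, n=100, seed=42)
        b = sample_subset(pop, n=100, seed=42)
        assert [r.patient_id for r in a] == [r.patient_id for r in b]

    def test_different_seeds_differ(self):
        pop = self._population(978)
        a = sample_subset(pop, n=100, seed=1)
        b = sample_subset(pop, n=100, seed=2)
        assert {r.patient_id for r in a} != {r.patient_id for r in b}

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            sample_subset(self._population(5), n=6, seed=0)
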