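"""Synthetic flow-sheet cohorts with known gold labels.

No de-identified charting data accompanies studies of this kind, so the
package ships a generator that emulates the event structure a nurse-charted
airway flow sheet actually exhibits, together with the documented
misclassification modes of rule-based extubation-failure detection:

* ``TRUE_FAILURE``            — endotracheal reintubation within 72 h (gold +)
* ``MISCODED_STATUS``         — a real failure whose extubation was charted
  with a non-matching status token, so the detector sees no extubation (gold +)
* ``NO_REINTUBATION``         — extubated, never reintubated (gold −)
* ``LATE_REINTUBATION``       — reintubated after the 72 h window (gold −)
* ``NASAL_TRUMPET``           — nasopharyngeal airway "Inserted" after
  extubation; flags the initial signature, excluded by the final one (gold −)
* ``TRACHEOSTOMY``            — tracheostomy inserted after extubation;
  same false-positive/exclusion structure as the nasal trumpet (gold −)
* ``ACCIDENTAL_EXTUBATION``   — accidental extubation with prompt
  endotracheal reintubation; a genuine reintubation the manual reviewers do
  not count as extubation failure, so it is a *final-signature* FP (gold −)
* ``PROCEDURAL_REINTUBATION`` — brief (<2 h) reintubation for a procedure
  with re-extubation; likewise a final-signature FP (gold −)
* ``OR_INTUBATION_ONLY``      — post-extubation intubation charted in the
  operating room; the location restriction excludes it (gold −)

Two deterministic 100-patient fixtures mirror the derivation and
validation subsets of a typical accuracy study: the derivation fixture
carries 14 gold positives (prevalence 0.14) with 4 nasal-trumpet false
positives and 2 miscoded misses; the validation fixture carries 16 gold
positives with 4 false positives (2 accidental, 2 procedural) and 1
miscoded miss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .model import FlowsheetEntry, PatientRecord

logger = logging.getLogger(__name__)


class Scenario(str, Enum):
    TRUE_FAILURE = "TRUE_FAILURE"
    LATE_REINTUBATION = "LATE_REINTUBATION"
    NO_REINTUBATION = "NO_REINTUBATION"
    NASAL_TRUMPET = "NASAL_TRUMPET"
    ACCIDENTAL_EXTUBATION = "ACCIDENTAL_EXTUBATION"
    PROCEDURAL_REINTUBATION = "PROCEDURAL_REINTUBATION"
    MISCODED_STATUS = "MISCODED_STATUS"
    OR_INTUBATION_ONLY = "OR_INTUBATION_ONLY"
    TRACHEOSTOMY = "TRACHEOSTOMY"


#: scenarios whose patients truly experienced extubation failure
GOLD_POSITIVE_SCENARIOS = frozenset({Scenario.TRUE_FAILURE, Scenario.MISCODED_STATUS})

#: gold-negative scenarios that the final signature still flags, by design
FINAL_FP_SCENARIOS = frozenset(
    {Scenario.ACCIDENTAL_EXTUBATION, Scenario.PROCEDURAL_REINTUBATION}
)

# status token used for a miscoded extubation: a plausible picklist value
# that fails the {extubation, extubated} whole-token match
MISCODED_EXTUBATION_VALUE = "Removed"

_EPOCH = datetime(2008, 1, 1, 0, 0)

# delay bounds in hours, per scenario convention
FAILURE_DELAY_H = (1.0, 72.0)
LATE_DELAY_H = (73.0, 120.0)
ACCIDENTAL_REINTUBATION_DELAY_H = (0.1, 1.0)
PROCEDURAL_DURATION_H = (0.5, 2.0)


def gold_label_for(scenario: Scenario) -> bool:
    return scenario in GOLD_POSITIVE_SCENARIOS


@dataclass
class CohortConfig:
    """Generator configuration: cohort size, prevalence and scenario mix.

    ``mix`` maps scenario names to sampling proportions (must sum to 1);
    each patient's scenario is drawn i.i.d. from it.  ``prevalence`` must
    equal the total gold-positive scenario mass.  ``n_ineligible`` patients
    violating the age/ventilation eligibility rules are appended for
    funnel demonstrations.
    """

    n_patients: int = 100
    prevalence: float = 0.14
    mix: dict[Scenario, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    seed: int = 0
    n_ineligible: int = 0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_ineligible < 0:
            raise ConfigError("cohort sizes must be non-negative")
        self.mix = {Scenario(k): float(v) for k, v in self.mix.items()}
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"scenario mix proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.mix.values()):
            raise ConfigError("scenario mix proportions must be non-negative")
        gold_mass = sum(
            v for k, v in self.mix.items() if k in GOLD_POSITIVE_SCENARIOS
        )
        if abs(gold_mass - self.prevalence) > 1e-9:
            raise ConfigError(
                f"prevalence {self.prevalence} inconsistent with gold-positive "
                f"scenario mass {gold_mass}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a YAML or JSON config mirroring the dataclass fields."""
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        allowed = {"n_patients", "prevalence", "mix", "seed", "n_ineligible"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"{path}: unknown config field(s) {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc


#: default mix mirroring the derivation-subset structure (prevalence 0.14)
DEFAULT_MIX: dict[Scenario, float] = {
    Scenario.TRUE_FAILURE: 0.12,
    Scenario.MISCODED_STATUS: 0.02,
    Scenario.NASAL_TRUMPET: 0.04,
    Scenario.LATE_REINTUBATION: 0.10,
    Scenario.NO_REINTUBATION: 0.64,
    Scenario.ACCIDENTAL_EXTUBATION: 0.02,
    Scenario.PROCEDURAL_REINTUBATION: 0.02,
    Scenario.OR_INTUBATION_ONLY: 0.02,
    Scenario.TRACHEOSTOMY: 0.02,
}

#: a mix of unambiguous scenarios only, for calibration runs
CLEAN_MIX: dict[Scenario, float] = {
    Scenario.TRUE_FAILURE: 0.14,
    Scenario.NO_REINTUBATION: 0.66,
    Scenario.LATE_REINTUBATION: 0.20,
}


def _minute(ts: datetime) -> datetime:
    return ts.replace(second=0, microsecond=0)


def _chart(
    pid: str, aid: str, ts: datetime, row: str, value: str, loc: str = "ICU"
) -> FlowsheetEntry:
    return FlowsheetEntry(
        patient_id=pid, admission_id=aid, timestamp=_minute(ts),
        row_name=row, value=value, location=loc,
    )


def _build_patient(
    pid: str,
    scenario: Scenario,
    rng: np.random.Generator,
    eligible: bool = True,
) -> tuple[PatientRecord, dict]:
    """Chart one synthetic patient-admission under the given scenario."""
    aid = f"{pid}-A1"
    admit = _EPOCH + timedelta(hours=float(rng.uniform(0, 24 * 365 * 4)))
    admit = _minute(admit)
    intub = _minute(admit + timedelta(hours=float(rng.uniform(1, 6))))

    if eligible:
        age = float(rng.uniform(18, 90))
        vent_h = float(rng.uniform(48, 240))
    else:
        # violate one of the two eligibility rules at random
        if rng.random() < 0.5:
            age = float(rng.uniform(14, 17.5))
            vent_h = float(rng.uniform(48, 240))
        else:
            age = float(rng.uniform(18, 90))
            vent_h = float(rng.uniform(4, 47.5))

    # charting is minute-resolution; anchor delays on the charted extubation
    # time so a delay <= 72 h can never round past the window
    extub = _minute(intub + timedelta(hours=vent_h))
    entries: list[FlowsheetEntry] = [
        _chart(pid, aid, intub, "Airway Tube Status", "Intubated"),
        _chart(pid, aid, intub, "Airway Tube Type", "Endotracheal tube"),
    ]
    extubation_value = (
        MISCODED_EXTUBATION_VALUE
        if scenario is Scenario.MISCODED_STATUS
        else "Extubated"
    )
    entries.append(_chart(pid, aid, extub, "Airway Tube Status", extubation_value))

    manifest: dict = {
        "patient_id": pid,
        "scenario": scenario.value,
        "gold_label": gold_label_for(scenario),
        "eligible": eligible,
        "extubation_time": _minute(extub).isoformat(timespec="minutes"),
    }
    last = extub

    def reintubate(delay_h: float, tube: str, status: str = "Intubated", loc: str = "ICU"):
        nonlocal last
        t = extub + timedelta(hours=delay_h)
        entries.append(_chart(pid, aid, t, "Airway Tube Status", status, loc))
        entries.append(_chart(pid, aid, t, "Airway Tube Type", tube, loc))
        manifest["reintubation_time"] = _minute(t).isoformat(timespec="minutes")
        manifest["reintubation_delay_h"] = round(delay_h, 3)
        last = t
        return t

    if scenario in (Scenario.TRUE_FAILURE, Scenario.MISCODED_STATUS):
        reintubate(float(rng.uniform(*FAILURE_DELAY_H)), "Endotracheal tube")
    elif scenario is Scenario.LATE_REINTUBATION:
        reintubate(float(rng.uniform(*LATE_DELAY_H)), "Endotracheal tube")
    elif scenario is Scenario.NASAL_TRUMPET:
        reintubate(
            float(rng.uniform(*FAILURE_DELAY_H)), "Nasal trumpet", status="Inserted"
        )
    elif scenario is Scenario.TRACHEOSTOMY:
        reintubate(
            float(rng.uniform(*FAILURE_DELAY_H)), "Tracheostomy", status="Inserted"
        )
    elif scenario is Scenario.ACCIDENTAL_EXTUBATION:
        # the charted extubation was accidental; prompt reintubation follows
        reintubate(
            float(rng.uniform(*ACCIDENTAL_REINTUBATION_DELAY_H)), "Endotracheal tube"
        )
    elif scenario is Scenario.PROCEDURAL_REINTUBATION:
        t = reintubate(float(rng.uniform(*FAILURE_DELAY_H)), "Endotracheal tube")
        reext = t + timedelta(hours=float(rng.uniform(*PROCEDURAL_DURATION_H)))
        entries.append(_chart(pid, aid, reext, "Airway Tube Status", "Extubated"))
        last = reext
    elif scenario is Scenario.OR_INTUBATION_ONLY:
        reintubate(
            float(rng.uniform(*FAILURE_DELAY_H)), "Endotracheal tube", loc="OR"
        )
    # NO_REINTUBATION: nothing after the extubation

    icu_end = _minute(last + timedelta(hours=12))
    record = PatientRecord(
        patient_id=pid,
        admission_id=aid,
        age_years=round(age, 1),
        vent_duration_h=round(vent_h, 1),
        icu_interval=(admit, icu_end),
        entries=entries,
        gold_label=gold_label_for(scenario),
    )
    return record, manifest


def _build_cohort(
    scenarios: Sequence[Scenario],
    seed: int,
    prefix: str = "P",
    n_ineligible: int = 0,
    shuffle: bool = True,
) -> tuple[list[PatientRecord], list[dict]]:
    rng = np.random.default_rng(seed)
    plan: list[tuple[Scenario, bool]] = [(s, True) for s in scenarios]
    plan += [
        (Scenario(str(rng.choice([s.value for s in Scenario]))), False)
        for _ in range(n_ineligible)
    ]
    if shuffle:
        order = rng.permutation(len(plan))
        plan = [plan[i] for i in order]
    records, manifest = [], []
    width = max(3, len(str(len(plan))))
    for i, (scenario, eligible) in enumerate(plan, start=1):
        pid = f"{prefix}{i:0{width}d}"
        rec, man = _build_patient(pid, scenario, rng, eligible=eligible)
        records.append(rec)
        manifest.append(man)
    return records, manifest


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[dict]]:
    """Generate a labeled cohort; identical config (incl. seed) gives identical output.

    Returns the records and a manifest listing each patient's planted
    scenario, gold label and event times.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.mix, key=lambda s: s.value)
    probs = np.array([config.mix[s] for s in names])
    draws = rng.choice(len(names), size=config.n_patients, p=probs / probs.sum())
    scenarios = [names[i] for i in draws]
    # derive the per-patient stream seed from the config seed (kept < 2**31)
    records, manifest = _build_cohort(
        scenarios,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_ineligible=config.n_ineligible,
        shuffle=False,
    )
    counts = {s.value: scenarios.count(s) for s in names}
    logger.info(
        "generated cohort of %d (+%d ineligible): %s",
        config.n_patients, config.n_ineligible, counts,
    )
    return records, manifest


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


_DERIVATION_SEED = 20020101
_VALIDATION_SEED = 20111231


def fixture_derivation() -> tuple[list[PatientRecord], list[dict]]:
    """Deterministic 100-patient cohort mirroring a derivation subset.

    14 gold positives (12 cleanly detectable failures + 2 miscoded misses),
    4 nasal-trumpet insertions that only the initial signature flags, and
    82 clean negatives.  Against gold, the initial signature scores
    (TP=12, FP=4, FN=2, TN=82); the final signature removes all 4 false
    positives.
    """
    scenarios = (
        [Scenario.TRUE_FAILURE] * 12
        + [Scenario.MISCODED_STATUS] * 2
        + [Scenario.NASAL_TRUMPET] * 4
        + [Scenario.NO_REINTUBATION] * 41
        + [Scenario.LATE_REINTUBATION] * 41
    )
    return _build_cohort(scenarios, seed=_DERIVATION_SEED, prefix="D")


def fixture_validation() -> tuple[list[PatientRecord], list[dict]]:
    """Deterministic 100-patient cohort mirroring a validation subset.

    16 gold positives (15 cleanly detectable + 1 miscoded miss), plus 2
    accidental extubations and 2 brief procedural reintubations that the
    final signature flags but manual review does not count.  The final
    signature therefore disagrees with gold for exactly 5 patients
    (4 false positives, 1 false negative).
    """
    scenarios = (
        [Scenario.TRUE_FAILURE] * 15
        + [Scenario.MISCODED_STATUS] * 1
        + [Scenario.ACCIDENTAL_EXTUBATION] * 2
        + [Scenario.PROCEDURAL_REINTUBATION] * 2
        + [Scenario.NO_REINTUBATION] * 60
        + [Scenario.LATE_REINTUBATION] * 20
    )
    return _build_cohort(scenarios, seed=_VALIDATION_SEED, prefix="V")
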