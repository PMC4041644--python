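# extufail

Rule-based detection of **extubation failure** — the need for endotracheal
reintubation within 72 hours of a prior extubation — from ICU flow-sheet
event streams, together with the machinery to validate such a detector
against manual chart review.

## Who this is for

Identifying reintubation episodes is the necessary first step before
studying their predictors and consequences, but the evidence is buried in
nurse-charted flow-sheet rows ("Airway Tube Status", "Airway Tube Type")
rather than in any single structured field. `extufail` implements a
computable phenotype for extubation failure as a declarative *temporal
signature* over those rows, and reports the diagnostic accuracy of the
signature against per-patient gold labels the way clinical validation
studies print it: sensitivity, specificity, PPV, NPV and prevalence from
the patient-level 2×2 table, each with a 95% confidence interval.

Because charting data of this kind is never publicly deposited, the package
also ships a synthetic flow-sheet generator whose scenario catalog plants
the documented real-world error modes — nasal-trumpet insertions after
extubation, accidental extubations with prompt reintubation, brief
procedural reintubations, miscoded status values, intubations charted in
the OR — so detector behavior under each confounder is known by
construction.

## The detector

A patient's charted rows are normalized into airway events by
case-insensitive whole-token matching against closed vocabularies
({extubation, extubated} and {intubation, intubated, inserted}), with each
intubation event assigned the tube type charted at the same time (or the
nearest within ±60 min). Two signatures classify a patient-admission:

* **initial** — some extubation is followed within 72 h by an
  intubation/insertion charting, both events ICU-located, same admission;
* **final** — the same, **and** the reintubation's "Airway Tube Type" is an
  endotracheal tube (excluding nasal trumpets, tracheostomies and
  nasotracheal tubes).

A reintubation pairs with the most recent prior extubation; simultaneous
chartings never pair; the 72 h bound is inclusive. The verdict is
patient-level: any qualifying pair makes the patient positive.

For a metric with k successes in n trials, intervals default to the Wilson
score interval **with continuity correction** at z = 1.96 — the method
behind the classic online clinical calculators, whose integer-percent
endpoints match how such studies print their CIs. The Clopper–Pearson
exact interval is available with `--method clopper_pearson`.

## Worked example

Generate the packaged 100-patient derivation-like cohort, run the initial
signature, and validate it against the gold labels:

```bash
extufail simulate --fixture derivation --out cohort
extufail detect --flowsheet cohort/flowsheet.csv --meta cohort/metadata.csv \
                --signature initial --out calls_initial.csv
extufail validate --calls calls_initial.csv --meta cohort/metadata.csv \
                  --out report_initial.json
```

which prints:

```
100 patients written to cohort (gold-positive 14, prevalence 0.14)
scenario counts: {"LATE_REINTUBATION": 41, "MISCODED_STATUS": 2, "NASAL_TRUMPET": 4, "NO_REINTUBATION": 41, "TRUE_FAILURE": 12}
100 patients read, 100 eligible, 16 positive under the initial signature -> calls_initial.csv
signature: initial
counts: TP=12 FP=4 FN=2 TN=82
metric       value (95% CI)
sensitivity  86% (56%-97%)
specificity  95% (88%-98%)
PPV          75% (47%-92%)
NPV          98% (91%-100%)
prevalence   0.14
```

Reading the output: of the 14 patients who truly failed extubation, the
initial signature finds 12 (the 2 misses are patients whose extubation was
charted with a status token outside the controlled vocabulary), and it
falsely flags the 4 patients whose post-extubation "Inserted" charting was
a nasal trumpet. Rerunning `detect` with `--signature final` removes all
4 false positives (FP=0, specificity 100%) because the final signature
additionally requires an endotracheal tube type.

A standalone interval calculator is also exposed:

```bash
$ extufail ci --successes 12 --trials 14
12/14: 0.8571 (0.5615-0.9749) at 95% [wilson_cc] — renders 86% (56%-97%)
```

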