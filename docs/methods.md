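# Methods

## The detection model

A patient-admission is represented as a stream of timestamped flow-sheet
entries. Only two row names carry airway information: "Airway Tube Status"
(the nurse's charting of intubation/extubation state) and "Airway Tube
Type" (the device in place). Status values are matched case-insensitively
as whole tokens against closed vocabularies — {extubation, extubated} and
{intubation, intubated, inserted}. Whole-token (not substring) matching is
deliberate: flow-sheet fields are picklist-like designations, so a value
such as "re-intubated" is treated as a distinct token and does **not**
match "intubated". Values outside both vocabularies become OTHER events
and can never trigger a detection; this is also the mechanism by which a
miscoded extubation produces a false negative.

Each intubation event is assigned a tube type by association: the
"Airway Tube Type" entry charted at the identical timestamp wins; failing
that, the nearest such entry within ±60 minutes (ties to the
earlier-charted entry); failing that, UNKNOWN. The association window is
a convention — charting practice does not guarantee that status and type
rows share a timestamp, but they are charted together closely in practice;
60 minutes is wide enough to absorb charting skew and narrow enough not to
bridge distinct airway episodes (episode delays in the generator are ≥ 6
minutes for accidental reintubations and typically hours).

Detection is a sweep over the time-sorted event stream. A reintubation
pairs with the most recent prior extubation (no other extubation strictly
between), with delta strictly positive and at most the window (default
72 h, inclusive — "within 72 hours" read literally; simultaneous chartings
never pair). With `icu_only` (default) both events must be ICU-located,
which implements the restriction against counting intubations performed in
the operating room or emergency department; same-admission is enforced by
construction since a record holds one admission. The *final* signature
adds one conjunct: the reintubation's tube type must be ENDOTRACHEAL.
The verdict is per patient — any qualifying pair makes the patient
positive, and the reported evidence is the earliest qualifying pair.

Because the final signature is a pure restriction of the initial one,
final-positive ⇒ initial-positive on every input; the test suite checks
this as an invariant alongside agreement with an exhaustive
pair-enumeration oracle on random streams.

## Eligibility and sampling

Cohort eligibility follows the usual ICU-study funnel: age ≥ 18 years and
mechanical ventilation ≥ 48 h during the ICU admission, both thresholds
inclusive. Ventilation duration is supplied as metadata rather than
inferred from ventilator-setting rows — ventilator parameters can be
present for noninvasive ventilation and tracheostomy support, so no
reliable inference rule exists at the flow-sheet level. Records missing
either metadatum are excluded conservatively, with a warning. Subset
sampling (`sample_subset`) is uniform without replacement under an
explicit seed.

## Accuracy statistics

Detector calls are cross-tabulated against per-patient gold labels (the
manual-review surrogate) into a 2×2 table; patients without a label are
dropped from accuracy computation (but not from detection). Sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN) and
prevalence (TP+FN)/n are each reported as a binomial proportion with a
95% interval. A metric whose denominator is zero is reported absent rather
than coerced to 0 or raised as an error.

The default interval is the Wilson score interval **with continuity
correction**:

    lower = max(0, [2np̂ + z² − 1 − z√(z² − 2 − 1/n + 4p̂(n(1−p̂)+1))] / (2(n+z²)))
    upper = min(1, [2np̂ + z² + 1 + z√(z² + 2 − 1/n + 4p̂(n(1−p̂)−1))] / (2(n+z²)))

with the conventional caps at k=0 (lower = 0) and k=n (upper = 1). z is
pinned at 1.96 for the 95% level — the value used by the classic online
clinical calculators whose output this rendering mirrors — and taken from
the exact normal quantile at other levels; the 1.96-vs-1.959964 difference
never survives integer-percent rendering. The Clopper–Pearson equal-tailed
exact interval (beta-quantile form) is provided as the alternative method;
the tests pin it to a direct binomial tail-sum bisection for all n ≤ 30.

Rendered percentages round half away from zero to the integer. Published
validation studies are not always internally consistent at this precision
(e.g. printing 85 where the estimate is 85.7); the package renders
arithmetically and documents rather than imitates such cells.

## The synthetic generator

The generator emulates the event structure a nurse-charted airway flow
sheet exhibits around an extubation-failure question, not ICU physiology.
Every synthetic patient has one admission, an initial ICU intubation
charting (status + endotracheal tube type), an extubation, and
scenario-specific subsequent rows; the ICU interval spans all charted
events. Timestamps are minute-resolution in a single implicit timezone.
Scenario timing conventions, in hours:

| scenario | delay after extubation | gold | initial | final |
|---|---|---|---|---|
| TRUE_FAILURE | U(1, 72) | + | + | + |
| MISCODED_STATUS | U(1, 72), extubation charted "Removed" | + | − | − |
| NO_REINTUBATION | — | − | − | − |
| LATE_REINTUBATION | U(73, 120) | − | − | − |
| NASAL_TRUMPET | U(1, 72), "Inserted"/nasal trumpet | − | + | − |
| TRACHEOSTOMY | U(1, 72), "Inserted"/tracheostomy | − | + | − |
| ACCIDENTAL_EXTUBATION | U(0.1, 1), endotracheal | − | + | + |
| PROCEDURAL_REINTUBATION | U(1, 72), re-extubated after U(0.5, 2) | − | + | + |
| OR_INTUBATION_ONLY | U(1, 72), charted in OR | − | − | − |

Gold labels are fixed per scenario. ACCIDENTAL_EXTUBATION and
PROCEDURAL_REINTUBATION are genuine endotracheal reintubations inside the
window that manual reviewers do not count as extubation failure — they are
*designed* false-positive generators for the final signature, which cannot
distinguish them from true failures on flow-sheet evidence alone. The
miscoded status token "Removed" is a plausible picklist value chosen to
fail the extubation vocabulary. Ages are U(18, 90) years and ventilation
durations U(48, 240) h for eligible patients; `n_ineligible` appends
patients violating one eligibility rule for funnel demonstrations.

`CohortConfig` draws each patient's scenario i.i.d. from a mix whose
gold-positive mass must equal the declared prevalence (default 0.14, the
conventional derivation-subset figure); detected prevalence on clean mixes
is therefore binomial around the target, which the tests check at n=1,000
within three standard errors. All randomness flows through one
`numpy.random.Generator` per run, so identical configs give byte-identical
output files.

Two deterministic 100-patient fixtures (internally fixed seeds) mirror the
two subsets of a derivation/validation study design:

* **derivation**: 12 TRUE_FAILURE + 2 MISCODED_STATUS (14 gold positives,
  prevalence 0.14), 4 NASAL_TRUMPET, 82 clean negatives. Initial
  signature vs gold: (TP=12, FP=4, FN=2, TN=82) — 6 disagreements; the
  final signature eliminates exactly the 4 trumpet false positives.
* **validation**: 15 TRUE_FAILURE + 1 MISCODED_STATUS (16 gold positives),
  2 ACCIDENTAL_EXTUBATION + 2 PROCEDURAL_REINTUBATION, 80 clean negatives.
  Final signature vs gold: (TP=15, FP=4, FN=1, TN=80) — 5 disagreements,
  sensitivity 15/16 (renders 94%).

## What passing tests do and do not show

The generator plants the *mechanisms* of misclassification with known
frequency; it does not estimate real charting cadence, tube-type
re-charting frequency, or free-text variability, and every patient has
exactly one admission. Perfect final-signature accuracy on clean-only
cohorts therefore demonstrates the detector's logic, not its field
performance; performance on real data depends on how often the planted
confounder modes occur and on charting discipline, neither of which a
synthetic cohort can establish. Refining a signature against the same
subset used to measure it (as derivation/refinement workflows do)
optimistically biases the derivation-subset accuracy; only the untouched
validation subset measures generalization.

A restriction-only refinement can remove false positives but can never
convert a false negative into a true positive, so a sensitivity *increase*
under the final signature is not reproducible from the stated rule alone;
the fixtures reproduce the false-positive-elimination mechanics exactly
and leave sensitivity unchanged between signatures. Likewise, printed
accuracy tables at n=100 are not always jointly consistent (4 FP + 1 FN
cannot yield specificity 98% and PPV 94% simultaneously); the validation
fixture targets the disagreement *counts*, which are unambiguous.

## Numerical and design choices

* Problem sizes: property sweeps use ≥1,000 random streams of ≤10 events,
  CI cross-checks cover all k ≤ n ≤ 30, coverage simulation uses 10,000
  binomial draws at n=14, p=0.85, and prevalence recovery uses n=1,000
  patients — sizes at which every check is exact or statistically stable
  while the whole suite runs in seconds.
* Tube-type association ties (two type rows equidistant from an
  intubation) resolve to the earlier-charted entry, a deterministic rule.
* Events with identical timestamps keep their charting (row) order;
  detection is invariant to input row shuffling because normalization
  sorts with that stable key.
* `detect` on a record with no airway events returns a negative call with
  no evidence; `qualifying_pairs` rejects unsorted input as a contract
  violation rather than silently sorting.
* The CLI is a thin layer over the library with a stable exit-code
  contract: 0 success, 1 usage/config error, 2 data error.
* Validation (`cmd_validate`) reads calls and labels from files keyed by
  patient id; ids in the calls file absent from the metadata are an error
  listing the unmatched ids, while patients whose gold label is NA are
  dropped from the 2×2 with a warning.
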