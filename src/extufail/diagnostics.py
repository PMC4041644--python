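"""Diagnostic-accuracy statistics for detector validation.

Patient-level calls are compared against the manual-review reference
standard to form a 2x2 confusion table, from which sensitivity,
specificity, PPV, NPV and prevalence are reported with 95% confidence
intervals.

The default interval is the Wilson score interval *with continuity
correction* at z = 1.96 — the method behind the classic online clinical
calculators — because its endpoints, rendered as integer percents, match
how such studies conventionally print their CIs.  The Clopper–Pearson
exact interval is available as an alternative.  z is fixed at 1.96 for the
default 95% level (rather than 1.959964); the difference never survives
integer-percent rendering.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

from scipy import stats

from .errors import DataError
from .signature import FailureCall

logger = logging.getLogger(__name__)


class CIMethod(str, Enum):
    WILSON_CC = "wilson_cc"
    CLOPPER_PEARSON = "clopper_pearson"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 patient-level confusion counts (detector vs reference standard)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with a two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    conf_level: float
    method: CIMethod
    successes: int
    trials: int

    def __post_init__(self):
        assert 0.0 <= self.lower <= self.estimate <= self.upper <= 1.0


def render_percent(x: float) -> int:
    """Integer-percent rendering, rounding half away from zero."""
    return int(math.floor(abs(x) * 100.0 + 0.5)) * (1 if x >= 0 else -1)


def _check_counts(successes: int, trials: int) -> None:
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")


def wilson_cc_interval(
    successes: int,
    trials: int,
    conf_level: float = 0.95,
    z: Optional[float] = None,
) -> ProportionCI:
    """Wilson score interval with continuity correction.

    Closed form, with the conventional caps: 0 successes pins the lower
    bound at 0, all successes pins the upper bound at 1.  ``z`` defaults
    to 1.96 at the 95% level and to the exact normal quantile otherwise.
    """
    _check_counts(successes, trials)
    if z is None:
        z = 1.96 if abs(conf_level - 0.95) < 1e-12 else float(
            stats.norm.ppf((1.0 + conf_level) / 2.0)
        )
    n = float(trials)
    p = successes / n
    z2 = z * z
    denom = 2.0 * (n + z2)
    lo_rad = z2 - 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) + 1.0)
    hi_rad = z2 + 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) - 1.0)
    lower = (2.0 * n * p + z2 - 1.0 - z * math.sqrt(max(lo_rad, 0.0))) / denom
    upper = (2.0 * n * p + z2 + 1.0 + z * math.sqrt(max(hi_rad, 0.0))) / denom
    if successes == 0:
        lower = 0.0
    if successes == trials:
        upper = 1.0
    return ProportionCI(
        estimate=p,
        lower=max(0.0, min(lower, p)),
        upper=min(1.0, max(upper, p)),
        conf_level=conf_level,
        method=CIMethod.WILSON_CC,
        successes=successes,
        trials=trials,
    )


def clopper_pearson_interval(
    successes: int, trials: int, conf_level: float = 0.95
) -> ProportionCI:
    """Equal-tailed exact binomial interval (beta-quantile form)."""
    _check_counts(successes, trials)
    alpha = 1.0 - conf_level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return ProportionCI(
        estimate=successes / trials,
        lower=lower,
        upper=upper,
        conf_level=conf_level,
        method=CIMethod.CLOPPER_PEARSON,
        successes=successes,
        trials=trials,
    )


_INTERVALS = {
    CIMethod.WILSON_CC: wilson_cc_interval,
    CIMethod.CLOPPER_PEARSON: clopper_pearson_interval,
}


def proportion_ci(
    successes: int,
    trials: int,
    conf_level: float = 0.95,
    method: CIMethod = CIMethod.WILSON_CC,
) -> ProportionCI:
    return _INTERVALS[CIMethod(method)](successes, trials, conf_level)


def confusion(
    calls: Sequence[FailureCall], gold: Mapping[str, bool]
) -> ConfusionTable:
    """Cross-tabulate detector verdicts against per-patient gold labels.

    Calls for patients without a gold label are dropped with a warning;
    duplicate patient ids are an error.
    """
    seen: set[str] = set()
    tp = fp = fn = tn = 0
    n_unlabeled = 0
    for call in calls:
        if call.patient_id in seen:
            raise DataError(f"duplicate patient id in calls: {call.patient_id}")
        seen.add(call.patient_id)
        label = gold.get(call.patient_id)
        if label is None:
            n_unlabeled += 1
            continue
        if call.positive and label:
            tp += 1
        elif call.positive and not label:
            fp += 1
        elif not call.positive and label:
            fn += 1
        else:
            tn += 1
    if n_unlabeled:
        logger.warning("%d unlabeled patients dropped from accuracy computation", n_unlabeled)
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class AccuracyReport:
    """Sensitivity/specificity/PPV/NPV/prevalence with intervals.

    A metric whose denominator is zero is reported as ``None`` (absent)
    rather than 0 or an error.
    """

    table: ConfusionTable
    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    prevalence: Optional[ProportionCI]
    method: CIMethod
    conf_level: float

    def metric(self, name: str) -> Optional[ProportionCI]:
        return getattr(self, name)

    def to_dict(self) -> dict:
        metrics = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            ci = self.metric(name)
            metrics[name] = (
                None if ci is None
                else {"est": ci.estimate, "lo": ci.lower, "hi": ci.upper}
            )
        metrics["prevalence"] = (
            None if self.prevalence is None else {"est": self.prevalence.estimate}
        )
        t = self.table
        return {
            "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
            "metrics": metrics,
            "method": self.method.value,
            "conf_level": self.conf_level,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def render_table(self) -> str:
        """Human-readable accuracy table (integer percents with CIs)."""

        def fmt(ci: Optional[ProportionCI]) -> str:
            if ci is None:
                return "—"
            return (
                f"{render_percent(ci.estimate)}% "
                f"({render_percent(ci.lower)}%-{render_percent(ci.upper)}%)"
            )

        lines = [
            f"{'metric':<12} {'value (95% CI)':<20}",
            f"{'sensitivity':<12} {fmt(self.sensitivity):<20}",
            f"{'specificity':<12} {fmt(self.specificity):<20}",
            f"{'PPV':<12} {fmt(self.ppv):<20}",
            f"{'NPV':<12} {fmt(self.npv):<20}",
        ]
        if self.prevalence is not None:
            lines.append(f"{'prevalence':<12} {self.prevalence.estimate:.2f}")
        return "\n".join(lines)


def accuracy_report(
    table: ConfusionTable,
    method: CIMethod = CIMethod.WILSON_CC,
    conf_level: float = 0.95,
) -> AccuracyReport:
    """Build the full accuracy report from a confusion table."""
    if table.n == 0:
        raise ValueError("cannot build an accuracy report from an all-zero table")
    method = CIMethod(method)

    def maybe(successes: int, trials: int) -> Optional[ProportionCI]:
        if trials == 0:
            return None
        return proportion_ci(successes, trials, conf_level, method)

    return AccuracyReport(
        table=table,
        sensitivity=maybe(table.tp, table.tp + table.fn),
        specificity=maybe(table.tn, table.tn + table.fp),
        ppv=maybe(table.tp, table.tp + table.fp),
        npv=maybe(table.tn, table.tn + table.fn),
        prevalence=maybe(table.tp + table.fn, table.n),
        method=method,
        conf_level=conf_level,
    )
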