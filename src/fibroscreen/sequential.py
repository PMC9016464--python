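"""Two-stage sequential testing for advanced fibrosis.

A first dual-cutoff test (canonically FIB-4) triages everyone into low /
indeterminate / high; only the indeterminate stratum receives a second,
single-cutoff test that forces a binary call. The pathway therefore
never outputs an indeterminate result, and any specificity the second
test has on the gray zone converts first-stage indeterminates into
negatives — reducing false-positive referrals at the cost of sensitivity
lost in that stratum.

For a BMI-adjusted second test (NFS), the rule-out cutoff of the
subject's BMI band acts as the binary threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cutoffs import BmiBandConfig, DEFAULT_BANDS, assign_bmi_band
from .diagnostics import (ConfusionSummary, CutoffRule, DiagnosticMetrics,
                          classify_dual, confusion, metrics)
from .errors import DegenerateDataError, ValidationError

__all__ = [
    "SequentialRule",
    "SequentialPerformance",
    "sequential_classify",
    "sequential_performance",
    "NFS_BMI_ADJUSTED_RULEOUT",
]

#: Published BMI-adjusted NFS rule-out cutoffs used as the binary second-stage
#: threshold (band label -> cutoff).
NFS_BMI_ADJUSTED_RULEOUT: dict[str, float] = {
    "nonobese": -2.022,
    "obese": -1.083,
    "morbidly_obese": 0.544,
}


@dataclass(frozen=True)
class SequentialRule:
    """First-stage dual rule plus a binary second-stage threshold.

    ``second_cutoff`` is either a single number or, for a BMI-adjusted
    second test, a mapping of band label -> cutoff.
    """

    first: CutoffRule
    second_name: str
    second_cutoff: float | Mapping[str, float]
    band_config: BmiBandConfig = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if not self.first.is_dual:
            raise ValidationError("the first-stage rule must carry both cutoffs")

    def second_threshold(self, bmi: float | None) -> float:
        if isinstance(self.second_cutoff, Mapping):
            if bmi is None:
                raise ValidationError("BMI required for a BMI-adjusted second test")
            return self.second_cutoff[assign_bmi_band(bmi, self.band_config)]
        return float(self.second_cutoff)


def sequential_classify(first_value: float, second_value: float | None,
                        rule: SequentialRule, age: float | None = None,
                        bmi: float | None = None) -> str:
    """Final low/high call; 'unclassifiable' if the gray zone lacks a second score.

    First-stage low and high calls are final and never consult the second
    test; indeterminates are resolved by the second test (at or above its
    cutoff means high).
    """
    stage1 = classify_dual(first_value, rule.first, age)
    if stage1 != "indeterminate":
        return stage1
    if second_value is None:
        return "unclassifiable"
    return "high" if second_value >= rule.second_threshold(bmi) else "low"


@dataclass(frozen=True)
class SequentialPerformance:
    metrics: DiagnosticMetrics
    fp_sequential: int
    fp_first_alone: int
    fp_reduction: float | None          # 1 - FP_seq / FP_single
    n_second_stage: int                 # subjects routed to the second test
    n_unclassifiable: int


def sequential_performance(first_scores: Sequence[float],
                           second_scores: Sequence[float | None],
                           labels: Sequence[bool],
                           rule: SequentialRule,
                           ages: Sequence[float] | None = None,
                           bmis: Sequence[float] | None = None,
                           lr_rounding: str = "raw") -> SequentialPerformance:
    """Metrics of the sequential call plus referral (false-positive) savings.

    The comparator for false positives is the first test's lower cutoff
    used alone as a binary screen (score >= lower positive, age-adjusted
    where applicable) — the policy the sequential pathway replaces.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise DegenerateDataError("both condition classes required")
    n = len(y)
    ages = [None] * n if ages is None else ages
    bmis = [None] * n if bmis is None else bmis

    calls = [sequential_classify(f, s2, rule, a, b)
             for f, s2, a, b in zip(first_scores, second_scores, ages, bmis, strict=True)]
    n_unclassifiable = sum(c == "unclassifiable" for c in calls)
    classified = [(c, bool(t)) for c, t in zip(calls, y) if c != "unclassifiable"]
    cs = confusion([c for c, _ in classified], [t for _, t in classified])
    m = metrics(cs, lr_rounding=lr_rounding)

    first_pos = [f >= rule.first.effective_lower(a)
                 for f, a in zip(first_scores, ages)]
    fp_single = int(sum(p and not t for p, t in zip(first_pos, y)))
    fp_seq = cs.fp
    reduction = 1.0 - fp_seq / fp_single if fp_single > 0 else None

    n_second = sum(classify_dual(f, rule.first, a) == "indeterminate"
                   for f, a in zip(first_scores, ages))
    return SequentialPerformance(metrics=m, fp_sequential=fp_seq,
                                 fp_first_alone=fp_single,
                                 fp_reduction=reduction,
                                 n_second_stage=n_second,
                                 n_unclassifiable=n_unclassifiable)
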