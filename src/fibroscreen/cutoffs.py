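"""BMI-stratified derivation and validation of score cutoffs.

The pipeline mirrors how decision thresholds are established for a
screening score whose specificity drifts with adiposity: patients are
binned into BMI bands, each band is split 70:30 into derivation and
validation subsets (stratified on the target condition), and three
cutoffs are selected on the derivation subset:

* rule-out -- the largest cutoff keeping sensitivity at or above the
  target (default 85%), which maximizes specificity under that floor;
* rule-in -- the smallest cutoff keeping specificity at or above the
  target (default 95%), which maximizes sensitivity under that floor;
* best single -- the cutoff maximizing Youden's index (Se + Sp - 1).

Candidate cutoffs are midpoints between adjacent distinct observed
scores, plus -inf/+inf, so the selection is rank-based and insensitive to
monotone transformations of the score. The sensitivity/specificity
anchors are chosen so that, at a 15% planning prevalence, the rule-out
cutoff yields NPV >= 95% and the rule-in cutoff PPV >= 75%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .diagnostics import (ConfusionSummary, CutoffRule, DiagnosticMetrics,
                          confusion, metrics, percent)
from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "BmiBandConfig",
    "DEFAULT_BANDS",
    "DerivationTargets",
    "DerivedCutoffs",
    "BandCutoffs",
    "BmiCutoffSet",
    "assign_bmi_band",
    "split_derivation_validation",
    "stratified_split",
    "derive_cutoffs",
    "validate_cutoffs",
    "derive_bmi_adjusted_cutoffs",
]


@dataclass(frozen=True)
class BmiBandConfig:
    """Ordered half-open BMI intervals partitioning (0, inf).

    ``boundaries`` are the interior cut points; band i covers
    [boundaries[i-1], boundaries[i]).
    """

    boundaries: tuple[float, ...] = (30.0, 40.0)
    labels: tuple[str, ...] = ("nonobese", "obese", "morbidly_obese")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValidationError("need one more label than boundaries")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("boundaries must be strictly increasing")
        if self.boundaries and self.boundaries[0] <= 0:
            raise ValidationError("boundaries must be positive")


DEFAULT_BANDS = BmiBandConfig()


def assign_bmi_band(bmi: float, config: BmiBandConfig = DEFAULT_BANDS) -> str:
    """Map a BMI to its unique band label (half-open intervals)."""
    if not bmi > 0:
        raise DomainError(f"bmi must be > 0, got {bmi}")
    for bound, label in zip(config.boundaries, config.labels):
        if bmi < bound:
            return label
    return config.labels[-1]


@dataclass(frozen=True)
class DerivationTargets:
    """Anchors of the cutoff search and the split design."""

    se_target: float = 0.85
    sp_target: float = 0.95
    planning_prevalence: float = 0.15
    split_ratio: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("se_target", "sp_target", "planning_prevalence", "split_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# Stratified 70:30 split
# ---------------------------------------------------------------------------

def stratified_split(n: int, labels: Sequence[bool], ratio: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving case prevalence to within one subject."""
    y = np.asarray(labels, dtype=bool)
    if len(y) != n:
        raise ValidationError("labels length mismatch")
    first, second = [], []
    for stratum in (np.flatnonzero(y), np.flatnonzero(~y)):
        perm = rng.permutation(stratum)
        k = int(round(ratio * len(perm)))
        first.append(perm[:k])
        second.append(perm[k:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def split_derivation_validation(
    records: Sequence[PatientRecord],
    labels: Sequence[bool],
    targets: DerivationTargets,
    config: BmiBandConfig = DEFAULT_BANDS,
) -> dict[str, tuple[list[int], list[int]]]:
    """Per-band stratified 70:30 split, reproducible from the seed.

    Returns band label -> (derivation indices, validation indices) into the
    input sequence. Bands without a single case are excluded (they cannot
    anchor a sensitivity floor) and reported with an empty tuple.
    """
    y = np.asarray(labels, dtype=bool)
    bands = np.array([assign_bmi_band(r.bmi, config) for r in records])
    rng = np.random.default_rng(targets.seed)
    out: dict[str, tuple[list[int], list[int]]] = {}
    for label in config.labels:
        idx = np.flatnonzero(bands == label)
        if idx.size == 0:
            continue
        if not y[idx].any():
            out[label] = ([], [])
            continue
        d, v = stratified_split(idx.size, y[idx], targets.split_ratio, rng)
        out[label] = (list(idx[d]), list(idx[v]))
    return out


# ---------------------------------------------------------------------------
# Cutoff selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffChoice:
    cutoff: float
    se: float
    sp: float
    attainable: bool = True

    @property
    def youden(self) -> float:
        return self.se + self.sp - 1


@dataclass(frozen=True)
class DerivedCutoffs:
    rule_out: CutoffChoice
    rule_in: CutoffChoice
    best_single: CutoffChoice

    def as_rule(self, score: str) -> CutoffRule:
        return CutoffRule(score, lower=self.rule_out.cutoff,
                          upper=self.rule_in.cutoff)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2 if u.size > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def derive_cutoffs(scores: Sequence[float], labels: Sequence[bool],
                   targets: DerivationTargets = DerivationTargets()) -> DerivedCutoffs:
    """Select rule-out / rule-in / best-single cutoffs on one data set.

    Every candidate is evaluated as a binary test (score >= cutoff is
    positive). Ties in the objective break toward the lower cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(s) != len(y):
        raise ValidationError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("both classes required to derive cutoffs")

    cands = _candidate_cutoffs(s)
    pred = s[None, :] >= cands[:, None]          # candidates x subjects
    tp = (pred & y[None, :]).sum(axis=1)
    fp = (pred & ~y[None, :]).sum(axis=1)
    se = tp / n_pos
    sp = 1 - fp / n_neg

    def choice(i: int, attainable: bool = True) -> CutoffChoice:
        return CutoffChoice(float(cands[i]), float(se[i]), float(sp[i]), attainable)

    # best single: maximal Youden, ties toward the lower cutoff
    youden = se + sp - 1
    best = choice(int(np.argmax(youden)))

    # rule-out: se floor, maximize sp (sp is nondecreasing in the cutoff,
    # so take the last candidate meeting the floor)
    ok = np.flatnonzero(se >= targets.se_target)
    rule_out = choice(int(ok[np.argmax(sp[ok])])) if ok.size else \
        CutoffChoice(float("-inf"), 1.0, 0.0, attainable=False)
    if not math.isfinite(rule_out.cutoff):
        rule_out = CutoffChoice(rule_out.cutoff, rule_out.se, rule_out.sp,
                                attainable=False)

    # rule-in: sp floor, maximize se (se is nonincreasing, take the first)
    ok = np.flatnonzero(sp >= targets.sp_target)
    rule_in = choice(int(ok[np.argmax(se[ok])])) if ok.size else \
        CutoffChoice(float("inf"), 0.0, 1.0, attainable=False)
    if not math.isfinite(rule_in.cutoff):
        rule_in = CutoffChoice(rule_in.cutoff, rule_in.se, rule_in.sp,
                               attainable=False)

    return DerivedCutoffs(rule_out=rule_out, rule_in=rule_in, best_single=best)


# ---------------------------------------------------------------------------
# Validation / application report
# ---------------------------------------------------------------------------

def _binary_metrics(s, y, cutoff, strict=False, lr_rounding="integer_percent"):
    cls = ["high" if (v > cutoff if strict else v >= cutoff) else "low" for v in s]
    return metrics(confusion(cls, y), lr_rounding=lr_rounding)


def validate_cutoffs(scores: Sequence[float], labels: Sequence[bool],
                     cutoffs: DerivedCutoffs,
                     lr_rounding: str = "integer_percent") -> pd.DataFrame:
    """Apply derived cutoffs to a data set; stratified application report.

    One row per stratum (below rule-out / indeterminate / above rule-in)
    with subject counts split by condition status, plus rule-out, rule-in
    and best-single metric rows with likelihood ratios.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    lo, hi, single = (cutoffs.rule_out.cutoff, cutoffs.rule_in.cutoff,
                      cutoffs.best_single.cutoff)

    below = s < lo
    above = s > hi
    between = ~below & ~above

    def count_row(name, mask, interpretation):
        return {"stratum": name, "n": int(mask.sum()),
                "n_neg": int((mask & ~y).sum()), "n_pos": int((mask & y).sum()),
                "se_pct": None, "sp_pct": None, "ppv_pct": None, "npv_pct": None,
                "lr_pos": None, "lr_neg": None, "interpretation": interpretation}

    def metric_row(name, m: DiagnosticMetrics, interpretation, n, n_neg, n_pos):
        return {"stratum": name, "n": n, "n_neg": n_neg, "n_pos": n_pos,
                "se_pct": percent(m.se), "sp_pct": percent(m.sp),
                "ppv_pct": percent(m.ppv) if m.ppv is not None else None,
                "npv_pct": percent(m.npv) if m.npv is not None else None,
                "lr_pos": round(m.lr_pos, 2) if m.lr_pos is not None else None,
                "lr_neg": round(m.lr_neg, 2) if m.lr_neg is not None else None,
                "interpretation": interpretation}

    m_out = _binary_metrics(s, y, lo, strict=False, lr_rounding=lr_rounding)
    m_in = _binary_metrics(s, y, hi, strict=True, lr_rounding=lr_rounding)
    m_single = _binary_metrics(s, y, single, strict=False, lr_rounding=lr_rounding)
    ge_single = s >= single

    rows = [
        {**count_row(f"<{lo:g}", below, "Rule out"),
         **{k: v for k, v in metric_row("", m_out, "Rule out", 0, 0, 0).items()
            if k.endswith("pct") or k.startswith("lr")}},
        count_row(f"{lo:g}-{hi:g}", between, "Indeterminate"),
        {**count_row(f">{hi:g}", above, "Rule in"),
         **{k: v for k, v in metric_row("", m_in, "Rule in", 0, 0, 0).items()
            if k.endswith("pct") or k.startswith("lr")}},
        metric_row(f">={single:g}", m_single, "Best single",
                   int(ge_single.sum()), int((ge_single & ~y).sum()),
                   int((ge_single & y).sum())),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-cohort driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandCutoffs:
    band: str
    cutoffs: DerivedCutoffs
    derivation_n: int
    derivation_cases: int
    validation_n: int
    validation_cases: int
    derivation_report: pd.DataFrame
    validation_report: pd.DataFrame


@dataclass
class BmiCutoffSet:
    score: str
    bands: dict[str, BandCutoffs] = field(default_factory=dict)

    def rule_for(self, bmi: float,
                 config: BmiBandConfig = DEFAULT_BANDS) -> CutoffRule:
        band = assign_bmi_band(bmi, config)
        return self.bands[band].cutoffs.as_rule(self.score)


def derive_bmi_adjusted_cutoffs(
    records: Sequence[PatientRecord],
    scores: Sequence[float],
    labels: Sequence[bool],
    score_name: str,
    targets: DerivationTargets = DerivationTargets(),
    config: BmiBandConfig = DEFAULT_BANDS,
) -> BmiCutoffSet:
    """Full pipeline: band, split, derive on 70%, validate on 30%."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    splits = split_derivation_validation(records, y, targets, config)
    out = BmiCutoffSet(score=score_name)
    for band, (d_idx, v_idx) in splits.items():
        if not d_idx:
            continue
        d_idx, v_idx = np.asarray(d_idx), np.asarray(v_idx)
        derived = derive_cutoffs(s[d_idx], y[d_idx], targets)
        out.bands[band] = BandCutoffs(
            band=band,
            cutoffs=derived,
            derivation_n=len(d_idx), derivation_cases=int(y[d_idx].sum()),
            validation_n=len(v_idx), validation_cases=int(y[v_idx].sum()),
            derivation_report=validate_cutoffs(s[d_idx], y[d_idx], derived),
            validation_report=validate_cutoffs(s[v_idx], y[v_idx], derived),
        )
    return out
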