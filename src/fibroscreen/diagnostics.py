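"""Diagnostic-accuracy statistics for single- and dual-cutoff tests.

Covers the evaluation surface used throughout the package: confusion
tallies with exact Clopper-Pearson intervals, dual-cutoff classification
with an indeterminate gray zone (and the convention that gray-zone
subjects, who are assumed to proceed to biopsy, count as correctly
classified when combined performance is reported), ROC/AUROC with DeLong
inference, the Obuchowski measure for ordinal stages, paired comparisons
(exact McNemar, chi-squared, weighted generalized score for predictive
values), and prevalence-projected predictive values.

Conventions
-----------
* Orientation: a higher score always indicates more advanced disease.
* Lower (rule-out) cutoff as a binary screen: score >= cutoff is positive.
* Upper (rule-in) cutoff: score > upper is positive; values in
  [lower, upper] are indeterminate.
* A rule carrying a single cutoff is binary: score >= cutoff is positive.
* ROC ties contribute 1/2 (Mann-Whitney convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "CutoffRule",
    "ConfusionSummary",
    "DiagnosticMetrics",
    "DualCutoffPerformance",
    "RocCurve",
    "PUBLISHED_CUTOFFS",
    "classify_dual",
    "classify_many",
    "confusion",
    "metrics",
    "dual_cutoff_performance",
    "combined_dual_metrics",
    "roc_curve",
    "auroc",
    "delong",
    "delong_ci",
    "obuchowski",
    "compare_paired_rates",
    "compare_unpaired_rates",
    "compare_predictive_values",
    "predictive_values_at_prevalence",
    "percent",
]

Classification = Literal["low", "indeterminate", "high"]


def percent(p: float) -> int:
    """Round a proportion to a whole percent, half away from zero."""
    return int(math.floor(p * 100.0 + 0.5))


# ---------------------------------------------------------------------------
# Cutoff rules and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffRule:
    """Decision thresholds for one score.

    With both cutoffs present the rule is dual (gray zone in between);
    with a single cutoff it is a binary test, positive at or above the
    cutoff. ``age_adjusted_lower`` replaces the lower cutoff for subjects
    aged >= 65 years.
    """

    score: str
    lower: float | None = None
    upper: float | None = None
    age_adjusted_lower: float | None = None
    orientation: str = "higher"

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValidationError("a cutoff rule needs at least one cutoff")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValidationError("lower cutoff must not exceed upper cutoff")
        if self.orientation != "higher":
            raise ValidationError("only higher-is-more-diseased scores are supported")

    @property
    def is_dual(self) -> bool:
        return self.lower is not None and self.upper is not None

    def effective_lower(self, age: float | None) -> float | None:
        if (self.age_adjusted_lower is not None and age is not None and age >= 65):
            return self.age_adjusted_lower
        return self.lower


#: Previously published decision thresholds for advanced fibrosis
#: (MACK-3: fibrotic NASH). Parenthesized values in the source tables,
#: used for patients aged >= 65 years, appear as age_adjusted_lower.
PUBLISHED_CUTOFFS: dict[str, CutoffRule] = {
    "FIB4": CutoffRule("FIB4", lower=1.3, upper=2.67, age_adjusted_lower=2.0),
    "NFS": CutoffRule("NFS", lower=-1.455, upper=0.676, age_adjusted_lower=0.12),
    "HFS": CutoffRule("HFS", lower=0.12, upper=0.47),
    "APRI": CutoffRule("APRI", lower=1.0),
    "BARD": CutoffRule("BARD", lower=2.0),
    "ADAPT": CutoffRule("ADAPT", lower=6.3287),
    "FIBC3": CutoffRule("FIBC3", lower=0.4),
    "MACK3": CutoffRule("MACK3", lower=0.134, upper=0.549),
}


def classify_dual(value: float, rule: CutoffRule,
                  age: float | None = None) -> Classification:
    """Classify one score value as low / indeterminate / high risk."""
    if rule.is_dual:
        lower = rule.effective_lower(age)
        if value > rule.upper:
            return "high"
        if value < lower:
            return "low"
        return "indeterminate"
    cutoff = rule.effective_lower(age) if rule.lower is not None else rule.upper
    return "high" if value >= cutoff else "low"


def classify_many(values: Sequence[float], rule: CutoffRule,
                  ages: Sequence[float] | None = None) -> list[Classification]:
    ages = [None] * len(values) if ages is None else ages
    return [classify_dual(v, rule, a) for v, a in zip(values, ages, strict=True)]


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    """Six-way tally; gray-zone subjects split by true condition status."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    indeterminate_pos: int = 0
    indeterminate_neg: int = 0

    def __post_init__(self) -> None:
        for f in ("tp", "fp", "tn", "fn", "indeterminate_pos", "indeterminate_neg"):
            if getattr(self, f) < 0:
                raise ValidationError(f"count {f} must be >= 0")

    @property
    def total(self) -> int:
        return (self.tp + self.fp + self.tn + self.fn
                + self.indeterminate_pos + self.indeterminate_neg)

    def indeterminates_as_correct(self) -> "ConfusionSummary":
        """Fold gray-zone subjects into tp/tn (assumed resolved by biopsy)."""
        return ConfusionSummary(tp=self.tp + self.indeterminate_pos,
                                fp=self.fp,
                                tn=self.tn + self.indeterminate_neg,
                                fn=self.fn)


def confusion(classifications: Sequence[Classification],
              condition_labels: Sequence[bool]) -> ConfusionSummary:
    """Tally classifications against true condition labels."""
    if len(classifications) != len(condition_labels):
        raise ValidationError("classifications and labels differ in length")
    tp = fp = tn = fn = ip = iq = 0
    for cls, pos in zip(classifications, condition_labels):
        if cls == "high":
            tp, fp = (tp + 1, fp) if pos else (tp, fp + 1)
        elif cls == "low":
            fn, tn = (fn + 1, tn) if pos else (fn, tn + 1)
        elif cls == "indeterminate":
            ip, iq = (ip + 1, iq) if pos else (ip, iq + 1)
        else:
            raise ValidationError(f"unknown classification {cls!r}")
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn,
                            indeterminate_pos=ip, indeterminate_neg=iq)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV with exact 95% CIs, likelihood ratios and NND.

    Proportions are fractions in [0, 1]; an undefined metric (zero
    denominator, or Youden <= 0 for NND) is ``None`` rather than NaN.
    """

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    se_ci: tuple[float, float] | None
    sp_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    lr_pos: float | None
    lr_neg: float | None
    nnd: float | None
    indeterminate_fraction: float = 0.0
    counts: ConfusionSummary | None = None


def _prop(k: int, n: int, alpha: float):
    if n == 0:
        return None, None
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return k / n, (float(lo), float(hi))


def metrics(cs: ConfusionSummary, ci_level: float = 0.95,
            lr_rounding: Literal["raw", "integer_percent"] = "raw") -> DiagnosticMetrics:
    """Derive Se/Sp/PPV/NPV (Clopper-Pearson CIs), LR+/-, and NND.

    In ``integer_percent`` mode the likelihood ratios and NND are formed
    from sensitivity and specificity first rounded to whole percents (half
    away from zero), reproducing how printed summary tables derive them;
    ``raw`` is the analytic default. Gray-zone subjects do not enter any
    denominator here; fold them first via
    :meth:`ConfusionSummary.indeterminates_as_correct` if the combined
    convention is wanted.
    """
    alpha = 1 - ci_level
    se, se_ci = _prop(cs.tp, cs.tp + cs.fn, alpha)
    sp, sp_ci = _prop(cs.tn, cs.tn + cs.fp, alpha)
    ppv, ppv_ci = _prop(cs.tp, cs.tp + cs.fp, alpha)
    npv, npv_ci = _prop(cs.tn, cs.tn + cs.fn, alpha)

    lr_pos = lr_neg = nnd = None
    if se is not None and sp is not None:
        if lr_rounding == "integer_percent":
            se_r, sp_r = percent(se) / 100.0, percent(sp) / 100.0
        else:
            se_r, sp_r = se, sp
        if sp_r < 1:
            lr_pos = se_r / (1 - sp_r)
        if sp_r > 0:
            lr_neg = (1 - se_r) / sp_r
        youden = se_r + sp_r - 1
        if youden > 0:
            nnd = 1.0 / youden

    n = cs.total
    return DiagnosticMetrics(
        se=se, sp=sp, ppv=ppv, npv=npv,
        se_ci=se_ci, sp_ci=sp_ci, ppv_ci=ppv_ci, npv_ci=npv_ci,
        lr_pos=lr_pos, lr_neg=lr_neg, nnd=nnd,
        indeterminate_fraction=(cs.indeterminate_pos + cs.indeterminate_neg) / n if n else 0.0,
        counts=cs,
    )


@dataclass(frozen=True)
class DualCutoffPerformance:
    lower: DiagnosticMetrics            # rule-out cutoff as a binary screen
    upper: DiagnosticMetrics            # rule-in cutoff as a binary screen
    indeterminate_fraction: float


def _require_both_classes(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise DegenerateDataError("both condition-positive and -negative subjects required")
    return y


def dual_cutoff_performance(scores: Sequence[float], labels: Sequence[bool],
                            ages: Sequence[float] | None, rule: CutoffRule,
                            ci_level: float = 0.95,
                            lr_rounding: Literal["raw", "integer_percent"] = "raw",
                            ) -> DualCutoffPerformance:
    """Per-cutoff binary performance plus the gray-zone fraction.

    The lower cutoff screens positive at score >= lower (age-adjusted where
    applicable); the upper cutoff at score > upper.
    """
    y = _require_both_classes(labels)
    s = np.asarray(scores, dtype=float)
    ages = [None] * len(s) if ages is None else ages
    if not rule.is_dual:
        raise ValidationError("dual_cutoff_performance needs a dual rule")

    lower_cls = ["high" if v >= rule.effective_lower(a) else "low"
                 for v, a in zip(s, ages)]
    upper_cls = ["high" if v > rule.upper else "low" for v in s]
    gray = [classify_dual(v, rule, a) == "indeterminate" for v, a in zip(s, ages)]

    return DualCutoffPerformance(
        lower=metrics(confusion(lower_cls, y), ci_level, lr_rounding),
        upper=metrics(confusion(upper_cls, y), ci_level, lr_rounding),
        indeterminate_fraction=float(np.mean(gray)),
    )


def combined_dual_metrics(scores: Sequence[float], labels: Sequence[bool],
                          ages: Sequence[float] | None, rule: CutoffRule,
                          ci_level: float = 0.95,
                          lr_rounding: Literal["raw", "integer_percent"] = "raw",
                          ) -> DiagnosticMetrics:
    """Combined two-cutoff performance with indeterminates counted correct.

    Gray-zone subjects are assumed to be definitively staged by biopsy, so
    condition-positives in the gray zone count as true positives and
    condition-negatives as true negatives.
    """
    y = _require_both_classes(labels)
    cs = confusion(classify_many(scores, rule, ages), y)
    m = metrics(cs.indeterminates_as_correct(), ci_level, lr_rounding)
    n = cs.total
    frac = (cs.indeterminate_pos + cs.indeterminate_neg) / n if n else 0.0
    return DiagnosticMetrics(**{**vars(m), "indeterminate_fraction": frac, "counts": cs})


# ---------------------------------------------------------------------------
# ROC / AUROC and DeLong inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-corrected Mann-Whitney AUROC."""
    y = _require_both_classes(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC points at all unique thresholds plus AUROC with a DeLong 95% CI."""
    y = _require_both_classes(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc, ci = delong_ci(s, y)
    return RocCurve(thresholds=thr, se=tpr, sp=1 - fpr, auroc=auc, auroc_ci=ci)


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y], scores[~y]
    # psi(X, Y) = 1 if X > Y, 0.5 if X == Y, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, cmp.mean()


def delong_ci(scores: Sequence[float], labels: Sequence[bool],
              ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUROC and its DeLong-variance normal CI (clipped to [0, 1])."""
    y = _require_both_classes(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01, auc = _structural_components(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


@dataclass(frozen=True)
class DeLongComparison:
    auroc_a: float
    auroc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float | None
    p: float | None
    degenerate: bool = False


def delong(scores_a: Sequence[float], scores_b: Sequence[float],
           labels: Sequence[bool]) -> DeLongComparison:
    """Compare two paired AUROCs with the DeLong structural-components test."""
    y = _require_both_classes(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValidationError("paired scores and labels must have equal length")

    v10a, v01a, auc_a = _structural_components(a, y)
    v10b, v01b, auc_b = _structural_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        # perfect separation in both tests, or identical components
        degenerate = not np.isclose(auc_a, auc_b)
        z = 0.0 if np.isclose(auc_a, auc_b) else None
        p = 1.0 if z == 0.0 else None
        return DeLongComparison(auc_a, auc_b, cov[0, 0], cov[1, 1], cov[0, 1],
                                z, p, degenerate=degenerate)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongComparison(float(auc_a), float(auc_b), float(cov[0, 0]),
                            float(cov[1, 1]), float(cov[0, 1]), float(z), float(p))


# ---------------------------------------------------------------------------
# Obuchowski measure (ordinal stages)
# ---------------------------------------------------------------------------

def obuchowski(scores: Sequence[float], stages: Sequence[int],
               penalty_per_stage: float = 0.25,
               ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Weighted probability of correctly ranking two patients by stage.

    Over all subject pairs with different fibrosis stages, a pair scores 1
    if the biomarker orders them concordantly with stage, 1/2 on a score
    tie, 0 otherwise; the pair weight is ``penalty_per_stage x |stage
    difference|`` and the measure is the weighted mean pair score. The CI
    is a leave-one-out jackknife on the weighted mean.
    """
    s = np.asarray(scores, dtype=float)
    k = np.asarray(stages, dtype=int)
    if len(s) != len(k):
        raise ValidationError("scores and stages must have equal length")
    if np.unique(k).size < 2:
        raise DegenerateDataError("at least two distinct stages required")

    n = len(s)
    dk = k[:, None] - k[None, :]
    ds = s[:, None] - s[None, :]
    differs = dk != 0
    concordant = (np.sign(ds) == np.sign(dk)) & differs
    tied = (ds == 0) & differs
    pair_score = concordant * 1.0 + tied * 0.5
    w = penalty_per_stage * np.abs(dk) * differs

    # each unordered pair appears twice in the matrices; ratios are unaffected
    tot_w = w.sum()
    tot_ws = (w * pair_score).sum()
    theta = tot_ws / tot_w

    # leave-one-out via row sums (matrices are symmetric in weight)
    row_w = w.sum(axis=1)
    row_ws = (w * pair_score).sum(axis=1)
    loo = np.empty(n)
    for i in range(n):
        denom = tot_w - 2 * row_w[i]
        loo[i] = (tot_ws - 2 * row_ws[i]) / denom if denom > 0 else theta
    pseudo = n * theta - (n - 1) * loo
    var = pseudo.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return float(theta), (max(0.0, theta - half), min(1.0, theta + half))


# ---------------------------------------------------------------------------
# Paired / unpaired comparisons
# ---------------------------------------------------------------------------

def compare_paired_rates(correct_a: Sequence[bool],
                         correct_b: Sequence[bool]) -> float:
    """Exact McNemar p for paired binary outcomes (zero discordants -> p=1)."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if len(a) != len(b):
        raise ValidationError("paired outcomes must have equal length")
    b01 = int(np.sum(a & ~b))
    b10 = int(np.sum(~a & b))
    if b01 + b10 == 0:
        return 1.0
    table = [[int(np.sum(a & b)), b01], [b10, int(np.sum(~a & ~b))]]
    res = _sm_mcnemar(table, exact=True)
    return float(min(res.pvalue, 1.0))


def compare_unpaired_rates(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pearson chi-squared p for two independent proportions."""
    if min(n1, n2) <= 0:
        raise DomainError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


@dataclass(frozen=True)
class PredictiveValueComparison:
    ppv_a: float
    ppv_b: float
    npv_a: float
    npv_b: float
    p_ppv: float
    p_npv: float


def _wgs_proportion_test(in_a: np.ndarray, in_b: np.ndarray,
                         response: np.ndarray) -> float:
    """Cluster-robust generalized score test for two correlated proportions.

    Subjects may contribute to one or both groups (paired design). The
    common proportion is estimated under H0 by pooling weighted by group
    size, and the variance of the difference by a sandwich over per-subject
    influence contributions.
    """
    n1, n2 = int(in_a.sum()), int(in_b.sum())
    if n1 == 0 or n2 == 0:
        raise DegenerateDataError("a predictive value is undefined in one arm")
    p1 = response[in_a].mean()
    p2 = response[in_b].mean()
    p0 = (n1 * p1 + n2 * p2) / (n1 + n2)
    resid = response - p0
    infl = in_a * resid / n1 - in_b * resid / n2
    var = float(np.sum(infl ** 2))
    diff = p1 - p2
    if var <= 0:
        return 1.0
    z = diff / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def compare_predictive_values(test_a: Sequence[bool], test_b: Sequence[bool],
                              labels: Sequence[bool]) -> PredictiveValueComparison:
    """Compare PPVs and NPVs of two paired binary tests.

    Weighted generalized score approach for relative predictive values of
    paired tests: each subject contributes its disease status to the
    test-positive arm of every test that calls it positive (and likewise
    for NPV with negative calls); the score statistic pools under H0 and
    uses a cluster-robust variance, so subjects positive on both tests are
    handled as matched contributions.
    """
    a = np.asarray(test_a, dtype=bool)
    b = np.asarray(test_b, dtype=bool)
    d = np.asarray(labels, dtype=bool).astype(float)
    if not (len(a) == len(b) == len(d)):
        raise ValidationError("paired tests and labels must have equal length")
    for arm, name in ((a, "A"), (b, "B")):
        if arm.sum() == 0 or (~arm).sum() == 0:
            raise DegenerateDataError(f"test {name} has an undefined predictive value")

    p_ppv = _wgs_proportion_test(a, b, d)
    p_npv = _wgs_proportion_test(~a, ~b, 1.0 - d)
    return PredictiveValueComparison(
        ppv_a=float(d[a].mean()), ppv_b=float(d[b].mean()),
        npv_a=float(1 - d[~a].mean()), npv_b=float(1 - d[~b].mean()),
        p_ppv=p_ppv, p_npv=p_npv,
    )


# ---------------------------------------------------------------------------
# Prevalence projection
# ---------------------------------------------------------------------------

def predictive_values_at_prevalence(se: float, sp: float,
                                    prevalence: float) -> dict[str, float]:
    """Bayes-projected PPV, NPV and accuracy at a planning prevalence."""
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must be in [0, 1], got {v}")
    pi = prevalence
    num_p = se * pi
    den_p = num_p + (1 - sp) * (1 - pi)
    num_n = sp * (1 - pi)
    den_n = num_n + (1 - se) * pi
    ppv = num_p / den_p if den_p > 0 else (0.0 if pi == 0 else 1.0)
    npv = num_n / den_n if den_n > 0 else (1.0 if pi == 0 else 0.0)
    return {"ppv": ppv, "npv": npv, "accuracy": se * pi + sp * (1 - pi)}
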