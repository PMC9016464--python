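"""Synthetic NAFLD biopsy cohorts with stage-dependent biomarker structure.

The generator emulates the statistical skeleton the analyses assume: an
ordinal fibrosis stage drawn from a configurable prevalence vector, a
log-normal BMI distribution, and analytes whose stage-conditional
distributions shift monotonically with stage — transaminases, PRO-C3 and
CK-18 rising (log-normal), platelets falling (truncated normal), plus a
diabetes probability logistic in BMI and stage and a NASH/activity-score
model conditional on stage. AST and ALT share a log-normal hepatocellular
injury factor so the AST/ALT ratio behaves the way the composite scores
exploit.

Analytes are conditionally independent given stage, BMI and the shared
injury factor; real cohorts carry richer correlation, so passing recovery
tests on these cohorts demonstrates correctness of the pipeline, not
field performance. Presets approximate the marginal summaries of three
published cohort types (a bariatric-surgery-dominated overweight/obese
clinic, a leaner retrospective hepatology cohort, and an
elevated-risk tertiary cohort); they emulate those summaries, they do not
reproduce any restricted data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import PatientRecord
from .errors import ConfigurationError, ValidationError

__all__ = ["SyntheticCohortSpec", "preset", "PRESETS", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All knobs of the generator; defaults match the overweight/obese preset.

    Stage effects are on the log scale for log-normal analytes (per stage
    unit) and on the natural scale for normal analytes.
    """

    n: int = 1000
    seed: int = 0
    # stage F0..F4 probabilities
    stage_probs: tuple[float, ...] = (204 / 378, 125 / 378, 21 / 378, 17 / 378, 11 / 378)
    # demographics
    age_mean: float = 50.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (18.0, 75.0)
    male_prob: float = 0.29
    bmi_log_mu: float = 3.696        # median ~40.3 kg/m^2
    bmi_log_sigma: float = 0.16
    bmi_bounds: tuple[float, float] = (18.0, 80.0)
    # transaminases: shared log-normal injury factor + idiosyncratic noise
    ast_log_base: float = 3.33       # median ~28 U/L at F0
    ast_stage_effect: float = 0.16
    alt_log_base: float = 3.66       # median ~39 U/L at F0
    alt_stage_effect: float = 0.02
    shared_injury_sd: float = 0.30
    ast_noise_sd: float = 0.20
    alt_noise_sd: float = 0.28
    # platelets (10^9/L), truncated normal
    platelets_base: float = 262.0
    platelets_stage_effect: float = -21.0
    platelets_sd: float = 55.0
    platelets_floor: float = 30.0
    # albumin (g/dL)
    albumin_base: float = 3.9
    albumin_stage_effect: float = -0.06
    albumin_sd: float = 0.35
    albumin_bounds: tuple[float, float] = (2.0, 5.5)
    # fasting glucose (mmol/L) and insulin (mU/L)
    glucose_base: float = 5.7
    glucose_stage_effect: float = 0.15
    glucose_sd: float = 1.1
    glucose_floor: float = 3.0
    insulin_log_base: float = 2.48   # median ~12 mU/L
    insulin_stage_effect: float = 0.10
    insulin_log_sd: float = 0.55
    # diabetes: logistic in BMI and stage
    diabetes_intercept: float = -5.9
    diabetes_bmi_coef: float = 0.13
    diabetes_stage_coef: float = 0.40
    # neo-epitope biomarkers
    pro_c3_log_base: float = 2.25    # median ~9.5 ng/mL at F0
    pro_c3_stage_effect: float = 0.22
    pro_c3_log_sd: float = 0.32
    ck18_m30_log_base: float = 5.0   # median ~148 U/L at F0
    ck18_m30_stage_effect: float = 0.28
    ck18_m30_log_sd: float = 0.50
    ck18_m65_log_offset: float = 0.30    # M65 = M30 * exp(offset + noise)
    ck18_m65_log_sd: float = 0.25
    # histological activity
    nash_prob_by_stage: tuple[float, ...] = (0.10, 0.45, 0.75, 0.85, 0.90)
    # per-analyte missingness rates (field name -> probability)
    missingness: Mapping[str, float] = field(default_factory=dict)
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        p = np.asarray(self.stage_probs, dtype=float)
        if p.size != 5 or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValidationError("stage_probs must be 5 nonnegative values summing to 1")
        for name in ("age_sd", "bmi_log_sigma", "ast_noise_sd", "alt_noise_sd",
                     "shared_injury_sd", "platelets_sd", "albumin_sd", "glucose_sd",
                     "insulin_log_sd", "pro_c3_log_sd", "ck18_m30_log_sd",
                     "ck18_m65_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if len(self.nash_prob_by_stage) != 5:
            raise ValidationError("nash_prob_by_stage needs one probability per stage")
        for k, v in dict(self.missingness).items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"missingness[{k!r}] must be in [0, 1]")


PRESETS: dict[str, SyntheticCohortSpec] = {
    # bariatric/endocrinology-dominated clinic: very obese, low advanced-fibrosis
    # prevalence, neo-epitope biomarkers measured
    "overweight_obese": SyntheticCohortSpec(cohort_label="overweight_obese"),
    # retrospective hepatology cohort: leaner, younger spread, F1 heavy,
    # advanced fibrosis ~12%
    "hepatology_lean": SyntheticCohortSpec(
        stage_probs=(163 / 646, 256 / 646, 149 / 646, 58 / 646, 20 / 646),
        age_mean=48.0, age_sd=14.0, male_prob=0.62,
        bmi_log_mu=3.332, bmi_log_sigma=0.134,     # median ~28 kg/m^2
        ast_log_base=3.6, alt_log_base=4.1,        # higher enzymes
        cohort_label="hepatology_lean",
    ),
    # tertiary referral for suspected NASH: older, cirrhosis-enriched,
    # low platelets
    "elevated_risk": SyntheticCohortSpec(
        stage_probs=(25 / 213, 30 / 213, 39 / 213, 40 / 213, 79 / 213),
        age_mean=61.0, age_sd=10.0, male_prob=0.61,
        bmi_log_mu=3.395, bmi_log_sigma=0.10,      # median ~29.8 kg/m^2
        platelets_base=250.0, platelets_stage_effect=-28.0,
        cohort_label="elevated_risk",
    ),
}


def preset(name: str) -> SyntheticCohortSpec:
    """Return the documented spec for a named cohort preset (pure function)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.random(size if size is not None else np.shape(mean))
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(spec: SyntheticCohortSpec,
                    seed: int | None = None) -> list[PatientRecord]:
    """Draw a cohort of validated records, bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    stage = rng.choice(5, size=n, p=np.asarray(spec.stage_probs))
    age = _truncated_normal(rng, np.full(n, spec.age_mean), spec.age_sd,
                            *spec.age_bounds)
    male = rng.random(n) < spec.male_prob
    log_lo, log_hi = np.log(spec.bmi_bounds)
    bmi = np.exp(_truncated_normal(rng, np.full(n, spec.bmi_log_mu),
                                   spec.bmi_log_sigma, log_lo, log_hi))

    injury = rng.normal(0.0, spec.shared_injury_sd, n)
    ast = np.exp(spec.ast_log_base + spec.ast_stage_effect * stage + injury
                 + rng.normal(0.0, spec.ast_noise_sd, n))
    alt = np.exp(spec.alt_log_base + spec.alt_stage_effect * stage + injury
                 + rng.normal(0.0, spec.alt_noise_sd, n))

    platelets = _truncated_normal(
        rng, spec.platelets_base + spec.platelets_stage_effect * stage,
        spec.platelets_sd, spec.platelets_floor, np.inf)
    albumin = _truncated_normal(
        rng, spec.albumin_base + spec.albumin_stage_effect * stage,
        spec.albumin_sd, *spec.albumin_bounds)
    glucose = _truncated_normal(
        rng, spec.glucose_base + spec.glucose_stage_effect * stage,
        spec.glucose_sd, spec.glucose_floor, np.inf)
    insulin = np.exp(spec.insulin_log_base + spec.insulin_stage_effect * stage
                     + rng.normal(0.0, spec.insulin_log_sd, n))

    lin = (spec.diabetes_intercept + spec.diabetes_bmi_coef * bmi
           + spec.diabetes_stage_coef * stage)
    diabetes = rng.random(n) < 1.0 / (1.0 + np.exp(-lin))

    pro_c3 = np.exp(spec.pro_c3_log_base + spec.pro_c3_stage_effect * stage
                    + rng.normal(0.0, spec.pro_c3_log_sd, n))
    ck18_m30 = np.exp(spec.ck18_m30_log_base + spec.ck18_m30_stage_effect * stage
                      + rng.normal(0.0, spec.ck18_m30_log_sd, n))
    ck18_m65 = ck18_m30 * np.exp(spec.ck18_m65_log_offset
                                 + rng.normal(0.0, spec.ck18_m65_log_sd, n))

    p_nash = np.asarray(spec.nash_prob_by_stage)[stage]
    nash = rng.random(n) < p_nash
    # NASH implies steatosis + inflammation + ballooning, hence activity >= 3
    nas = np.where(nash, 3 + rng.binomial(5, 0.45, n), rng.binomial(4, 0.45, n))

    miss = {k: rng.random(n) < v for k, v in dict(spec.missingness).items()}

    def opt(arr, name, i, cast=float):
        if name in miss and miss[name][i]:
            return None
        return cast(arr[i])

    records = []
    for i in range(n):
        records.append(PatientRecord(
            id=f"{spec.cohort_label}-{i:05d}",
            age=float(age[i]),
            sex="male" if male[i] else "female",
            bmi=float(bmi[i]),
            ast=float(ast[i]),
            alt=float(alt[i]),
            platelets=float(platelets[i]),
            albumin=float(albumin[i]),
            glucose_fasting=opt(glucose, "glucose_fasting", i),
            insulin_fasting=opt(insulin, "insulin_fasting", i),
            diabetes=bool(diabetes[i]),
            pro_c3=opt(pro_c3, "pro_c3", i),
            ck18_m30=opt(ck18_m30, "ck18_m30", i),
            ck18_m65=opt(ck18_m65, "ck18_m65", i),
            fibrosis_stage=int(stage[i]),
            nash=bool(nash[i]),
            nas=int(nas[i]),
            cohort=spec.cohort_label,
        ))
    return records
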