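"""Composite liver-fibrosis scores from routine labs and neo-epitope markers.

Eight scores are supported:

========  =====================================================  ==========
name      inputs                                                 output
========  =====================================================  ==========
FIB4      age, AST, ALT, platelets                               real > 0
NFS       age, BMI, IFG/diabetes, AST, ALT, platelets, albumin   real
APRI      AST, AST upper limit of normal, platelets              real >= 0
BARD      BMI, AST, ALT, diabetes                                int 0-4
HFS       age, sex, AST, albumin, HOMA-IR, diabetes, platelets   (0, 1)
ADAPT     age, PRO-C3, platelets, diabetes                       real > 0
FIBC3     age, BMI, diabetes, platelets, PRO-C3                  real
MACK3     HOMA-IR, AST, CK-18 M30                                (0, 1)
========  =====================================================  ==========

Higher values indicate more advanced disease for every score. Coefficients
for HFS/ADAPT/FIBC3/MACK-3 live in a provenance-stamped YAML config
(:func:`load_coefficients`) rather than in operation logic, so the
transcription from the developer publications is auditable.

A score is *missing* (``None``) iff any required input is missing on the
record; invalid values inside the formula domain (ALT = 0, platelets = 0)
raise :class:`~fibroscreen.errors.DomainError` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cohort import PatientRecord
from .errors import ConfigurationError, DomainError

__all__ = [
    "SCORE_NAMES",
    "ScoreCoefficients",
    "load_coefficients",
    "ScorePanel",
    "fib4",
    "nfs",
    "apri",
    "bard",
    "hfs",
    "adapt",
    "fibc3",
    "mack3",
    "logistic_or_linear_score",
    "score_panel",
    "panel_dataframe",
]

SCORE_NAMES = ("FIB4", "NFS", "APRI", "BARD", "HFS", "ADAPT", "FIBC3", "MACK3")


@dataclass(frozen=True)
class ScoreCoefficients:
    """Named coefficient tables loaded from the versioned config file."""

    version: int
    tables: Mapping[str, Mapping[str, float | str]]

    def table(self, score: str) -> Mapping[str, float | str]:
        key = score.lower().replace("-", "")
        if key not in self.tables:
            raise ConfigurationError(f"no coefficient table for score {score!r}")
        return self.tables[key]

    def coef(self, score: str, name: str) -> float:
        t = self.table(score)
        if name not in t:
            raise ConfigurationError(f"coefficient {name!r} missing for {score!r}")
        v = float(t[name])
        if not math.isfinite(v):
            raise ConfigurationError(f"coefficient {score}.{name} is not finite")
        return v

    def provenance(self, score: str) -> str:
        return str(self.table(score).get("provenance", ""))


def load_coefficients(path: str | Path | None = None) -> ScoreCoefficients:
    """Load score coefficients; defaults to the bundled config."""
    if path is None:
        text = resources.files("fibroscreen.data").joinpath(
            "score_coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    version = int(raw.pop("version", 0))
    return ScoreCoefficients(version=version, tables=raw)


# ---------------------------------------------------------------------------
# Simple scores (coefficients fixed by definition)
# ---------------------------------------------------------------------------

def fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """Fibrosis-4 index: age x AST / (platelets x sqrt(ALT))."""
    if alt <= 0 or platelets <= 0:
        raise DomainError("FIB-4 requires ALT > 0 and platelets > 0")
    return age * ast / (platelets * math.sqrt(alt))


def nfs(age: float, bmi: float, ifg_or_diabetes: int, ast: float, alt: float,
        platelets: float, albumin: float,
        coeffs: ScoreCoefficients | None = None) -> float:
    """NAFLD fibrosis score (albumin in g/dL, platelets in 10^9/L)."""
    if alt <= 0:
        raise DomainError("NFS requires ALT > 0")
    c = coeffs or _DEFAULT_COEFFS
    return (c.coef("nfs", "intercept")
            + c.coef("nfs", "age") * age
            + c.coef("nfs", "bmi") * bmi
            + c.coef("nfs", "ifg_or_diabetes") * (1 if ifg_or_diabetes else 0)
            + c.coef("nfs", "ast_alt_ratio") * (ast / alt)
            + c.coef("nfs", "platelets") * platelets
            + c.coef("nfs", "albumin") * albumin)


def apri(ast: float, ast_uln: float, platelets: float) -> float:
    """AST-to-platelet ratio index: 100 x (AST/ULN) / platelets."""
    if ast_uln <= 0 or platelets <= 0:
        raise DomainError("APRI requires ULN > 0 and platelets > 0")
    return (ast / ast_uln) / platelets * 100.0


def bard(bmi: float, ast: float, alt: float, diabetes: bool) -> int:
    """BARD point score: BMI >= 28 (1 pt), AST/ALT >= 0.8 (2 pts), diabetes (1 pt)."""
    if alt <= 0:
        raise DomainError("BARD requires ALT > 0")
    points = 0
    if bmi >= 28.0:
        points += 1
    if ast / alt >= 0.8:
        points += 2
    if diabetes:
        points += 1
    return points


# ---------------------------------------------------------------------------
# Config-driven scores
# ---------------------------------------------------------------------------

def hfs(age: float, sex: str, ast: float, albumin: float, homa_ir: float,
        diabetes: bool, platelets: float,
        coeffs: ScoreCoefficients | None = None) -> float:
    """Hepamet fibrosis score (logistic output in (0, 1)).

    Categorical bands use closed lower bounds, e.g. AST 35-69 means
    35 <= AST < 70.
    """
    c = coeffs or _DEFAULT_COEFFS
    x = c.coef("hfs", "intercept")
    if 45 <= age < 65:
        x -= c.coef("hfs", "age_45_to_64")
    elif age >= 65:
        x -= c.coef("hfs", "age_ge_65")
    if sex == "male":
        x -= c.coef("hfs", "male")
    if 35 <= ast < 70:
        x -= c.coef("hfs", "ast_35_to_69")
    elif ast >= 70:
        x -= c.coef("hfs", "ast_ge_70")
    if 4.0 <= albumin < 4.5:
        x -= c.coef("hfs", "albumin_4_to_4_49")
    elif albumin < 4.0:
        x -= c.coef("hfs", "albumin_lt_4")
    if 2.0 <= homa_ir < 4.0:
        x -= c.coef("hfs", "homa_2_to_3_99")
    elif homa_ir >= 4.0:
        x -= c.coef("hfs", "homa_ge_4")
    if diabetes:
        x -= c.coef("hfs", "diabetes")
    if 155 <= platelets < 220:
        x -= c.coef("hfs", "platelets_155_to_219")
    elif platelets < 155:
        x -= c.coef("hfs", "platelets_lt_155")
    return 1.0 / (1.0 + math.exp(x))


def adapt(age: float, pro_c3: float, platelets: float, diabetes: bool,
          coeffs: ScoreCoefficients | None = None) -> float:
    """ADAPT score: exp(log10(age x PRO-C3 / sqrt(platelets)) + diabetes)."""
    if platelets <= 0:
        raise DomainError("ADAPT requires platelets > 0")
    if pro_c3 <= 0 or age <= 0:
        raise DomainError("ADAPT requires age > 0 and PRO-C3 > 0")
    c = coeffs or _DEFAULT_COEFFS
    x = math.log10(age * pro_c3 / math.sqrt(platelets))
    if diabetes:
        x += c.coef("adapt", "diabetes")
    return math.exp(x)


def fibc3(age: float, bmi: float, diabetes: bool, platelets: float,
          pro_c3: float, coeffs: ScoreCoefficients | None = None) -> float:
    """FIB-C3 linear score incorporating PRO-C3."""
    c = coeffs or _DEFAULT_COEFFS
    return (c.coef("fibc3", "intercept")
            + c.coef("fibc3", "age") * age
            + c.coef("fibc3", "bmi") * bmi
            + c.coef("fibc3", "diabetes") * (1 if diabetes else 0)
            + c.coef("fibc3", "platelets") * platelets
            + c.coef("fibc3", "pro_c3") * pro_c3)


def mack3(homa_ir: float, ast: float, ck18_m30: float,
          coeffs: ScoreCoefficients | None = None) -> float:
    """MACK-3 logistic score for fibrotic NASH (HOMA-IR, AST, CK-18 M30).

    The bundled coefficients are a reconstructed surrogate for the developer
    model (see the coefficient config provenance); the functional form and
    monotone sign structure follow the published score.
    """
    c = coeffs or _DEFAULT_COEFFS
    x = (c.coef("mack3", "intercept")
         + c.coef("mack3", "homa_ir") * homa_ir
         + c.coef("mack3", "ast") * ast
         + c.coef("mack3", "ck18_m30") * ck18_m30)
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Record-level dispatch and the full panel
# ---------------------------------------------------------------------------

def _maybe(values: Sequence[object]) -> bool:
    return all(v is not None for v in values)


def logistic_or_linear_score(name: str, record: PatientRecord,
                             coeffs: ScoreCoefficients | None = None) -> float | None:
    """Evaluate one of the config-driven scores on a record.

    Returns ``None`` when a required input is missing; raises
    :class:`ConfigurationError` for an unknown score name.
    """
    c = coeffs or _DEFAULT_COEFFS
    key = name.upper().replace("-", "")
    if key == "HFS":
        h = record.homa_ir
        if h is None:
            return None
        return hfs(record.age, record.sex, record.ast, record.albumin, h,
                   record.diabetes, record.platelets, c)
    if key == "ADAPT":
        if record.pro_c3 is None:
            return None
        return adapt(record.age, record.pro_c3, record.platelets,
                     record.diabetes, c)
    if key == "FIBC3":
        if record.pro_c3 is None:
            return None
        return fibc3(record.age, record.bmi, record.diabetes,
                     record.platelets, record.pro_c3, c)
    if key == "MACK3":
        h = record.homa_ir
        if h is None or record.ck18_m30 is None:
            return None
        return mack3(h, record.ast, record.ck18_m30, c)
    raise ConfigurationError(f"unknown score name {name!r}")


@dataclass(frozen=True)
class ScorePanel:
    """The eight composite scores for one subject, missing-aware."""

    id: str
    FIB4: float | None
    NFS: float | None
    APRI: float | None
    BARD: int | None
    HFS: float | None
    ADAPT: float | None
    FIBC3: float | None
    MACK3: float | None
    # raw passthroughs for the direct biomarkers
    pro_c3: float | None = None
    ck18_m30: float | None = None
    ck18_m65: float | None = None

    def value(self, name: str) -> float | None:
        return getattr(self, name.upper().replace("-", ""))


def score_panel(record: PatientRecord,
                coeffs: ScoreCoefficients | None = None) -> ScorePanel:
    """Compute all eight scores, propagating missing inputs to missing scores."""
    c = coeffs or _DEFAULT_COEFFS
    return ScorePanel(
        id=record.id,
        FIB4=fib4(record.age, record.ast, record.alt, record.platelets),
        NFS=nfs(record.age, record.bmi, record.ifg_or_diabetes, record.ast,
                record.alt, record.platelets, record.albumin, c),
        APRI=apri(record.ast, c.coef("apri", "ast_uln"), record.platelets),
        BARD=bard(record.bmi, record.ast, record.alt, record.diabetes),
        HFS=logistic_or_linear_score("HFS", record, c),
        ADAPT=logistic_or_linear_score("ADAPT", record, c),
        FIBC3=logistic_or_linear_score("FIBC3", record, c),
        MACK3=logistic_or_linear_score("MACK3", record, c),
        pro_c3=record.pro_c3,
        ck18_m30=record.ck18_m30,
        ck18_m65=record.ck18_m65,
    )


def panel_dataframe(records: Sequence[PatientRecord],
                    coeffs: ScoreCoefficients | None = None):
    """Score a whole cohort; one row per record, NaN for missing scores."""
    import pandas as pd

    panels = [score_panel(r, coeffs) for r in records]
    return pd.DataFrame([vars(p) for p in panels])


_DEFAULT_COEFFS = load_coefficients()
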