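"""Patient records, target conditions, and cohort file I/O.

Canonical units
---------------
Every :class:`PatientRecord` stores laboratory values in the units the
composite fibrosis scores are defined on:

* albumin: g/dL (clinical chemistry often reports g/L; divide by 10)
* platelets: 10^9/L
* fasting glucose: mmol/L (mg/dL divides by 18.016)
* fasting insulin: mU/L
* AST / ALT: U/L

The CSV reader performs declared conversions so that downstream score
formulae never need to know the source units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

__all__ = [
    "PatientRecord",
    "TargetCondition",
    "TARGET_CONDITIONS",
    "CohortReadResult",
    "RejectedRow",
    "read_cohort",
    "write_cohort",
    "cohort_to_dataframe",
    "compute_homa_ir",
    "IFG_GLUCOSE_THRESHOLD",
]

#: Fasting glucose (mmol/L) at or above which impaired fasting glucose is
#: flagged when no explicit IFG indicator is available (ADA criterion,
#: 100 mg/dL). The NFS formula needs an IFG-or-diabetes indicator.
IFG_GLUCOSE_THRESHOLD = 5.6

_GLUCOSE_MGDL_PER_MMOL = 18.016


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics, labs, biomarkers and histology.

    Optional fields use ``None`` as the explicit missing marker; a missing
    input silently propagates to a missing score downstream, never to zero.
    """

    id: str
    age: float                      # years
    sex: str                        # "male" | "female"
    bmi: float                      # kg/m^2
    ast: float                      # U/L
    alt: float                      # U/L
    platelets: float                # 10^9/L
    albumin: float                  # g/dL
    glucose_fasting: float | None = None   # mmol/L
    insulin_fasting: float | None = None   # mU/L
    diabetes: bool = False
    ifg: bool | None = None
    pro_c3: float | None = None     # ng/mL
    ck18_m30: float | None = None   # U/L
    ck18_m65: float | None = None   # U/L
    fibrosis_stage: int | None = None      # ordinal 0-4
    nash: bool | None = None
    nas: int | None = None          # NAFLD activity score 0-8
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValidationError(f"age must be > 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.bmi > 0:
            raise ValidationError(f"bmi must be > 0, got {self.bmi}")
        if self.ast < 0 or self.alt < 0:
            raise ValidationError("AST and ALT must be >= 0")
        if not self.platelets > 0:
            raise ValidationError(f"platelets must be > 0, got {self.platelets}")
        if not self.albumin > 0:
            raise ValidationError(f"albumin must be > 0, got {self.albumin}")
        if self.fibrosis_stage is not None and self.fibrosis_stage not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"fibrosis_stage must be in 0..4, got {self.fibrosis_stage}"
            )
        if self.nas is not None and not 0 <= self.nas <= 8:
            raise ValidationError(f"nas must be in 0..8, got {self.nas}")
        for name in ("glucose_fasting", "insulin_fasting", "pro_c3", "ck18_m30", "ck18_m65"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def ifg_or_diabetes(self) -> bool:
        """Indicator used by NFS: impaired fasting glucose or diabetes.

        Falls back on the fasting-glucose criterion when no explicit IFG
        flag is present and glucose is available.
        """
        if self.diabetes:
            return True
        if self.ifg is not None:
            return self.ifg
        if self.glucose_fasting is not None:
            return self.glucose_fasting >= IFG_GLUCOSE_THRESHOLD
        return False

    @property
    def homa_ir(self) -> float | None:
        """HOMA-IR from fasting glucose and insulin; None if either missing."""
        if self.glucose_fasting is None or self.insulin_fasting is None:
            return None
        return compute_homa_ir(self.glucose_fasting, self.insulin_fasting)


def compute_homa_ir(glucose_fasting: float, insulin_fasting: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = glucose (mmol/L) x insulin (mU/L) / 22.5.
    """
    if glucose_fasting < 0 or insulin_fasting < 0:
        raise DomainError("glucose and insulin must be >= 0 for HOMA-IR")
    return glucose_fasting * insulin_fasting / 22.5


# ---------------------------------------------------------------------------
# Target conditions (histological reference standard)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetCondition:
    """A binary histological endpoint defined over a PatientRecord.

    ``predicate`` returns True/False, or None when the record lacks the
    histology needed to evaluate the condition.
    """

    name: str
    predicate: Callable[[PatientRecord], bool | None]

    def __call__(self, record: PatientRecord) -> bool | None:
        return self.predicate(record)

    def labels(self, records: Iterable[PatientRecord]) -> list[bool | None]:
        return [self(r) for r in records]


def _advanced(r: PatientRecord) -> bool | None:
    return None if r.fibrosis_stage is None else r.fibrosis_stage >= 3


def _significant(r: PatientRecord) -> bool | None:
    return None if r.fibrosis_stage is None else r.fibrosis_stage >= 2


def _fibrotic_nash(r: PatientRecord) -> bool | None:
    # NASH with activity score >= 4 and at least significant (>=F2) fibrosis.
    if r.nash is None or r.fibrosis_stage is None:
        return None
    if not r.nash:
        return False
    if r.nas is None:
        return None
    return r.nas >= 4 and r.fibrosis_stage >= 2


TARGET_CONDITIONS: dict[str, TargetCondition] = {
    "advanced_fibrosis": TargetCondition("advanced_fibrosis", _advanced),
    "significant_fibrosis": TargetCondition("significant_fibrosis", _significant),
    "fibrotic_nash": TargetCondition("fibrotic_nash", _fibrotic_nash),
}


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

#: canonical field -> supported source units and the factor that converts
#: a value in that unit to the canonical unit.
_UNIT_CONVERSIONS: dict[str, dict[str, float]] = {
    "albumin": {"g/dL": 1.0, "g/dl": 1.0, "g/L": 0.1, "g/l": 0.1},
    "glucose_fasting": {
        "mmol/L": 1.0, "mmol/l": 1.0,
        "mg/dL": 1.0 / _GLUCOSE_MGDL_PER_MMOL, "mg/dl": 1.0 / _GLUCOSE_MGDL_PER_MMOL,
    },
}

_MANDATORY = ("id", "age", "sex", "bmi", "ast", "alt", "platelets", "albumin")
_OPTIONAL_NUMERIC = (
    "glucose_fasting", "insulin_fasting", "pro_c3", "ck18_m30", "ck18_m65",
)
_BOOL_TRUE = {"1", "true", "yes", "y", "t"}
_BOOL_FALSE = {"0", "false", "no", "n", "f"}


@dataclass(frozen=True)
class RejectedRow:
    index: int
    reason: str


@dataclass
class CohortReadResult:
    records: list[PatientRecord]
    rejected: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def _parse_float(value, name: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric value {value!r} in field {name!r}") from None


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> CohortReadResult:
    """Read a patient table, validate rows, and canonicalize units.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping of canonical field name -> column name in the file.
        Fields absent from the mapping are looked up under their canonical
        name.
    units
        Optional mapping of canonical field name -> unit of the source column
        (e.g. ``{"albumin": "g/L"}``). Unlisted fields are assumed canonical;
        conversion of an already-canonical column is the identity.

    Returns
    -------
    CohortReadResult
        Validated records plus rejected rows with index and reason. Missing
        optional fields are stored as ``None``, never coerced to zero.
    """
    schema = dict(schema or {})
    units = dict(units or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    def column(fld: str) -> str:
        return schema.get(fld, fld)

    for fld in _MANDATORY:
        if column(fld) not in df.columns:
            raise SchemaError(f"mandatory column {column(fld)!r} (field {fld!r}) missing")

    for fld, unit in units.items():
        table = _UNIT_CONVERSIONS.get(fld)
        if table is None or unit not in table:
            raise SchemaError(f"no declared conversion for field {fld!r} from unit {unit!r}")

    records: list[PatientRecord] = []
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, column, units, df.columns))
        except (ValidationError, DomainError) as exc:
            rejected.append(RejectedRow(int(idx), str(exc)))
    return CohortReadResult(records, rejected)


def _get(row, col: str, columns) -> str | None:
    if col not in columns:
        return None
    v = str(row[col]).strip()
    return v if v not in ("", "NA", "NaN", "nan", "None") else None


def _row_to_record(row, column, units, columns) -> PatientRecord:
    def convert(fld: str, value: float) -> float:
        unit = units.get(fld)
        if unit is None:
            return value
        return value * _UNIT_CONVERSIONS[fld][unit]

    kwargs: dict = {}
    for fld in _MANDATORY:
        raw = _get(row, column(fld), columns)
        if raw is None:
            raise ValidationError(f"mandatory field {fld!r} empty")
        if fld == "id":
            kwargs["id"] = raw
        elif fld == "sex":
            s = raw.lower()
            if s in ("m", "male"):
                s = "male"
            elif s in ("f", "female"):
                s = "female"
            kwargs["sex"] = s
        else:
            kwargs[fld] = convert(fld, _parse_float(raw, fld))

    for fld in _OPTIONAL_NUMERIC:
        raw = _get(row, column(fld), columns)
        kwargs[fld] = None if raw is None else convert(fld, _parse_float(raw, fld))

    for fld in ("diabetes", "ifg", "nash"):
        raw = _get(row, column(fld), columns)
        if raw is not None:
            kwargs[fld] = _parse_bool(raw)
        elif fld == "diabetes":
            kwargs[fld] = False

    for fld in ("fibrosis_stage", "nas"):
        raw = _get(row, column(fld), columns)
        if raw is not None:
            v = _parse_float(raw, fld)
            if not float(v).is_integer():
                raise ValidationError(f"{fld} must be an integer, got {raw!r}")
            kwargs[fld] = int(v)

    raw = _get(row, column("cohort"), columns)
    if raw is not None:
        kwargs["cohort"] = raw
    return PatientRecord(**kwargs)


def cohort_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate records in canonical units (booleans as 0/1 integers)."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(PatientRecord)}
        for b in ("diabetes", "ifg", "nash"):
            if d[b] is not None:
                d[b] = int(d[b])
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to CSV in canonical units (round-trips with read_cohort)."""
    df = cohort_to_dataframe(records)
    df.to_csv(path, index=False, float_format="%.17g")
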