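"""Composite cardiovascular / cognitive risk scoring.

Each subject accumulates one point per present risk factor:

* cardiovascular (0-5): diabetes, hypertension, dyslipidemia, active
  smoking, obesity;
* cognitive (0-2): depression risk (GDS > 9) and lower education
  (below baccalaureate);
* combined (0-7): their sum — the "potentially modifiable" risk profile.

Thresholds are applied exactly as defined for the cohort: glycemia
> 1.26 g/L, blood pressure >= 140 mmHg systolic / >= 90 mmHg diastolic,
cholesterol > 2.5 mmol/L, BMI > 30, GDS > 9 — strict or inclusive as
written.  Amyloid positivity is a strict GCI > 1.45.

APOE epsilon-4 carriage is a non-modifiable risk factor: it may be carried
in the tables but never enters any composite score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd

from .errors import MissingDataError, ValidationError

__all__ = [
    "ClinicalRecord",
    "RiskProfile",
    "CARDIOVASCULAR_FLAGS",
    "COGNITIVE_FLAGS",
    "score_cardiovascular",
    "score_cognitive",
    "combine_risk",
    "classify_amyloid",
    "score_record",
    "score_cohort",
]

#: names of the five cardiovascular flags, in scoring order
CARDIOVASCULAR_FLAGS = ("diabetes", "hypertension", "dyslipidemia", "smoking", "obesity")
#: names of the two cognitive flags
COGNITIVE_FLAGS = ("depression_risk", "low_education")

_NUMERIC_FIELDS = ("age", "sbp", "dbp", "glycemia", "cholesterol", "bmi", "gds")
_BOOLEAN_FIELDS = (
    "active_smoker",
    "self_reported_diabetes",
    "antidiabetic_drug",
    "self_reported_hypertension",
    "antihypertensive_drug",
    "self_reported_hypercholesterolemia",
    "lipid_lowering_drug",
    "high_education",
)


@dataclass
class ClinicalRecord:
    """Raw per-subject clinical and demographic fields feeding risk scoring."""

    subject_id: str
    age: float  # years, 50-70 at inclusion
    gender: str  # "female" | "male"
    sbp: float  # mmHg
    dbp: float  # mmHg
    glycemia: float  # g/L
    cholesterol: float  # mmol/L
    bmi: float  # kg/m^2
    active_smoker: Optional[bool]
    self_reported_diabetes: Optional[bool]
    antidiabetic_drug: Optional[bool]
    self_reported_hypertension: Optional[bool]
    antihypertensive_drug: Optional[bool]
    self_reported_hypercholesterolemia: Optional[bool]
    lipid_lowering_drug: Optional[bool]
    gds: Optional[float]  # Geriatric Depression Scale score
    high_education: Optional[bool]  # baccalaureate or higher

    def validate(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValidationError(f"gender must be 'female'/'male', got {self.gender!r}")
        for name in ("age", "sbp", "dbp", "glycemia", "cholesterol", "bmi"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                raise MissingDataError(f"field {name!r} missing for subject {self.subject_id}")
        if not 50 <= self.age <= 70:
            raise ValidationError(f"age {self.age} outside [50, 70] for {self.subject_id}")
        if not self.sbp > self.dbp > 0:
            raise ValidationError(
                f"blood pressure must satisfy sbp > dbp > 0, got {self.sbp}/{self.dbp}"
            )
        if self.bmi <= 0:
            raise ValidationError(f"bmi must be positive, got {self.bmi}")
        if self.gds is not None and self.gds < 0:
            raise ValidationError(f"gds must be >= 0, got {self.gds}")


@dataclass
class RiskProfile:
    """Binary risk flags and the three composite scores for one subject."""

    subject_id: str
    flags: dict = field(default_factory=dict)
    cardiovascular: int = 0
    cognitive: int = 0
    combined: int = 0


def _require_bool(rec: ClinicalRecord, name: str, assume_absent: bool) -> bool:
    v = getattr(rec, name)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        if assume_absent:
            return False
        raise MissingDataError(f"field {name!r} missing for subject {rec.subject_id}")
    return bool(v)


def score_cardiovascular(
    rec: ClinicalRecord,
    hypertension_rule: str = "or",
    assume_absent_when_missing: bool = False,
) -> RiskProfile:
    """Count the five cardiovascular risk flags for one subject.

    Each flag fires when ANY of its OR-clauses holds.  ``hypertension_rule``
    selects how the blood-pressure clause combines the systolic and
    diastolic thresholds: ``"or"`` (default; one elevated measurement
    suffices) or ``"and"`` (both must be elevated).
    """
    if hypertension_rule not in ("or", "and"):
        raise ValidationError(f"hypertension_rule must be 'or'/'and', got {hypertension_rule!r}")
    rec.validate()
    b = lambda name: _require_bool(rec, name, assume_absent_when_missing)

    if hypertension_rule == "or":
        bp_high = rec.sbp >= 140 or rec.dbp >= 90
    else:
        bp_high = rec.sbp >= 140 and rec.dbp >= 90

    flags = {
        "diabetes": rec.glycemia > 1.26 or b("self_reported_diabetes") or b("antidiabetic_drug"),
        "hypertension": b("antihypertensive_drug") or b("self_reported_hypertension") or bp_high,
        "dyslipidemia": rec.cholesterol > 2.5
        or b("self_reported_hypercholesterolemia")
        or b("lipid_lowering_drug"),
        "smoking": b("active_smoker"),
        "obesity": rec.bmi > 30,
    }
    score = sum(flags[k] for k in CARDIOVASCULAR_FLAGS)
    return RiskProfile(rec.subject_id, flags=flags, cardiovascular=score)


def score_cognitive(rec: ClinicalRecord, assume_absent_when_missing: bool = False) -> RiskProfile:
    """Count the two cognitive risk flags: GDS > 9 and lower education."""
    if rec.gds is None or (isinstance(rec.gds, float) and not math.isfinite(rec.gds)):
        raise MissingDataError(f"field 'gds' missing for subject {rec.subject_id}")
    flags = {
        "depression_risk": rec.gds > 9,
        "low_education": not _require_bool(rec, "high_education", assume_absent_when_missing),
    }
    return RiskProfile(rec.subject_id, flags=flags, cognitive=sum(flags.values()))


def combine_risk(cardiovascular: int, cognitive: int) -> int:
    """Sum the two composites into the combined modifiable-risk score (0-7)."""
    if not (isinstance(cardiovascular, (int,)) and 0 <= cardiovascular <= 5):
        raise ValidationError(f"cardiovascular score must be an int in [0, 5], got {cardiovascular!r}")
    if not (isinstance(cognitive, (int,)) and 0 <= cognitive <= 2):
        raise ValidationError(f"cognitive score must be an int in [0, 2], got {cognitive!r}")
    return cardiovascular + cognitive


def classify_amyloid(gci: float) -> bool:
    """Amyloid positivity: global cortical index strictly above 1.45."""
    if gci is None or not math.isfinite(gci) or gci <= 0:
        raise ValidationError(f"gci must be a positive finite number, got {gci!r}")
    return gci > 1.45


def score_record(rec: ClinicalRecord, **kwargs) -> RiskProfile:
    """Full risk profile (flags + three composites) for one subject."""
    cv = score_cardiovascular(rec, **kwargs)
    cog = score_cognitive(rec, assume_absent_when_missing=kwargs.get("assume_absent_when_missing", False))
    flags = {**cv.flags, **cog.flags}
    return RiskProfile(
        rec.subject_id,
        flags=flags,
        cardiovascular=cv.cardiovascular,
        cognitive=cog.cognitive,
        combined=combine_risk(cv.cardiovascular, cog.cognitive),
    )


def record_from_row(row: pd.Series) -> ClinicalRecord:
    """Build a :class:`ClinicalRecord` from one clinical-table row."""
    kwargs = {}
    for f in fields(ClinicalRecord):
        if f.name not in row.index:
            raise MissingDataError(f"clinical table lacks column {f.name!r}")
        v = row[f.name]
        if f.name in _BOOLEAN_FIELDS and v is not None and not (
            isinstance(v, float) and math.isnan(v)
        ):
            v = bool(v)
        kwargs[f.name] = v
    return ClinicalRecord(**kwargs)


def score_cohort(clinical: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Score every row of a clinical table.

    Returns one row per subject: ``subject_id``, the seven flags and the
    ``cardiovascular`` / ``cognitive`` / ``combined`` composites.
    """
    out = []
    for _, row in clinical.iterrows():
        p = score_record(record_from_row(row), **kwargs)
        out.append(
            {
                "subject_id": p.subject_id,
                **{k: bool(v) for k, v in p.flags.items()},
                "cardiovascular": p.cardiovascular,
                "cognitive": p.cognitive,
                "combined": p.combined,
            }
        )
    return pd.DataFrame(out)
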