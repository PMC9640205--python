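"""Domain vocabulary, record types, and payload validation.

The surveillance protocol collects three submission stages per respondent:

1. a one-off medical history questionnaire (demographics + chronic diseases),
2. a vaccination record after each vaccine administration,
3. an adverse-drug-reaction (ADR) report solicited seven days after each dose.

All three are keyed by a pseudonymous respondent identifier (see
:mod:`adrlong.identity`).  Vocabularies are closed sets: ten chronic
conditions, twelve post-vaccination symptoms, four vaccine products.

Validation is *total*: every payload either yields a validated record or a
non-empty list of field-level errors, never both.  Errors are reported as
``FieldError(field, message)`` so a transport layer can return them verbatim
as ``{field, message}`` JSON objects.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Any, Mapping, Optional, Sequence

__all__ = [
    "CHRONIC_CONDITIONS",
    "SYMPTOMS",
    "VACCINES",
    "INSTITUTIONS",
    "GENDERS",
    "LEGAL_AGE",
    "StudyWindow",
    "DEFAULT_STUDY_WINDOW",
    "FieldError",
    "PayloadError",
    "MedicalHistory",
    "VaccinationRecord",
    "AdrReport",
    "validate_medical_history",
    "validate_vaccination",
    "validate_adr",
]

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

#: Chronic diseases offered by the medical-history questionnaire (closed set).
CHRONIC_CONDITIONS: tuple[str, ...] = (
    "dyslipidemia",
    "hypertension",
    "autoimmune diseases",
    "asthma",
    "cardiovascular diseases",
    "tumor",
    "liver diseases",
    "diabetes",
    "bronchitis",
    "kidney disease",
)

#: Post-vaccination symptoms offered by the ADR questionnaire (closed set),
#: following the CDC/WHO checklist of recognized COVID-19 vaccine side effects.
SYMPTOMS: tuple[str, ...] = (
    "fever",
    "headache",
    "injection site pain",
    "tiredness",
    "muscular pain",
    "swollen lymph nodes",
    "joint pain",
    "paresthesia",
    "dizziness",
    "sleepiness",
    "nausea",
    "abdominal pain",
)

#: Vaccine products administered during the campaign (closed set).
VACCINES: tuple[str, ...] = ("Vaxzevria", "Comirnaty", "moderna-mRNA1273", "Janssen")

INSTITUTIONS: tuple[str, ...] = ("UniMiB", "PoliMi")
GENDERS: tuple[str, ...] = ("male", "female")

#: Participants confirm legal age before submitting anything.
LEGAL_AGE = 18


@dataclass(frozen=True)
class StudyWindow:
    """Calendar window inside which vaccination dates are accepted."""

    start: dt.date
    end: dt.date

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


#: Default campaign window: report collection opened 2021-01-01 and the
#: system was switched off on 2022-02-09.
DEFAULT_STUDY_WINDOW = StudyWindow(dt.date(2021, 1, 1), dt.date(2022, 2, 9))


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldError:
    field: str
    message: str


class PayloadError(ValueError):
    """Raised when a submission payload fails validation.

    Carries the full field-level error list so callers can surface every
    problem at once rather than the first one encountered.
    """

    def __init__(self, errors: Sequence[FieldError]):
        self.errors: tuple[FieldError, ...] = tuple(errors)
        super().__init__("; ".join(f"{e.field}: {e.message}" for e in self.errors))


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MedicalHistory:
    """One-off demographic and chronic-disease questionnaire.

    At most one per respondent; ``conditions`` is a duplicate-free subset of
    :data:`CHRONIC_CONDITIONS`, stored in canonical vocabulary order.
    """

    respondent_id: str
    institution: str
    gender: str
    age: int
    conditions: tuple[str, ...]
    submitted_at: Optional[dt.datetime] = None

    def to_payload(self) -> dict[str, Any]:
        return {
            "institution": self.institution,
            "gender": self.gender,
            "age": self.age,
            "conditions": list(self.conditions),
            "submitted_at": _iso(self.submitted_at),
        }


@dataclass(frozen=True)
class VaccinationRecord:
    """One vaccine administration: product, site, and calendar date."""

    respondent_id: str
    vaccine: str
    site: str
    administered_at: dt.date
    submitted_at: Optional[dt.datetime] = None

    def to_payload(self) -> dict[str, Any]:
        return {
            "vaccine": self.vaccine,
            "site": self.site,
            "administered_at": self.administered_at.isoformat(),
            "submitted_at": _iso(self.submitted_at),
        }


@dataclass(frozen=True)
class AdrReport:
    """Symptoms observed in the seven days following one vaccination.

    An empty symptom set is a valid (asymptomatic) report — "no symptoms" is
    itself an outcome class in the longitudinal analysis.  ``dose_ref`` is
    assigned by curation, never by the submitting client.
    """

    respondent_id: str
    symptoms: tuple[str, ...]
    dose_ref: Optional[int] = None
    submitted_at: Optional[dt.datetime] = None

    def to_payload(self) -> dict[str, Any]:
        return {
            "symptoms": list(self.symptoms),
            "submitted_at": _iso(self.submitted_at),
        }


# ---------------------------------------------------------------------------
# Payload parsing helpers
# ---------------------------------------------------------------------------


def _iso(ts: Optional[dt.datetime]) -> Optional[str]:
    return None if ts is None else ts.isoformat()


def _parse_date(value: Any) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value)
    raise ValueError(f"not a date: {value!r}")


def _parse_datetime(value: Any) -> dt.datetime:
    if isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.date):
        return dt.datetime(value.year, value.month, value.day)
    if isinstance(value, str):
        return dt.datetime.fromisoformat(value)
    raise ValueError(f"not a timestamp: {value!r}")


def _canonical_subset(
    values: Any, vocabulary: Sequence[str], field_name: str, errors: list[FieldError]
) -> tuple[str, ...]:
    """Deduplicate and order ``values`` by vocabulary order; report unknowns."""
    if values is None:
        values = []
    if isinstance(values, str) or not isinstance(values, (list, tuple, set, frozenset)):
        errors.append(FieldError(field_name, "expected a list of labels"))
        return ()
    seen: list[str] = []
    for v in values:
        if v not in vocabulary:
            errors.append(FieldError(field_name, f"unknown {field_name[:-1]} label: {v!r}"))
        elif v not in seen:
            seen.append(v)
    return tuple(sorted(seen, key=vocabulary.index))


def _optional_submitted_at(
    payload: Mapping[str, Any], errors: list[FieldError]
) -> Optional[dt.datetime]:
    raw = payload.get("submitted_at")
    if raw is None:
        return None
    try:
        return _parse_datetime(raw)
    except ValueError:
        errors.append(FieldError("submitted_at", f"invalid timestamp: {raw!r}"))
        return None


# ---------------------------------------------------------------------------
# Validators
# ---------------------------------------------------------------------------


def validate_medical_history(
    payload: Mapping[str, Any], respondent_id: str = ""
) -> MedicalHistory:
    """Validate a medical-history payload.

    Raises :class:`PayloadError` with one entry per offending field.  Age
    below :data:`LEGAL_AGE` is rejected (participants confirm legal age);
    no upper age bound is enforced.
    """
    errors: list[FieldError] = []

    institution = payload.get("institution")
    if institution is None:
        errors.append(FieldError("institution", "missing field"))
    elif institution not in INSTITUTIONS:
        errors.append(FieldError("institution", f"unknown institution: {institution!r}"))

    gender = payload.get("gender")
    if gender is None:
        errors.append(FieldError("gender", "missing field"))
    elif gender not in GENDERS:
        errors.append(FieldError("gender", f"unknown gender: {gender!r}"))

    age_raw = payload.get("age")
    age = -1
    if age_raw is None:
        errors.append(FieldError("age", "missing field"))
    else:
        try:
            age = int(age_raw)
        except (TypeError, ValueError):
            errors.append(FieldError("age", f"not an integer: {age_raw!r}"))
        else:
            if age < LEGAL_AGE:
                errors.append(FieldError("age", "age below legal age"))

    conditions = _canonical_subset(
        payload.get("conditions"), CHRONIC_CONDITIONS, "conditions", errors
    )
    submitted_at = _optional_submitted_at(payload, errors)

    if errors:
        raise PayloadError(errors)
    return MedicalHistory(
        respondent_id=respondent_id,
        institution=str(institution),
        gender=str(gender),
        age=age,
        conditions=conditions,
        submitted_at=submitted_at,
    )


def validate_vaccination(
    payload: Mapping[str, Any],
    respondent_id: str = "",
    window: StudyWindow = DEFAULT_STUDY_WINDOW,
) -> VaccinationRecord:
    """Validate a vaccination payload against the vaccine vocabulary and the
    study window.  ``administered_at`` may not postdate ``submitted_at``."""
    errors: list[FieldError] = []

    vaccine = payload.get("vaccine")
    if vaccine is None:
        errors.append(FieldError("vaccine", "missing field"))
    elif vaccine not in VACCINES:
        errors.append(FieldError("vaccine", f"unknown vaccine: {vaccine!r}"))

    site = str(payload.get("site", ""))

    administered_at: Optional[dt.date] = None
    raw_date = payload.get("administered_at")
    if raw_date is None:
        errors.append(FieldError("administered_at", "missing field"))
    else:
        try:
            administered_at = _parse_date(raw_date)
        except ValueError:
            errors.append(FieldError("administered_at", f"invalid date: {raw_date!r}"))

    submitted_at = _optional_submitted_at(payload, errors)

    if administered_at is not None:
        if administered_at not in window:
            errors.append(FieldError("administered_at", "date outside study window"))
        if submitted_at is not None and administered_at > submitted_at.date():
            errors.append(
                FieldError("administered_at", "date is in the future relative to submission")
            )

    if errors:
        raise PayloadError(errors)
    assert administered_at is not None
    return VaccinationRecord(
        respondent_id=respondent_id,
        vaccine=str(vaccine),
        site=site,
        administered_at=administered_at,
        submitted_at=submitted_at,
    )


def validate_adr(payload: Mapping[str, Any], respondent_id: str = "") -> AdrReport:
    """Validate an ADR payload; symptoms are deduplicated (set semantics)."""
    errors: list[FieldError] = []
    symptoms = _canonical_subset(payload.get("symptoms"), SYMPTOMS, "symptoms", errors)
    submitted_at = _optional_submitted_at(payload, errors)
    if errors:
        raise PayloadError(errors)
    return AdrReport(
        respondent_id=respondent_id, symptoms=symptoms, submitted_at=submitted_at
    )


def stamp(record, submitted_at: dt.datetime):
    """Return a copy of a record with ``submitted_at`` set (server clock)."""
    return replace(record, submitted_at=submitted_at)
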