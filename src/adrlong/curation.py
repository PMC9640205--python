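"""Curation: raw store export → analysis dataset.

Assembles per-respondent timelines from the three exported tables, applies
the consistency rules below in order (logging every discard), and labels
retained vaccinations with ordinal dose numbers.

Consistency rules
-----------------
R1  Drop vaccinations for respondents with no medical history on file.
R2  Among vaccinations sharing a calendar date, keep the earliest-submitted
    and drop the rest.
R3  Scanning in submission order, drop any vaccination whose date is ≤ the
    date of an already-retained earlier vaccination.
R4  Drop ADR reports submitted before the respondent's first retained
    vaccination date.
R5  Drop ADR reports in excess of the number of retained vaccinations
    (earliest reports are kept).

The published analysis states only that inconsistent submissions were
discarded after inspection; R1–R5 codify the minimal consistency that the
staged protocol and one-report-per-dose structure require, so that the
filtering is reproducible.

Dose labeling is ordinal: retained vaccinations sorted by administration
date receive dose 1, 2, 3, …; the k-th retained ADR report (by submission
time) is attributed to dose k, because the protocol solicits exactly one ADR
questionnaire per vaccination.  Doses beyond 3 are labeled but flagged
out-of-study.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .core_model import (
    DEFAULT_STUDY_WINDOW,
    AdrReport,
    MedicalHistory,
    StudyWindow,
    VaccinationRecord,
    validate_adr,
    validate_medical_history,
    validate_vaccination,
)

__all__ = [
    "MAX_STUDY_DOSES",
    "LabeledVaccination",
    "LabeledAdr",
    "DiscardEntry",
    "Timeline",
    "AnalysisDataset",
    "read_export",
    "assemble",
    "consistency_filter",
    "label_doses",
    "build_dataset",
]

#: The campaign comprised three dose waves; later doses are out-of-study.
MAX_STUDY_DOSES = 3

_FAR_FUTURE = dt.datetime(9999, 1, 1)


@dataclass(frozen=True)
class LabeledVaccination:
    record_id: int
    record: VaccinationRecord
    dose: Optional[int] = None
    out_of_study: bool = False


@dataclass(frozen=True)
class LabeledAdr:
    record_id: int
    record: AdrReport  # dose_ref carries the attributed dose after labeling


@dataclass(frozen=True)
class DiscardEntry:
    table: str
    record_id: int
    respondent_id: str
    rule: str
    reason: str


@dataclass
class Timeline:
    """All curated material for one respondent."""

    respondent_id: str
    history: Optional[MedicalHistory] = None
    vaccinations: list[LabeledVaccination] = field(default_factory=list)
    adr_reports: list[LabeledAdr] = field(default_factory=list)

    def vaccination_for_dose(self, dose: int) -> Optional[LabeledVaccination]:
        for v in self.vaccinations:
            if v.dose == dose:
                return v
        return None

    def adr_for_dose(self, dose: int) -> Optional[LabeledAdr]:
        for a in self.adr_reports:
            if a.record.dose_ref == dose:
                return a
        return None


@dataclass
class AnalysisDataset:
    """Curated, dose-labeled timelines plus the discard log."""

    timelines: list[Timeline]
    discard_log: list[DiscardEntry]

    def discard_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for entry in self.discard_log:
            counts[entry.rule] = counts.get(entry.rule, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """One row per respondent × dose: history fields, vaccine, symptom flags."""
        from .core_model import SYMPTOMS

        rows = []
        for tl in self.timelines:
            if tl.history is None:
                continue
            h = tl.history
            doses = sorted(
                {v.dose for v in tl.vaccinations if v.dose is not None}
                | {a.record.dose_ref for a in tl.adr_reports if a.record.dose_ref}
            )
            for d in doses:
                vax = tl.vaccination_for_dose(d)
                adr = tl.adr_for_dose(d)
                row = {
                    "respondent_id": tl.respondent_id,
                    "institution": h.institution,
                    "gender": h.gender,
                    "age": h.age,
                    "conditions": ";".join(h.conditions),
                    "dose": d,
                    "out_of_study": bool(vax.out_of_study) if vax else False,
                    "vaccine": vax.record.vaccine if vax else "",
                    "administered_at": (
                        vax.record.administered_at.isoformat() if vax else ""
                    ),
                    "has_adr_report": adr is not None,
                    "n_symptoms": len(adr.record.symptoms) if adr else pd.NA,
                }
                for s in SYMPTOMS:
                    row[f"symptom:{s}"] = bool(adr and s in adr.record.symptoms)
                rows.append(row)
        return pd.DataFrame(rows)

    def retained_export(self) -> dict[str, pd.DataFrame]:
        """Re-export only retained records in the three-table shape.

        Curating this export again discards nothing (idempotence).
        """
        hist, vax, adr = [], [], []
        for tl in self.timelines:
            if tl.history is not None:
                h = tl.history
                hist.append(
                    {
                        "respondent_id": tl.respondent_id,
                        "institution": h.institution,
                        "gender": h.gender,
                        "age": h.age,
                        "conditions": ";".join(h.conditions),
                        "submitted_at": h.submitted_at.isoformat() if h.submitted_at else "",
                    }
                )
            for v in tl.vaccinations:
                vax.append(
                    {
                        "record_id": v.record_id,
                        "respondent_id": tl.respondent_id,
                        "vaccine": v.record.vaccine,
                        "site": v.record.site,
                        "administered_at": v.record.administered_at.isoformat(),
                        "submitted_at": (
                            v.record.submitted_at.isoformat() if v.record.submitted_at else ""
                        ),
                    }
                )
            for a in tl.adr_reports:
                adr.append(
                    {
                        "record_id": a.record_id,
                        "respondent_id": tl.respondent_id,
                        "symptoms": ";".join(a.record.symptoms),
                        "submitted_at": (
                            a.record.submitted_at.isoformat() if a.record.submitted_at else ""
                        ),
                    }
                )
        return {
            "histories": pd.DataFrame(
                hist, columns=list(_EXPECTED_COLUMNS_ORDER["histories"])
            ),
            "vaccinations": pd.DataFrame(
                vax, columns=list(_EXPECTED_COLUMNS_ORDER["vaccinations"])
            ),
            "adr_reports": pd.DataFrame(
                adr, columns=list(_EXPECTED_COLUMNS_ORDER["adr_reports"])
            ),
        }

    def discard_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "table": e.table,
                    "record_id": e.record_id,
                    "respondent_id": e.respondent_id,
                    "rule": e.rule,
                    "reason": e.reason,
                }
                for e in self.discard_log
            ],
            columns=["table", "record_id", "respondent_id", "rule", "reason"],
        )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def read_export(path: Union[str, Path]) -> dict[str, pd.DataFrame]:
    """Read the three-table CSV export from a directory."""
    path = Path(path)
    tables = {}
    for name in ("histories", "vaccinations", "adr_reports"):
        tables[name] = pd.read_csv(path / f"{name}.csv", dtype=str, keep_default_na=False)
    return tables


_EXPECTED_COLUMNS_ORDER = {
    "histories": ("respondent_id", "institution", "gender", "age", "conditions", "submitted_at"),
    "vaccinations": (
        "record_id", "respondent_id", "vaccine", "site", "administered_at", "submitted_at",
    ),
    "adr_reports": ("record_id", "respondent_id", "symptoms", "submitted_at"),
}

_EXPECTED_COLUMNS = {
    "histories": {"respondent_id", "institution", "gender", "age", "conditions", "submitted_at"},
    "vaccinations": {"record_id", "respondent_id", "vaccine", "site", "administered_at", "submitted_at"},
    "adr_reports": {"record_id", "respondent_id", "symptoms", "submitted_at"},
}


def _check_columns(tables: Mapping[str, pd.DataFrame]) -> None:
    for name, expected in _EXPECTED_COLUMNS.items():
        if name not in tables:
            raise ValueError(f"missing table: {name}")
        got = set(tables[name].columns)
        if got != expected:
            raise ValueError(
                f"unexpected columns in {name}: got {sorted(got)}, want {sorted(expected)}"
            )


def _split_list(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    cell = str(cell).strip()
    return [part for part in cell.split(";") if part] if cell else []


def assemble(
    tables: Mapping[str, pd.DataFrame], window: StudyWindow = DEFAULT_STUDY_WINDOW
) -> list[Timeline]:
    """Parse the export into raw per-respondent timelines.

    One timeline per respondent id appearing in *any* table; records are
    ordered by submission time (record id as tie-break), so the result is
    invariant under row permutations of the input.
    """
    _check_columns(tables)
    timelines: dict[str, Timeline] = {}

    def get(rid: str) -> Timeline:
        if rid not in timelines:
            timelines[rid] = Timeline(respondent_id=rid)
        return timelines[rid]

    for row in tables["histories"].itertuples(index=False):
        record = validate_medical_history(
            {
                "institution": row.institution,
                "gender": row.gender,
                "age": row.age,
                "conditions": _split_list(row.conditions),
                "submitted_at": row.submitted_at or None,
            },
            respondent_id=str(row.respondent_id),
        )
        get(record.respondent_id).history = record

    for row in tables["vaccinations"].itertuples(index=False):
        record = validate_vaccination(
            {
                "vaccine": row.vaccine,
                "site": row.site,
                "administered_at": row.administered_at,
                "submitted_at": row.submitted_at or None,
            },
            respondent_id=str(row.respondent_id),
            window=window,
        )
        get(record.respondent_id).vaccinations.append(
            LabeledVaccination(record_id=int(row.record_id), record=record)
        )

    for row in tables["adr_reports"].itertuples(index=False):
        record = validate_adr(
            {"symptoms": _split_list(row.symptoms), "submitted_at": row.submitted_at or None},
            respondent_id=str(row.respondent_id),
        )
        get(record.respondent_id).adr_reports.append(
            LabeledAdr(record_id=int(row.record_id), record=record)
        )

    out = []
    for rid in sorted(timelines):
        tl = timelines[rid]
        tl.vaccinations.sort(key=_vax_submission_key)
        tl.adr_reports.sort(key=_adr_submission_key)
        out.append(tl)
    return out


def _vax_submission_key(v: LabeledVaccination):
    return (v.record.submitted_at or _FAR_FUTURE, v.record_id)


def _adr_submission_key(a: LabeledAdr):
    return (a.record.submitted_at or _FAR_FUTURE, a.record_id)


# ---------------------------------------------------------------------------
# Consistency filtering
# ---------------------------------------------------------------------------


def consistency_filter(timeline: Timeline) -> tuple[Timeline, list[DiscardEntry]]:
    """Apply R1–R5 to one timeline; never fails, every drop is logged."""
    rid = timeline.respondent_id
    log: list[DiscardEntry] = []
    vaxes = sorted(timeline.vaccinations, key=_vax_submission_key)
    adrs = sorted(timeline.adr_reports, key=_adr_submission_key)

    # R1: vaccinations require a medical history on file.
    if timeline.history is None:
        for v in vaxes:
            log.append(
                DiscardEntry("vaccinations", v.record_id, rid, "R1", "no medical history on file")
            )
        vaxes = []

    # R2: one vaccination per calendar date — keep the earliest-submitted.
    seen_dates: set[dt.date] = set()
    after_r2 = []
    for v in vaxes:
        day = v.record.administered_at
        if day in seen_dates:
            log.append(
                DiscardEntry(
                    "vaccinations", v.record_id, rid, "R2",
                    f"duplicate vaccination date {day.isoformat()}",
                )
            )
        else:
            seen_dates.add(day)
            after_r2.append(v)

    # R3: dates must strictly increase along the submission order.
    retained: list[LabeledVaccination] = []
    max_date: Optional[dt.date] = None
    for v in after_r2:
        day = v.record.administered_at
        if max_date is not None and day <= max_date:
            log.append(
                DiscardEntry(
                    "vaccinations", v.record_id, rid, "R3",
                    f"date {day.isoformat()} not after previously retained "
                    f"vaccination ({max_date.isoformat()})",
                )
            )
        else:
            retained.append(v)
            max_date = day

    # R4: ADR reports predating the first retained vaccination.
    kept_adrs: list[LabeledAdr] = []
    first_vax_date = min((v.record.administered_at for v in retained), default=None)
    for a in adrs:
        sub = a.record.submitted_at
        if (
            first_vax_date is not None
            and sub is not None
            and sub.date() < first_vax_date
        ):
            log.append(
                DiscardEntry(
                    "adr_reports", a.record_id, rid, "R4",
                    "submitted before first retained vaccination",
                )
            )
        else:
            kept_adrs.append(a)

    # R5: at most one ADR report per retained vaccination (earliest kept).
    for a in kept_adrs[len(retained):]:
        log.append(
            DiscardEntry(
                "adr_reports", a.record_id, rid, "R5",
                "more ADR reports than retained vaccinations",
            )
        )
    kept_adrs = kept_adrs[: len(retained)]

    return (
        Timeline(
            respondent_id=rid,
            history=timeline.history,
            vaccinations=retained,
            adr_reports=kept_adrs,
        ),
        log,
    )


def label_doses(timeline: Timeline) -> Timeline:
    """Assign ordinal dose labels to a consistency-filtered timeline."""
    by_date = sorted(
        timeline.vaccinations, key=lambda v: (v.record.administered_at, v.record_id)
    )
    labeled_vax = [
        replace(v, dose=k, out_of_study=k > MAX_STUDY_DOSES)
        for k, v in enumerate(by_date, start=1)
    ]
    labeled_adr = [
        LabeledAdr(record_id=a.record_id, record=replace(a.record, dose_ref=k))
        for k, a in enumerate(sorted(timeline.adr_reports, key=_adr_submission_key), start=1)
    ]
    return Timeline(
        respondent_id=timeline.respondent_id,
        history=timeline.history,
        vaccinations=labeled_vax,
        adr_reports=labeled_adr,
    )


def build_dataset(
    export: Union[str, Path, Mapping[str, pd.DataFrame]],
    window: StudyWindow = DEFAULT_STUDY_WINDOW,
) -> AnalysisDataset:
    """assemble → filter → label for every respondent (deterministic)."""
    tables = read_export(export) if isinstance(export, (str, Path)) else export
    timelines = assemble(tables, window=window)
    out: list[Timeline] = []
    log: list[DiscardEntry] = []
    for tl in timelines:
        filtered, entries = consistency_filter(tl)
        log.extend(entries)
        out.append(label_doses(filtered))
    return AnalysisDataset(timelines=out, discard_log=log)
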