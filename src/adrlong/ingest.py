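"""Application-server behavior: staged ingestion and day-7 ADR reminders.

The protocol is strictly staged per respondent: register (token → id), then
one medical history, then a vaccination record per administration, each of
which schedules a reminder to submit the corresponding ADR report seven
calendar days after the vaccination date.

The architecture is one-way: no operation ever returns stored questionnaire
content to a client — only acknowledgments and the respondent id.  The store
is append-only for submissions, and the token/id pairing table is excluded
from every export.

Reminder policy: one push at ``administered_at + 7`` days, repeated every
2 days while unresolved, capped at 3 sends and bounded by the study window.
The real push gateway is not implemented; dispatch goes through the
:class:`Notifier` contract (an in-memory fake is provided for tests).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Protocol

import pandas as pd

from .core_model import (
    DEFAULT_STUDY_WINDOW,
    AdrReport,
    MedicalHistory,
    StudyWindow,
    VaccinationRecord,
    stamp,
    validate_adr,
    validate_medical_history,
    validate_vaccination,
)
from .identity import IdentityService, UnknownRespondentError

__all__ = [
    "REMINDER_DELAY_DAYS",
    "REMINDER_REPEAT_DAYS",
    "REMINDER_MAX_SENDS",
    "IngestError",
    "Ack",
    "ReminderJob",
    "Notifier",
    "InMemoryNotifier",
    "Store",
    "IngestServer",
    "EXPORT_TABLES",
]

REMINDER_DELAY_DAYS = 7
REMINDER_REPEAT_DAYS = 2
REMINDER_MAX_SENDS = 3

#: Export table names, in write order. No token column appears in any of them.
EXPORT_TABLES = ("histories", "vaccinations", "adr_reports")


class IngestError(ValueError):
    """Protocol violation: wrong stage order, unknown id, or duplicate."""


@dataclass(frozen=True)
class Ack:
    """Acknowledgment — the only content ever returned to a client."""

    respondent_id: str
    kind: str
    record_id: Optional[int] = None


@dataclass
class ReminderJob:
    job_id: int
    respondent_id: str
    vaccination_record_id: int
    due_on: dt.date
    status: str = "pending"  # pending | sent | resolved
    send_count: int = 0


class Notifier(Protocol):
    """Push-gateway contract; implementations deliver one message per call."""

    def push(self, token: str, message: str) -> None: ...


class InMemoryNotifier:
    """Records pushes instead of delivering them (test double)."""

    def __init__(self) -> None:
        self.sent: list[tuple[str, str]] = []

    def push(self, token: str, message: str) -> None:
        self.sent.append((token, message))


@dataclass
class Store:
    """SQL-database stand-in: append-only submission tables plus job state."""

    histories: dict[str, MedicalHistory] = field(default_factory=dict)
    vaccinations: list[tuple[int, VaccinationRecord]] = field(default_factory=list)
    adr_reports: list[tuple[int, AdrReport]] = field(default_factory=list)
    jobs: list[ReminderJob] = field(default_factory=list)

    def vaccinations_for(self, rid: str) -> list[tuple[int, VaccinationRecord]]:
        return [(i, v) for i, v in self.vaccinations if v.respondent_id == rid]

    def export(self) -> dict[str, pd.DataFrame]:
        """The three-table CSV-shaped export consumed by curation.

        Dates are ISO-8601, list fields are semicolon-joined; the identity
        pairing table is deliberately absent.
        """
        hist_rows = [
            {
                "respondent_id": h.respondent_id,
                "institution": h.institution,
                "gender": h.gender,
                "age": h.age,
                "conditions": ";".join(h.conditions),
                "submitted_at": h.submitted_at.isoformat() if h.submitted_at else "",
            }
            for h in self.histories.values()
        ]
        vax_rows = [
            {
                "record_id": i,
                "respondent_id": v.respondent_id,
                "vaccine": v.vaccine,
                "site": v.site,
                "administered_at": v.administered_at.isoformat(),
                "submitted_at": v.submitted_at.isoformat() if v.submitted_at else "",
            }
            for i, v in self.vaccinations
        ]
        adr_rows = [
            {
                "record_id": i,
                "respondent_id": a.respondent_id,
                "symptoms": ";".join(a.symptoms),
                "submitted_at": a.submitted_at.isoformat() if a.submitted_at else "",
            }
            for i, a in self.adr_reports
        ]
        return {
            "histories": pd.DataFrame(
                hist_rows,
                columns=[
                    "respondent_id",
                    "institution",
                    "gender",
                    "age",
                    "conditions",
                    "submitted_at",
                ],
            ),
            "vaccinations": pd.DataFrame(
                vax_rows,
                columns=[
                    "record_id",
                    "respondent_id",
                    "vaccine",
                    "site",
                    "administered_at",
                    "submitted_at",
                ],
            ),
            "adr_reports": pd.DataFrame(
                adr_rows, columns=["record_id", "respondent_id", "symptoms", "submitted_at"]
            ),
        }


class IngestServer:
    """Transport-agnostic realization of the submission service.

    Each method corresponds to one POST endpoint of the service contract
    (``/register``, ``/history``, ``/vaccination``, ``/adr``).  Submission
    timestamps are stamped with the supplied clock when the payload does not
    carry one, keeping replays deterministic.
    """

    def __init__(
        self,
        notifier: Optional[Notifier] = None,
        window: StudyWindow = DEFAULT_STUDY_WINDOW,
        identity_seed: Optional[int] = None,
    ):
        self.identity = IdentityService(seed=identity_seed)
        self.notifier: Notifier = notifier if notifier is not None else InMemoryNotifier()
        self.window = window
        self.store = Store()
        self._next_record_id = 0
        self._next_job_id = 0

    # -- protocol stages ----------------------------------------------------

    def register(self, token: str) -> str:
        """Issue (or re-issue, idempotently) the respondent id for a token."""
        return self.identity.issue_id(token)

    def _require_issued(self, respondent_id: str) -> None:
        if not self.identity.is_issued(respondent_id):
            raise UnknownRespondentError(respondent_id)

    def accept_medical_history(
        self, respondent_id: str, payload, now: Optional[dt.datetime] = None
    ) -> Ack:
        self._require_issued(respondent_id)
        if respondent_id in self.store.histories:
            raise IngestError("history exists for this respondent")
        record = validate_medical_history(payload, respondent_id=respondent_id)
        if record.submitted_at is None:
            record = stamp(record, now or dt.datetime.now(dt.timezone.utc))
        self.store.histories[respondent_id] = record
        return Ack(respondent_id, "history")

    def accept_vaccination(
        self, respondent_id: str, payload, now: Optional[dt.datetime] = None
    ) -> Ack:
        self._require_issued(respondent_id)
        if respondent_id not in self.store.histories:
            raise IngestError("no medical history on file")
        record = validate_vaccination(
            payload, respondent_id=respondent_id, window=self.window
        )
        if record.submitted_at is None:
            record = stamp(record, now or dt.datetime.now(dt.timezone.utc))
        record_id = self._next_record_id
        self._next_record_id += 1
        self.store.vaccinations.append((record_id, record))
        job = ReminderJob(
            job_id=self._next_job_id,
            respondent_id=respondent_id,
            vaccination_record_id=record_id,
            due_on=record.administered_at + dt.timedelta(days=REMINDER_DELAY_DAYS),
        )
        self._next_job_id += 1
        self.store.jobs.append(job)
        return Ack(respondent_id, "vaccination", record_id)

    def accept_adr(
        self, respondent_id: str, payload, now: Optional[dt.datetime] = None
    ) -> Ack:
        self._require_issued(respondent_id)
        if not self.store.vaccinations_for(respondent_id):
            raise IngestError("no vaccination on file")
        record = validate_adr(payload, respondent_id=respondent_id)
        if record.submitted_at is None:
            record = stamp(record, now or dt.datetime.now(dt.timezone.utc))
        record_id = self._next_record_id
        self._next_record_id += 1
        self.store.adr_reports.append((record_id, record))
        # Resolve the earliest open job; authoritative dose matching is a
        # curation concern (the server cannot know dose semantics at ingest).
        open_jobs = [
            j
            for j in self.store.jobs
            if j.respondent_id == respondent_id and j.status != "resolved"
        ]
        if open_jobs:
            min(open_jobs, key=lambda j: (j.due_on, j.job_id)).status = "resolved"
        return Ack(respondent_id, "adr", record_id)

    # -- reminders ----------------------------------------------------------

    def due_reminders(self, now: dt.date) -> list[tuple[str, str]]:
        """Dispatch every pending job due on or before ``now``.

        Returns the (token, message) pairs handed to the notifier.  Each
        dispatched job transitions to ``sent``; jobs with sends remaining are
        re-armed as ``pending`` two days out, within the study window.
        """
        dispatched: list[tuple[str, str]] = []
        for job in self.store.jobs:
            if job.status != "pending" or job.due_on > now:
                continue
            token = self.identity.token_for(job.respondent_id)
            message = (
                f"Please submit the adverse-reaction questionnaire for your "
                f"vaccination (due {job.due_on.isoformat()})."
            )
            self.notifier.push(token, message)
            dispatched.append((token, message))
            job.send_count += 1
            next_due = now + dt.timedelta(days=REMINDER_REPEAT_DAYS)
            if job.send_count < REMINDER_MAX_SENDS and next_due <= self.window.end:
                job.status = "pending"
                job.due_on = next_due
            else:
                job.status = "sent"
        return dispatched
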