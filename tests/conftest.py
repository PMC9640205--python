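"""Shared fixtures: deterministic random fixture builders and one reusable
paper-calibrated simulation (module-scoped where tests only read it)."""

from __future__ import annotations

import datetime as dt
import random

import pandas as pd
import pytest

from adrlong.core_model import (
    CHRONIC_CONDITIONS,
    SYMPTOMS,
    VACCINES,
    AdrReport,
    MedicalHistory,
    VaccinationRecord,
)
from adrlong.curation import AnalysisDataset, LabeledAdr, LabeledVaccination, Timeline
from adrlong.simulator import default_config, simulate

EXPORT_COLUMNS = {
    "histories": ["respondent_id", "institution", "gender", "age", "conditions", "submitted_at"],
    "vaccinations": [
        "record_id", "respondent_id", "vaccine", "site", "administered_at", "submitted_at",
    ],
    "adr_reports": ["record_id", "respondent_id", "symptoms", "submitted_at"],
}


def empty_tables() -> dict[str, pd.DataFrame]:
    return {name: pd.DataFrame(columns=cols) for name, cols in EXPORT_COLUMNS.items()}


def random_export(rng: random.Random, n_respondents: int) -> dict[str, pd.DataFrame]:
    """A deliberately messy export: missing histories, date collisions,
    out-of-order submissions, premature and surplus ADR reports."""
    hist, vax, adr = [], [], []
    record_id = 0
    date_pool = [dt.date(2021, 3, 1) + dt.timedelta(days=k) for k in range(10)]
    for i in range(n_respondents):
        rid = f"r{i:04d}"
        if rng.random() < 0.8:
            hist.append(
                {
                    "respondent_id": rid,
                    "institution": rng.choice(["UniMiB", "PoliMi"]),
                    "gender": rng.choice(["male", "female"]),
                    "age": rng.randint(19, 80),
                    "conditions": ";".join(
                        rng.sample(CHRONIC_CONDITIONS, k=rng.randint(0, 2))
                    ),
                    "submitted_at": "2021-02-20T08:00:00",
                }
            )
        for _ in range(rng.randint(0, 4)):
            administered = rng.choice(date_pool)
            submitted = dt.datetime(
                administered.year, administered.month, administered.day
            ) + dt.timedelta(hours=rng.randint(0, 400))
            vax.append(
                {
                    "record_id": record_id,
                    "respondent_id": rid,
                    "vaccine": rng.choice(VACCINES),
                    "site": "hub",
                    "administered_at": administered.isoformat(),
                    "submitted_at": submitted.isoformat(),
                }
            )
            record_id += 1
        for _ in range(rng.randint(0, 5)):
            submitted = dt.datetime(2021, 2, 25, 0, 0) + dt.timedelta(
                hours=rng.randint(0, 700)
            )
            adr.append(
                {
                    "record_id": record_id,
                    "respondent_id": rid,
                    "symptoms": ";".join(rng.sample(SYMPTOMS, k=rng.randint(0, 5))),
                    "submitted_at": submitted.isoformat(),
                }
            )
            record_id += 1
    return {
        "histories": pd.DataFrame(hist, columns=EXPORT_COLUMNS["histories"]),
        "vaccinations": pd.DataFrame(vax, columns=EXPORT_COLUMNS["vaccinations"]),
        "adr_reports": pd.DataFrame(adr, columns=EXPORT_COLUMNS["adr_reports"]),
    }


def make_timeline(
    rid: str,
    gender: str = "female",
    age: int = 30,
    institution: str = "UniMiB",
    conditions: tuple[str, ...] = (),
    doses: list[tuple[str, str]] | None = None,  # (vaccine, administered date)
    adr_symptom_sets: list[list[str]] | None = None,  # k-th set -> dose k
) -> Timeline:
    """Directly build an already-curated, dose-labeled timeline."""
    doses = doses or []
    adr_symptom_sets = adr_symptom_sets or []
    history = MedicalHistory(
        respondent_id=rid,
        institution=institution,
        gender=gender,
        age=age,
        conditions=tuple(conditions),
        submitted_at=dt.datetime(2021, 3, 1, 8, 0),
    )
    vaccinations = [
        LabeledVaccination(
            record_id=k,
            record=VaccinationRecord(
                respondent_id=rid,
                vaccine=vaccine,
                site="hub",
                administered_at=dt.date.fromisoformat(day),
                submitted_at=dt.datetime.fromisoformat(day + "T12:00:00"),
            ),
            dose=k + 1,
            out_of_study=k + 1 > 3,
        )
        for k, (vaccine, day) in enumerate(doses)
    ]
    adrs = [
        LabeledAdr(
            record_id=1000 + k,
            record=AdrReport(
                respondent_id=rid,
                symptoms=tuple(sorted(set(symptoms), key=SYMPTOMS.index)),
                dose_ref=k + 1,
                submitted_at=dt.datetime(2021, 3, 10 + k, 18, 0),
            ),
        )
        for k, symptoms in enumerate(adr_symptom_sets)
    ]
    return Timeline(respondent_id=rid, history=history, vaccinations=vaccinations, adr_reports=adrs)


def random_dataset(rng: random.Random, n: int) -> AnalysisDataset:
    """A random already-curated dataset for tally-oracle tests."""
    timelines = []
    for i in range(n):
        n_doses = rng.randint(0, 3)
        doses = [
            (rng.choice(VACCINES), (dt.date(2021, 3, 1) + dt.timedelta(days=60 * k)).isoformat())
            for k in range(n_doses)
        ]
        n_adr = rng.randint(0, n_doses)
        adrs = [rng.sample(SYMPTOMS, k=rng.randint(0, 6)) for _ in range(n_adr)]
        timelines.append(
            make_timeline(
                f"d{i:04d}",
                gender=rng.choice(["male", "female"]),
                age=rng.randint(19, 80),
                institution=rng.choice(["UniMiB", "PoliMi"]),
                conditions=tuple(rng.sample(CHRONIC_CONDITIONS, k=rng.randint(0, 3))),
                doses=doses,
                adr_symptom_sets=adrs,
            )
        )
    return AnalysisDataset(timelines=timelines, discard_log=[])


@pytest.fixture(scope="session")
def calibrated_stream():
    """One paper-calibrated simulation, reused read-only across tests."""
    return simulate(default_config(), seed=20210305)


@pytest.fixture(scope="session")
def calibrated_dataset(calibrated_stream):
    from adrlong.curation import build_dataset

    return build_dataset(calibrated_stream.to_export())
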