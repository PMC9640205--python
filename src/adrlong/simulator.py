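"""Synthetic three-dose campaign generator.

Emulates the participation funnel of the surveyed cohort so that ingestion,
curation, and analytics can be exercised end-to-end without real data:

* ``n_invited`` people are invited; each registers (and submits a medical
  history) with probability ``p_register``;
* demographics (institution, gender, age band) are drawn from independent
  categorical mixes; chronic conditions from per-gender prevalences;
* stage participation is a chain of conditional Bernoulli draws:
  history → dose-1 vaccination submission → dose-2 → dose-3, with the ADR
  report of dose *d* conditional on the dose-*d* vaccination submission.
  Dose-3 participation is spontaneous (no hub involvement, no sponsorship),
  hence its much smaller probability;
* per-stage participation is modulated by per-stratum retention multipliers
  (``participation_profile``) so that the stratified composition of each
  stage matches the published tables, not just the stage totals;
* symptom sets are independent per-symptom Bernoulli draws with probability
  ``logistic(base + gender + age-band + dose offsets)``; the positive female
  and young-age offsets encode the observed pattern that women and younger
  respondents report more post-vaccination symptoms;
* optional rule violations (see :mod:`adrlong.curation`) are injected at
  configurable rates with exact ground-truth bookkeeping.

Randomness: one root seed; respondent *i* draws from a dedicated substream
keyed by ``(seed, i)``, so enlarging the cohort never perturbs earlier
respondents' draws and identical config+seed reproduces the stream byte for
byte.
"""

from __future__ import annotations

import datetime as dt
import math
import uuid
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core_model import CHRONIC_CONDITIONS, GENDERS, INSTITUTIONS, SYMPTOMS, VACCINES

__all__ = [
    "AGE_BANDS",
    "STAGES",
    "STAGE_PARENT",
    "TABLE_COUNTS",
    "StageProfile",
    "SymptomModel",
    "SimulationConfig",
    "RespondentTruth",
    "ViolationEntry",
    "EventStream",
    "default_config",
    "simulate",
    "expected_funnel",
]

AGE_BANDS = ("<30", "30-55", ">55")
_AGE_RANGES = {"<30": (19, 29), "30-55": (30, 55), ">55": (56, 80)}

#: Funnel stages beyond the medical history, with their conditioning parent.
STAGES = ("admin1", "adr1", "admin2", "adr2", "admin3", "adr3")
STAGE_PARENT = {
    "admin1": "history",
    "adr1": "admin1",
    "admin2": "admin1",
    "adr2": "admin2",
    "admin3": "admin2",
    "adr3": "admin3",
}

#: Published per-stage stratum counts of the surveyed cohort (the
#: calibration input for the default configuration).  ``N`` is the stage
#: total; each factor maps stratum label → count.
TABLE_COUNTS: dict[str, dict] = {
    "history": {
        "N": 2733,
        "institution": {"UniMiB": 1676, "PoliMi": 1057},
        "gender": {"male": 1224, "female": 1509},
        "age_band": {"<30": 1301, "30-55": 1109, ">55": 323},
    },
    "admin1": {
        "N": 2360,
        "institution": {"UniMiB": 1383, "PoliMi": 977},
        "gender": {"male": 1075, "female": 1285},
        "age_band": {"<30": 1024, "30-55": 1043, ">55": 293},
    },
    "adr1": {
        "N": 2226,
        "institution": {"UniMiB": 1332, "PoliMi": 894},
        "gender": {"male": 998, "female": 1228},
        "age_band": {"<30": 962, "30-55": 983, ">55": 281},
    },
    "admin2": {
        "N": 1779,
        "institution": {"UniMiB": 1252, "PoliMi": 527},
        "gender": {"male": 713, "female": 1066},
        "age_band": {"<30": 955, "30-55": 634, ">55": 190},
    },
    "adr2": {
        "N": 1610,
        "institution": {"UniMiB": 1138, "PoliMi": 472},
        "gender": {"male": 645, "female": 965},
        "age_band": {"<30": 861, "30-55": 575, ">55": 174},
    },
    "admin3": {
        "N": 179,
        "institution": {"UniMiB": 116, "PoliMi": 63},
        "gender": {"male": 68, "female": 111},
        "age_band": {"<30": 64, "30-55": 80, ">55": 35},
    },
    "adr3": {
        "N": 169,
        "institution": {"UniMiB": 111, "PoliMi": 58},
        "gender": {"male": 65, "female": 104},
        "age_band": {"<30": 59, "30-55": 76, ">55": 34},
    },
}

_FACTORS = ("institution", "gender", "age_band")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _check_mix(mix: dict[str, float], name: str) -> None:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(mix.values())!r})")
    if any(p < 0 or p > 1 for p in mix.values()):
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")


class StageProfile(BaseModel):
    """Stratum-dependent participation for one funnel stage, on the
    log-odds scale: ``p(cell) = logistic(intercept + institution offset +
    gender offset + age-band offset)``.

    An additive logistic model keeps every cell probability inside (0, 1)
    while still matching arbitrary published per-factor retention margins —
    a purely multiplicative rate model cannot, because the observed margins
    (e.g. the strong joint retention of young UniMiB women at dose 2) imply
    per-cell rates above 1.
    """

    model_config = ConfigDict(frozen=True)

    intercept: float
    institution: dict[str, float] = Field(default_factory=lambda: {k: 0.0 for k in INSTITUTIONS})
    gender: dict[str, float] = Field(default_factory=lambda: {k: 0.0 for k in GENDERS})
    age_band: dict[str, float] = Field(default_factory=lambda: {k: 0.0 for k in AGE_BANDS})

    def probability(self, institution: str, gender: str, age_band: str) -> float:
        logit = (
            self.intercept
            + self.institution.get(institution, 0.0)
            + self.gender.get(gender, 0.0)
            + self.age_band.get(age_band, 0.0)
        )
        return 1.0 / (1.0 + math.exp(-logit))


class SymptomModel(BaseModel):
    """Per-symptom base log-odds plus gender, age-band, and dose offsets."""

    model_config = ConfigDict(frozen=True)

    base_logit: dict[str, float]
    gender_offset: dict[str, float]
    age_offset: dict[str, float]
    dose_offset: tuple[float, float, float]
    #: Standard deviation of an optional shared per-report frailty added to
    #: every symptom's logit (induces co-occurrence); off by default.
    frailty_sd: float = 0.0

    def probability(self, symptom: str, gender: str, age_band: str, dose: int,
                    frailty: float = 0.0) -> float:
        logit = (
            self.base_logit[symptom]
            + self.gender_offset.get(gender, 0.0)
            + self.age_offset.get(age_band, 0.0)
            + self.dose_offset[dose - 1]
            + frailty
        )
        return 1.0 / (1.0 + math.exp(-logit))


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_invited: int = Field(ge=0)
    p_register: float = Field(ge=0.0, le=1.0)
    institution_mix: dict[str, float]
    gender_mix: dict[str, float]
    age_mix: dict[str, float]
    condition_prev: dict[str, dict[str, float]]
    p_vax_submit: tuple[float, float, float]
    p_adr_submit: tuple[float, float, float]
    participation_profile: dict[str, StageProfile] = Field(default_factory=dict)
    vaccine_mix: tuple[dict[str, float], dict[str, float], dict[str, float]]
    symptom_model: SymptomModel
    corruption_rates: dict[str, float] = Field(
        default_factory=lambda: {r: 0.0 for r in ("R1", "R2", "R3", "R4", "R5")}
    )
    dose_windows: tuple[
        tuple[dt.date, dt.date], tuple[dt.date, dt.date], tuple[dt.date, dt.date]
    ]
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        _check_mix(self.institution_mix, "institution_mix")
        _check_mix(self.gender_mix, "gender_mix")
        _check_mix(self.age_mix, "age_mix")
        for d, mix in enumerate(self.vaccine_mix, start=1):
            _check_mix(mix, f"vaccine_mix[{d}]")
            if any(v not in VACCINES for v in mix):
                raise ValueError(f"vaccine_mix[{d}] has unknown vaccine labels")
        for seq_name, seq in (("p_vax_submit", self.p_vax_submit),
                              ("p_adr_submit", self.p_adr_submit)):
            if any(p < 0 or p > 1 for p in seq):
                raise ValueError(f"{seq_name} entries must be in [0, 1]")
        for rule, p in self.corruption_rates.items():
            if p < 0 or p > 1:
                raise ValueError(f"corruption rate {rule} must be in [0, 1]")
        for cond, per_gender in self.condition_prev.items():
            if cond not in CHRONIC_CONDITIONS:
                raise ValueError(f"unknown condition in condition_prev: {cond!r}")
            if any(p < 0 or p > 1 for p in per_gender.values()):
                raise ValueError(f"condition_prev[{cond!r}] must be in [0, 1]")
        prev_end: Optional[dt.date] = None
        for d, (start, end) in enumerate(self.dose_windows, start=1):
            if start > end:
                raise ValueError(f"dose_windows[{d}] start after end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("dose_windows must be non-overlapping and increasing")
            prev_end = end
        return self

    # -- derived quantities -------------------------------------------------

    def stage_overall(self, stage: str) -> float:
        if stage.startswith("admin"):
            return self.p_vax_submit[int(stage[-1]) - 1]
        return self.p_adr_submit[int(stage[-1]) - 1]

    def stage_probability(
        self, stage: str, institution: str, gender: str, age_band: str
    ) -> float:
        """Conditional participation probability for one demographic cell.

        With a profile configured for the stage, the profile's logistic
        model is authoritative; otherwise the flat per-dose rate applies.
        """
        profile = self.participation_profile.get(stage)
        if profile is not None:
            return profile.probability(institution, gender, age_band)
        return self.stage_overall(stage)


def _all_cells() -> list[tuple[str, str, str]]:
    return [
        (inst, gen, band)
        for inst in INSTITUTIONS
        for gen in GENDERS
        for band in AGE_BANDS
    ]


def _solve_stage_profile(
    stage: str, parent_masses: dict[tuple[str, str, str], float]
) -> StageProfile:
    """Fit the logistic stage model to the published retention margins.

    Five free parameters (intercept; PoliMi, female, 30-55, >55 offsets,
    with UniMiB/male/<30 as references) are solved against five independent
    margin equations: the overall retention plus one per non-reference
    level, each computed over the parent stage's demographic cell masses.
    """
    from scipy import optimize

    stage_counts, parent_counts = TABLE_COUNTS[stage], TABLE_COUNTS[STAGE_PARENT[stage]]
    cells = _all_cells()
    w = np.array([parent_masses[c] for c in cells])
    w = w / w.sum()

    targets = [stage_counts["N"] / parent_counts["N"]]
    constraints: list[tuple[str, str]] = []
    for factor, reference in (("institution", "UniMiB"), ("gender", "male"),
                              ("age_band", "<30")):
        for level in stage_counts[factor]:
            if level != reference:
                constraints.append((factor, level))
                targets.append(
                    stage_counts[factor][level] / parent_counts[factor][level]
                )

    def unpack(theta):
        alpha = theta[0]
        offsets = {
            "institution": {"UniMiB": 0.0, "PoliMi": theta[1]},
            "gender": {"male": 0.0, "female": theta[2]},
            "age_band": {"<30": 0.0, "30-55": theta[3], ">55": theta[4]},
        }
        return alpha, offsets

    idx = {"institution": 0, "gender": 1, "age_band": 2}

    def cell_probs(theta):
        alpha, offsets = unpack(theta)
        logits = np.array(
            [
                alpha
                + offsets["institution"][c[0]]
                + offsets["gender"][c[1]]
                + offsets["age_band"][c[2]]
                for c in cells
            ]
        )
        return 1.0 / (1.0 + np.exp(-logits))

    def residuals(theta):
        p = cell_probs(theta)
        out = [float(np.sum(w * p)) - targets[0]]
        for (factor, level), target in zip(constraints, targets[1:]):
            mask = np.array([c[idx[factor]] == level for c in cells])
            out.append(float(np.sum(w[mask] * p[mask]) / np.sum(w[mask])) - target)
        return out

    solution = optimize.root(residuals, np.zeros(5), tol=1e-12)
    if not solution.success or max(abs(r) for r in residuals(solution.x)) > 1e-8:
        raise RuntimeError(f"stage profile calibration failed for {stage}")
    alpha, offsets = unpack(solution.x)
    return StageProfile(intercept=alpha, **offsets)


def _calibrated_profiles() -> dict[str, StageProfile]:
    """Per-stage logistic profiles matching the published tables.

    Parent cell masses are propagated along the dose chain (history →
    admin1 → admin2 → admin3), so each stage's margins are fit over the
    demographic composition its parent stage actually has.
    """
    history = TABLE_COUNTS["history"]
    masses = {
        (inst, gen, band): (history["institution"][inst] / history["N"])
        * (history["gender"][gen] / history["N"])
        * (history["age_band"][band] / history["N"])
        for inst, gen, band in _all_cells()
    }
    profiles: dict[str, StageProfile] = {}
    admin_masses = masses
    for d in (1, 2, 3):
        admin_stage, adr_stage = f"admin{d}", f"adr{d}"
        profiles[admin_stage] = _solve_stage_profile(admin_stage, admin_masses)
        admin_masses = {
            c: m * profiles[admin_stage].probability(*c) for c, m in admin_masses.items()
        }
        profiles[adr_stage] = _solve_stage_profile(adr_stage, admin_masses)
    return profiles


_PROFILE_CACHE: dict[str, StageProfile] = {}


def calibrated_profiles() -> dict[str, StageProfile]:
    if not _PROFILE_CACHE:
        _PROFILE_CACHE.update(_calibrated_profiles())
    return dict(_PROFILE_CACHE)


def default_config() -> SimulationConfig:
    """Configuration calibrated to the published cohort.

    3712 invited (the first-wave vaccinees); 73.6% submit the history;
    stage retentions and per-stratum profiles follow the published tables;
    the vaccine mix is dominated by Vaxzevria at doses 1–2 and is mRNA-only
    at dose 3 (boosters); symptom log-odds favor the injection-site /
    systemic reactogenicity pattern with positive female and young-age
    offsets and a dose-2 dip.  Corruption is off.
    """
    history = TABLE_COUNTS["history"]
    return SimulationConfig(
        n_invited=3712,
        p_register=0.736,
        institution_mix={k: round(v / history["N"], 3) for k, v in history["institution"].items()},
        gender_mix={"male": 0.448, "female": 0.552},
        age_mix={"<30": 0.476, "30-55": 0.406, ">55": 0.118},
        condition_prev={
            # Bounded by the observed maximum prevalence (0.078, male
            # hypertension); men higher except asthma, liver, autoimmune.
            "dyslipidemia": {"male": 0.045, "female": 0.030},
            "hypertension": {"male": 0.078, "female": 0.030},
            "autoimmune diseases": {"male": 0.025, "female": 0.055},
            "asthma": {"male": 0.040, "female": 0.050},
            "cardiovascular diseases": {"male": 0.020, "female": 0.012},
            "tumor": {"male": 0.012, "female": 0.010},
            "liver diseases": {"male": 0.008, "female": 0.012},
            "diabetes": {"male": 0.020, "female": 0.010},
            "bronchitis": {"male": 0.012, "female": 0.008},
            "kidney disease": {"male": 0.010, "female": 0.006},
        },
        p_vax_submit=(0.863, 0.754, 0.101),
        p_adr_submit=(0.943, 0.905, 0.944),
        participation_profile=calibrated_profiles(),
        vaccine_mix=(
            {"Vaxzevria": 0.653, "Comirnaty": 0.270, "moderna-mRNA1273": 0.075, "Janssen": 0.002},
            {"Vaxzevria": 0.657, "Comirnaty": 0.270, "moderna-mRNA1273": 0.073, "Janssen": 0.0},
            {"Vaxzevria": 0.0, "Comirnaty": 0.55, "moderna-mRNA1273": 0.45, "Janssen": 0.0},
        ),
        symptom_model=SymptomModel(
            base_logit={
                "fever": -1.8,
                "headache": -1.3,
                "injection site pain": 0.0,
                "tiredness": -1.1,
                "muscular pain": -1.4,
                "swollen lymph nodes": -3.3,
                "joint pain": -2.0,
                "paresthesia": -3.8,
                "dizziness": -3.0,
                "sleepiness": -1.9,
                "nausea": -3.1,
                "abdominal pain": -3.6,
            },
            gender_offset={"male": 0.0, "female": 0.5},
            age_offset={"<30": 0.5, "30-55": 0.25, ">55": 0.0},
            dose_offset=(0.0, -0.4, -0.2),
        ),
        dose_windows=(
            (dt.date(2021, 3, 5), dt.date(2021, 3, 29)),
            (dt.date(2021, 5, 31), dt.date(2021, 6, 11)),
            (dt.date(2021, 11, 15), dt.date(2022, 1, 20)),
        ),
        seed=0,
    )


# ---------------------------------------------------------------------------
# Event stream
# ---------------------------------------------------------------------------


@dataclass
class RespondentTruth:
    """Latent ground truth for one simulated (or ghost) respondent."""

    index: int
    token: str
    respondent_id: str
    registered: bool
    institution: str = ""
    gender: str = ""
    age_band: str = ""
    age: int = 0
    stages: dict[str, bool] = dataclass_field(default_factory=dict)
    ghost: bool = False  # injected R1 respondent: vaccination, no history


@dataclass(frozen=True)
class ViolationEntry:
    respondent_id: str
    rule: str
    table: str
    record_key: str


@dataclass
class EventStream:
    """Time-ordered register/history/vaccination/ADR events + ground truth."""

    events: list[tuple[dt.datetime, str, str, dict]]  # (ts, kind, respondent_id, payload)
    truths: list[RespondentTruth]
    violations: list[ViolationEntry]

    def stage_counts(self) -> dict[str, int]:
        counts = {"history": sum(1 for t in self.truths if t.registered and not t.ghost)}
        for stage in STAGES:
            counts[stage] = sum(1 for t in self.truths if t.stages.get(stage, False))
        return counts

    def to_export(self) -> dict[str, pd.DataFrame]:
        """Materialize the three-table export; record ids follow event order."""
        hist_rows, vax_rows, adr_rows = [], [], []
        record_id = 0
        for ts, kind, rid, payload in self.events:
            if kind == "history":
                hist_rows.append(
                    {
                        "respondent_id": rid,
                        "institution": payload["institution"],
                        "gender": payload["gender"],
                        "age": payload["age"],
                        "conditions": ";".join(payload["conditions"]),
                        "submitted_at": ts.isoformat(),
                    }
                )
            elif kind == "vaccination":
                vax_rows.append(
                    {
                        "record_id": record_id,
                        "respondent_id": rid,
                        "vaccine": payload["vaccine"],
                        "site": payload["site"],
                        "administered_at": payload["administered_at"],
                        "submitted_at": ts.isoformat(),
                    }
                )
                record_id += 1
            elif kind == "adr":
                adr_rows.append(
                    {
                        "record_id": record_id,
                        "respondent_id": rid,
                        "symptoms": ";".join(payload["symptoms"]),
                        "submitted_at": ts.isoformat(),
                    }
                )
                record_id += 1
        from .curation import _EXPECTED_COLUMNS_ORDER as cols

        return {
            "histories": pd.DataFrame(hist_rows, columns=list(cols["histories"])),
            "vaccinations": pd.DataFrame(vax_rows, columns=list(cols["vaccinations"])),
            "adr_reports": pd.DataFrame(adr_rows, columns=list(cols["adr_reports"])),
        }

    def ground_truth_frame(self) -> pd.DataFrame:
        """Injected-violation log: one row per injected inconsistency."""
        return pd.DataFrame(
            [
                {
                    "respondent_id": v.respondent_id,
                    "rule": v.rule,
                    "table": v.table,
                    "record_key": v.record_key,
                }
                for v in self.violations
            ],
            columns=["respondent_id", "rule", "table", "record_key"],
        )

    def write(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_export().items():
            frame.to_csv(directory / f"{name}.csv", index=False)
        self.ground_truth_frame().to_csv(directory / "ground_truth.csv", index=False)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _uuid_from(rng: np.random.Generator) -> str:
    return str(uuid.UUID(bytes=rng.bytes(16), version=4))


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _at(day: dt.date, hour: int, minute: int) -> dt.datetime:
    return dt.datetime(day.year, day.month, day.day, hour, minute)


def simulate(config: SimulationConfig, seed: Optional[int] = None) -> EventStream:
    """Draw one synthetic campaign event stream (reproducible given seed)."""
    root_seed = config.seed if seed is None else seed
    events: list[tuple[dt.datetime, str, str, dict]] = []
    truths: list[RespondentTruth] = []
    violations: list[ViolationEntry] = []
    corruption = {r: config.corruption_rates.get(r, 0.0) for r in ("R1", "R2", "R3", "R4", "R5")}
    d1_start = config.dose_windows[0][0]

    for i in range(config.n_invited):
        rng = np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(i,)))
        token = f"tok-{root_seed}-{i:07d}"
        # Ghost respondents model devices submitting a vaccination without a
        # history — the inconsistency targeted by curation rule R1.
        make_ghost = rng.random() < corruption["R1"]

        registered = rng.random() < config.p_register
        truth = RespondentTruth(
            index=i, token=token, respondent_id="", registered=registered
        )
        if registered:
            rid = _uuid_from(rng)
            truth.respondent_id = rid
            truth.institution = _draw_categorical(rng, config.institution_mix)
            truth.gender = _draw_categorical(rng, config.gender_mix)
            truth.age_band = _draw_categorical(rng, config.age_mix)
            lo, hi = _AGE_RANGES[truth.age_band]
            truth.age = int(rng.integers(lo, hi + 1))
            conditions = [
                c
                for c in CHRONIC_CONDITIONS
                if rng.random() < config.condition_prev.get(c, {}).get(truth.gender, 0.0)
            ]
            history_day = d1_start + dt.timedelta(days=int(rng.integers(0, 26)))
            history_ts = _at(history_day, 8, int(rng.integers(0, 60)))
            events.append(
                (
                    history_ts,
                    "history",
                    rid,
                    {
                        "institution": truth.institution,
                        "gender": truth.gender,
                        "age": truth.age,
                        "conditions": conditions,
                    },
                )
            )
            _simulate_doses(rng, config, truth, events, violations, history_ts, corruption)
        truths.append(truth)

        if make_ghost:
            ghost_rid = _uuid_from(rng)
            ghost = RespondentTruth(
                index=i, token=token + "-ghost", respondent_id=ghost_rid,
                registered=True, ghost=True,
            )
            day = _uniform_date(rng, *config.dose_windows[0])
            ts = _at(day, 14, int(rng.integers(0, 60)))
            events.append(
                (
                    ts,
                    "vaccination",
                    ghost_rid,
                    {
                        "vaccine": _draw_categorical(rng, config.vaccine_mix[0]),
                        "site": "vaccination hub",
                        "administered_at": day.isoformat(),
                    },
                )
            )
            violations.append(ViolationEntry(ghost_rid, "R1", "vaccinations", day.isoformat()))
            truths.append(ghost)

    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return EventStream(events=events, truths=truths, violations=violations)


def _draw_categorical(rng: np.random.Generator, mix: dict[str, float]) -> str:
    u = rng.random()
    acc = 0.0
    labels = list(mix)
    for label in labels:
        acc += mix[label]
        if u < acc:
            return label
    return labels[-1]


def _simulate_doses(rng, config, truth, events, violations, history_ts, corruption):
    rid = truth.respondent_id
    cell = (truth.institution, truth.gender, truth.age_band)
    vax_days: list[dt.date] = []
    adr_events: list[tuple[dt.datetime, dict]] = []
    prev_admin = True
    for d in (1, 2, 3):
        admin_stage, adr_stage = f"admin{d}", f"adr{d}"
        admin = prev_admin and rng.random() < config.stage_probability(admin_stage, *cell)
        truth.stages[admin_stage] = admin
        adr = False
        if admin:
            day = _uniform_date(rng, *config.dose_windows[d - 1])
            vax_days.append(day)
            submit_day = max(day, history_ts.date())
            ts = _at(submit_day, 12, int(rng.integers(0, 60)))
            events.append(
                (
                    ts,
                    "vaccination",
                    rid,
                    {
                        "vaccine": _draw_categorical(rng, config.vaccine_mix[d - 1]),
                        "site": "vaccination hub" if d < 3 else "external hub",
                        "administered_at": day.isoformat(),
                    },
                )
            )
            adr = rng.random() < config.stage_probability(adr_stage, *cell)
            if adr:
                frailty = (
                    float(rng.normal(0.0, config.symptom_model.frailty_sd))
                    if config.symptom_model.frailty_sd > 0
                    else 0.0
                )
                symptoms = [
                    s
                    for s in SYMPTOMS
                    if rng.random()
                    < config.symptom_model.probability(s, truth.gender, truth.age_band, d, frailty)
                ]
                adr_day = day + dt.timedelta(days=7 + int(rng.integers(0, 3)))
                adr_events.append((_at(adr_day, 18, int(rng.integers(0, 60))), {"symptoms": symptoms}))
        truth.stages[adr_stage] = adr
        prev_admin = admin

    for ts, payload in adr_events:
        events.append((ts, "adr", rid, payload))

    _inject_corruption(rng, config, truth, events, violations, vax_days, adr_events, corruption)


def _inject_corruption(rng, config, truth, events, violations, vax_days, adr_events, corruption):
    """Append records that violate exactly one curation rule each."""
    rid = truth.respondent_id
    if not vax_days:
        return
    first_day = vax_days[0]
    last_ts = max(e[0] for e in events if e[2] == rid)

    if rng.random() < corruption["R2"]:
        # Same calendar date as dose 1, submitted later.
        ts = last_ts + dt.timedelta(hours=2)
        events.append(
            (
                ts,
                "vaccination",
                rid,
                {
                    "vaccine": _draw_categorical(rng, config.vaccine_mix[0]),
                    "site": "vaccination hub",
                    "administered_at": first_day.isoformat(),
                },
            )
        )
        violations.append(ViolationEntry(rid, "R2", "vaccinations", first_day.isoformat()))
        last_ts = ts
    if rng.random() < corruption["R3"]:
        # Earlier calendar date than dose 1, submitted after everything else.
        day = first_day - dt.timedelta(days=1)
        ts = last_ts + dt.timedelta(hours=3)
        events.append(
            (
                ts,
                "vaccination",
                rid,
                {
                    "vaccine": _draw_categorical(rng, config.vaccine_mix[0]),
                    "site": "vaccination hub",
                    "administered_at": day.isoformat(),
                },
            )
        )
        violations.append(ViolationEntry(rid, "R3", "vaccinations", day.isoformat()))
        last_ts = ts
    if rng.random() < corruption["R4"]:
        # ADR report submitted the day before the first vaccination.
        ts = _at(first_day - dt.timedelta(days=1), 9, int(rng.integers(0, 60)))
        events.append((ts, "adr", rid, {"symptoms": ["headache"]}))
        violations.append(ViolationEntry(rid, "R4", "adr_reports", ts.isoformat()))
    if len(adr_events) == len(vax_days) and rng.random() < corruption["R5"]:
        # One report more than there are vaccinations, submitted last.
        ts = last_ts + dt.timedelta(days=10)
        events.append((ts, "adr", rid, {"symptoms": []}))
        violations.append(ViolationEntry(rid, "R5", "adr_reports", ts.isoformat()))


# ---------------------------------------------------------------------------
# Analytic funnel oracle
# ---------------------------------------------------------------------------


def expected_funnel(config: SimulationConfig) -> dict[str, dict]:
    """Closed-form expected counts per stage (total and per stratum).

    Enumerates the 12 demographic cells and chains the conditional stage
    probabilities, mirroring the generative process exactly (including the
    clipping of cell probabilities), so it serves as an independent oracle
    for simulated stage counts.
    """
    cells = []
    for inst, p_i in config.institution_mix.items():
        for gen, p_g in config.gender_mix.items():
            for band, p_a in config.age_mix.items():
                cells.append(((inst, gen, band), p_i * p_g * p_a))

    out: dict[str, dict] = {}
    survival = {cell: config.n_invited * config.p_register * mass for cell, mass in cells}
    out["history"] = _summarize(survival)
    # admin chain carries forward; adr stages branch off their dose's admin.
    admin_survival = dict(survival)
    for d in (1, 2, 3):
        admin_stage, adr_stage = f"admin{d}", f"adr{d}"
        admin_survival = {
            cell: n * config.stage_probability(admin_stage, *cell)
            for cell, n in admin_survival.items()
        }
        out[admin_stage] = _summarize(admin_survival)
        adr_survival = {
            cell: n * config.stage_probability(adr_stage, *cell)
            for cell, n in admin_survival.items()
        }
        out[adr_stage] = _summarize(adr_survival)
    return out


def _summarize(survival: dict[tuple[str, str, str], float]) -> dict:
    total = sum(survival.values())
    summary: dict = {"N": total}
    for idx, factor in enumerate(_FACTORS):
        acc: dict[str, float] = {}
        for cell, n in survival.items():
            acc[cell[idx]] = acc.get(cell[idx], 0.0) + n
        summary[factor] = acc
    return summary
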