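"""Batch orchestration: simulate → curate → report, with a structured config.

Each command is deterministic given config + seed; the log carries the
config hash and seed for provenance, and INFO-level messages narrate the
participation funnel (registrations, per-dose submissions, discards).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import analytics
from .core_model import DEFAULT_STUDY_WINDOW, StudyWindow
from .curation import AnalysisDataset, build_dataset, read_export
from .simulator import SimulationConfig, default_config, simulate

__all__ = [
    "PipelineConfig",
    "default_pipeline_config",
    "load_config",
    "cmd_simulate",
    "cmd_curate",
    "cmd_report",
    "funnel_summary",
]

logger = logging.getLogger("adrlong")

_STAGE_SEQUENCE: tuple[tuple[str, Optional[int]], ...] = (
    ("history", None),
    ("admin", 1),
    ("adr", 1),
    ("admin", 2),
    ("adr", 2),
    ("admin", 3),
    ("adr", 3),
)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    export_dir: Path = Path("data/export")
    curated_dir: Path = Path("data/curated")
    reports_dir: Path = Path("data/reports")
    study_window_start: dt.date = DEFAULT_STUDY_WINDOW.start
    study_window_end: dt.date = DEFAULT_STUDY_WINDOW.end
    #: Campaign denominators used only for reporting percentages of the
    #: vaccinated population (they are external to the collected data).
    first_wave_vaccinated: int = Field(default=3712, gt=0)
    second_wave_vaccinated: int = Field(default=3718, gt=0)
    simulation: SimulationConfig = Field(default_factory=default_config)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _validate(self) -> "PipelineConfig":
        paths = [self.export_dir, self.curated_dir, self.reports_dir]
        if len({str(p) for p in paths}) != len(paths):
            raise ValueError("export_dir, curated_dir, reports_dir must be distinct")
        if self.study_window_start > self.study_window_end:
            raise ValueError("study window start after end")
        return self

    @property
    def study_window(self) -> StudyWindow:
        return StudyWindow(self.study_window_start, self.study_window_end)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_pipeline_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML pipeline config; omitted keys take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _setup_logging(config: PipelineConfig) -> None:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------


def cmd_simulate(config: PipelineConfig, seed: Optional[int] = None) -> Path:
    """Generate a synthetic campaign and write the export tables."""
    _setup_logging(config)
    effective_seed = config.simulation.seed if seed is None else seed
    logger.info(
        "simulate: config=%s seed=%d n_invited=%d",
        config.config_hash(), effective_seed, config.simulation.n_invited,
    )
    stream = simulate(config.simulation, seed=effective_seed)
    stream.write(config.export_dir)
    counts = stream.stage_counts()
    logger.info(
        "simulated funnel: history=%d admin=[%d, %d, %d] adr=[%d, %d, %d] "
        "injected_violations=%d",
        counts["history"],
        counts["admin1"], counts["admin2"], counts["admin3"],
        counts["adr1"], counts["adr2"], counts["adr3"],
        len(stream.violations),
    )
    return Path(config.export_dir)


def cmd_curate(config: PipelineConfig) -> AnalysisDataset:
    """Curate the export into the analysis dataset + discard log."""
    _setup_logging(config)
    logger.info("curate: config=%s reading %s", config.config_hash(), config.export_dir)
    dataset = build_dataset(read_export(config.export_dir), window=config.study_window)
    out = Path(config.curated_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(out / "analysis_dataset.csv", index=False)
    dataset.discard_frame().to_csv(out / "discard_log.csv", index=False)
    for rule, count in sorted(dataset.discard_counts().items()):
        logger.info("discarded under %s: %d", rule, count)
    logger.info("curated %d timelines, %d discards",
                len(dataset.timelines), len(dataset.discard_log))
    return dataset


def funnel_summary(config: PipelineConfig, dataset: AnalysisDataset) -> str:
    """Human-readable participation funnel with configured denominators."""
    lines = ["Participation funnel"]
    n_hist = len(analytics.stage_members(dataset, "history"))
    lines.append(
        f"  medical histories: {n_hist} "
        f"({analytics.percent(min(n_hist, config.first_wave_vaccinated), config.first_wave_vaccinated)}% "
        f"of {config.first_wave_vaccinated} first-wave vaccinated)"
    )
    for dose, denominator in ((1, config.first_wave_vaccinated),
                              (2, config.second_wave_vaccinated), (3, None)):
        n_admin = len(analytics.stage_members(dataset, "admin", dose))
        n_adr = len(analytics.stage_members(dataset, "adr", dose))
        if denominator:
            pct_admin = analytics.percent(min(n_admin, denominator), denominator)
            pct_adr = analytics.percent(min(n_adr, denominator), denominator)
            lines.append(
                f"  dose {dose}: vaccination data {n_admin} ({pct_admin}%), "
                f"ADR reports {n_adr} ({pct_adr}% of {denominator} vaccinated)"
            )
        else:
            lines.append(
                f"  dose {dose}: vaccination data {n_admin}, ADR reports {n_adr} "
                f"(spontaneous, no campaign denominator)"
            )
    return "\n".join(lines)


def cmd_report(config: PipelineConfig) -> Path:
    """Compute all analytics exports from the curated export tables."""
    _setup_logging(config)
    logger.info("report: config=%s", config.config_hash())
    dataset = build_dataset(read_export(config.export_dir), window=config.study_window)
    out = Path(config.reports_dir)
    out.mkdir(parents=True, exist_ok=True)

    empty = not any(tl.history is not None for tl in dataset.timelines)

    # Participation tables for every stage × stratifier with members.
    tables = []
    if not empty:
        for stage, dose in _STAGE_SEQUENCE:
            if stage != "history" and not analytics.stage_members(dataset, stage, dose):
                continue
            for stratifier in analytics.STRATIFIERS:
                tables.append(
                    analytics.participation_table(dataset, stratifier, stage, dose).to_frame()
                )
    pd.concat(tables, ignore_index=True).to_csv(
        out / "participation_tables.csv", index=False
    ) if tables else _write_empty(
        out / "participation_tables.csv", ["stage", "dose", "stratifier", "stratum", "n", "pct"]
    )

    mix_rows = []
    for dose in (None, 1, 2, 3):
        for vaccine, n, pct in analytics.vaccine_mix(dataset, dose):
            mix_rows.append(
                {"dose": dose if dose is not None else "all", "vaccine": vaccine, "n": n, "pct": pct}
            )
    pd.DataFrame(mix_rows).to_csv(out / "vaccine_mix.csv", index=False)

    prevalence_frames = []
    if not empty:
        disease = analytics.disease_prevalence(dataset)
        disease.insert(0, "kind", "chronic_condition")
        disease = disease.rename(columns={"condition": "label"})
        disease["dose"] = ""
        disease["age_band"] = ""
        prevalence_frames.append(disease)
        for dose in (1, 2, 3):
            adr = analytics.adr_prevalence(dataset, dose)
            if len(adr):
                adr.insert(0, "kind", "symptom")
                adr = adr.rename(columns={"symptom": "label"})
                prevalence_frames.append(adr)
    prevalence_cols = ["kind", "label", "gender", "age_band", "dose", "n", "N", "prevalence", "pct"]
    if prevalence_frames:
        pd.concat(prevalence_frames, ignore_index=True)[prevalence_cols].to_csv(
            out / "prevalence.csv", index=False
        )
    else:
        _write_empty(out / "prevalence.csv", prevalence_cols)

    contingency_rows = []
    for dose in (1, 2, 3):
        for stratifier in analytics.STRATIFIERS:
            if not analytics.stage_members(dataset, "adr", dose):
                continue
            table = analytics.dichotomize(dataset, dose, stratifier)
            try:
                statistic, dof, p = analytics.chi_square(table)
            except ValueError:
                statistic, dof, p = float("nan"), table.df, float("nan")
            for row_label in table.observed.index:
                for col_label in table.observed.columns:
                    contingency_rows.append(
                        {
                            "dose": dose,
                            "stratifier": stratifier,
                            "group": row_label,
                            "stratum": col_label,
                            "n": int(table.observed.loc[row_label, col_label]),
                            "statistic": statistic,
                            "df": dof,
                            "p_value": p,
                        }
                    )
    contingency_cols = ["dose", "stratifier", "group", "stratum", "n", "statistic", "df", "p_value"]
    (
        pd.DataFrame(contingency_rows, columns=contingency_cols)
        if contingency_rows
        else pd.DataFrame(columns=contingency_cols)
    ).to_csv(out / "contingency.csv", index=False)

    analytics.flow_matrix(dataset).to_frame().to_csv(out / "flows.csv", index=False)

    summary = funnel_summary(config, dataset) if not empty else "Participation funnel\n  (empty dataset)"
    (out / "summary.txt").write_text(summary + "\n")
    for line in summary.splitlines():
        logger.info("%s", line)
    return out


def _write_empty(path: Path, columns: list[str]) -> None:
    pd.DataFrame(columns=columns).to_csv(path, index=False)
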