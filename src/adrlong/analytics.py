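"""Descriptive and longitudinal analytics over the curated dataset.

Reproduces the campaign's reporting computations:

* participation tables — counts and one-decimal percentages per stratum
  (institution, gender, age band) at each funnel stage;
* the administered-vaccine mix, per dose or pooled;
* chronic-disease prevalence by gender (radar-plot-ready);
* the symptom-count dichotomy (≥3 vs <3 symptoms) cross-tabulated against a
  stratifier, with a Pearson chi-square test (no continuity correction);
* per-symptom ADR prevalence by gender × age band × dose;
* the dose-to-dose transition flow matrix over symptom-count classes
  {0, 1, 2, 3, >3} for respondents who reported after all three doses
  (Sankey-ready).

Percentages are rounded half-up to one decimal.  The dichotomy boundary
places exactly-3-symptom reports in the ≥3 group.  Empty strata are
reported as absent rather than zero, distinguishing "no respondents" from
"no events".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .core_model import GENDERS, INSTITUTIONS, SYMPTOMS, VACCINES, AdrReport
from .curation import AnalysisDataset, Timeline

__all__ = [
    "AGE_BAND_LABELS",
    "SYMPTOM_CLASSES",
    "STRATIFIERS",
    "age_band",
    "percent",
    "StratumTable",
    "ContingencyTable",
    "FlowMatrix",
    "stage_members",
    "participation_table",
    "vaccine_mix",
    "disease_prevalence",
    "symptom_class",
    "dichotomize",
    "chi_square",
    "adr_prevalence",
    "flow_matrix",
]

AGE_BAND_LABELS = ("<30", "30-55", ">55")
SYMPTOM_CLASSES = ("0", "1", "2", "3", ">3")

#: Canonical stratum orders per stratifier; unknown labels (e.g. a future
#: gender value) are appended after the known ones as their own group.
STRATIFIERS: dict[str, tuple[str, ...]] = {
    "institution": INSTITUTIONS,
    "gender": GENDERS,
    "age_band": AGE_BAND_LABELS,
}


def age_band(age: int) -> str:
    """Partition adult ages into <30 ([18,29]), 30-55, >55 ([56,∞))."""
    if age < 30:
        return "<30"
    if age <= 55:
        return "30-55"
    return ">55"


def percent(n: int, N: int) -> float:
    """100·n/N rounded half-up to one decimal (the tables' convention)."""
    if N == 0:
        raise ZeroDivisionError("percentage undefined for N = 0")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    value = (Decimal(100) * Decimal(n) / Decimal(N)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(value)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumTable:
    """Counts and relative frequencies per stratum at one funnel stage."""

    stage: str
    dose: Optional[int]
    stratifier: str
    strata: tuple[tuple[str, int, float], ...]  # (label, n, pct)
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": self.stage,
                    "dose": self.dose if self.dose is not None else "",
                    "stratifier": self.stratifier,
                    "stratum": label,
                    "n": n,
                    "pct": pct,
                }
                for label, n, pct in self.strata
            ]
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Observed/expected counts for the ≥3 vs <3 symptom dichotomy."""

    observed: pd.DataFrame  # rows: ">=3", "<3"; columns: strata
    dose: int
    stratifier: str

    @property
    def expected(self) -> pd.DataFrame:
        o = self.observed.to_numpy(dtype=float)
        row = o.sum(axis=1, keepdims=True)
        col = o.sum(axis=0, keepdims=True)
        return pd.DataFrame(
            row @ col / o.sum(), index=self.observed.index, columns=self.observed.columns
        )

    @property
    def df(self) -> int:
        r, c = self.observed.shape
        return (r - 1) * (c - 1)


@dataclass(frozen=True)
class FlowMatrix:
    """Symptom-count class transitions across doses 1→2 and 2→3.

    Restricted to complete responders (an ADR report attributed to every one
    of the three doses), so total flow is conserved across both level pairs.
    """

    flows: dict[tuple[int, str, str], int]  # (source dose, src class, dst class) -> n
    node_totals: dict[tuple[int, str], int]  # (dose, class) -> n
    complete_responders: int

    def level_total(self, source_dose: int) -> int:
        return sum(n for (d, _, _), n in self.flows.items() if d == source_dose)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": f"dose{d}->dose{d + 1}",
                "source_class": src,
                "destination_class": dst,
                "count": n,
            }
            for (d, src, dst), n in sorted(
                self.flows.items(),
                key=lambda kv: (
                    kv[0][0],
                    SYMPTOM_CLASSES.index(kv[0][1]),
                    SYMPTOM_CLASSES.index(kv[0][2]),
                ),
            )
        ]
        return pd.DataFrame(
            rows, columns=["level", "source_class", "destination_class", "count"]
        )


# ---------------------------------------------------------------------------
# Stage membership and stratification
# ---------------------------------------------------------------------------


def _stratum_of(tl: Timeline, stratifier: str) -> str:
    assert tl.history is not None
    if stratifier == "institution":
        return tl.history.institution
    if stratifier == "gender":
        return tl.history.gender
    if stratifier == "age_band":
        return age_band(tl.history.age)
    raise ValueError(f"unknown stratifier: {stratifier!r}")


def stage_members(
    dataset: AnalysisDataset, stage: str, dose: Optional[int] = None
) -> list[Timeline]:
    """Timelines present at a funnel stage.

    ``stage`` is ``"history"``, ``"admin"`` or ``"adr"``; the latter two
    require ``dose`` in 1..3.  Presence always implies a retained medical
    history (rule R1), so stratification is well defined.
    """
    with_history = [tl for tl in dataset.timelines if tl.history is not None]
    if stage == "history":
        return with_history
    if stage not in ("admin", "adr") or dose is None:
        raise ValueError(f"unknown stage: {stage!r} (dose={dose!r})")
    if stage == "admin":
        return [tl for tl in with_history if tl.vaccination_for_dose(dose) is not None]
    return [tl for tl in with_history if tl.adr_for_dose(dose) is not None]


def _ordered_labels(stratifier: str, present: Sequence[str]) -> list[str]:
    known = [s for s in STRATIFIERS[stratifier] if s in present]
    unknown = sorted(set(present) - set(STRATIFIERS[stratifier]))
    return known + unknown


def participation_table(
    dataset: AnalysisDataset,
    stratifier: str,
    stage: str,
    dose: Optional[int] = None,
) -> StratumTable:
    """Per-stratum counts and percentages of one funnel stage's total."""
    members = stage_members(dataset, stage, dose)
    if not members:
        raise ValueError(f"stage {stage!r} (dose={dose!r}) is empty")
    counts: dict[str, int] = {}
    for tl in members:
        label = _stratum_of(tl, stratifier)
        counts[label] = counts.get(label, 0) + 1
    N = len(members)
    strata = tuple(
        (label, counts[label], percent(counts[label], N))
        for label in _ordered_labels(stratifier, list(counts))
    )
    return StratumTable(stage=stage, dose=dose, stratifier=stratifier, strata=strata, N=N)


def vaccine_mix(
    dataset: AnalysisDataset, dose: Optional[int] = None
) -> tuple[tuple[str, int, float], ...]:
    """Administered-vaccine counts and percentages for one dose (or all
    study doses pooled when ``dose`` is None)."""
    counts = {v: 0 for v in VACCINES}
    for tl in dataset.timelines:
        for vax in tl.vaccinations:
            if vax.out_of_study or vax.dose is None:
                continue
            if dose is not None and vax.dose != dose:
                continue
            counts[vax.record.vaccine] += 1
    total = sum(counts.values())
    return tuple(
        (v, counts[v], percent(counts[v], total) if total else 0.0) for v in VACCINES
    )


def disease_prevalence(dataset: AnalysisDataset) -> pd.DataFrame:
    """Chronic-disease prevalence per condition and gender.

    Denominator: respondents of that gender with a medical history.  Raises
    if a gender stratum is empty (prevalence undefined).
    """
    from .core_model import CHRONIC_CONDITIONS

    members = stage_members(dataset, "history")
    by_gender: dict[str, list[Timeline]] = {}
    for tl in members:
        by_gender.setdefault(tl.history.gender, []).append(tl)
    if not by_gender:
        raise ValueError("no medical histories: prevalence undefined")
    rows = []
    for gender in _ordered_labels("gender", list(by_gender)):
        group = by_gender[gender]
        for cond in CHRONIC_CONDITIONS:
            n_with = sum(1 for tl in group if cond in tl.history.conditions)
            rows.append(
                {
                    "condition": cond,
                    "gender": gender,
                    "n": n_with,
                    "N": len(group),
                    "prevalence": n_with / len(group),
                    "pct": percent(n_with, len(group)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Symptom-count dichotomy and chi-square
# ---------------------------------------------------------------------------


def symptom_class(report: AdrReport | int) -> str:
    """Map a report (or symptom count) to the class {0, 1, 2, 3, >3}."""
    k = report if isinstance(report, int) else len(report.symptoms)
    if k < 0:
        raise ValueError("negative symptom count")
    return str(k) if k <= 3 else ">3"


def dichotomize(dataset: AnalysisDataset, dose: int, stratifier: str) -> ContingencyTable:
    """Cross-tabulate the ≥3 / <3 symptom dichotomy against a stratifier.

    A reporter with exactly 3 symptoms lands in the ≥3 row.
    """
    members = stage_members(dataset, "adr", dose)
    if not members:
        raise ValueError(f"no ADR reporters at dose {dose}")
    labels = _ordered_labels(stratifier, [_stratum_of(tl, stratifier) for tl in members])
    observed = pd.DataFrame(0, index=[">=3", "<3"], columns=labels, dtype=int)
    for tl in members:
        adr = tl.adr_for_dose(dose)
        assert adr is not None
        row = ">=3" if len(adr.record.symptoms) >= 3 else "<3"
        observed.loc[row, _stratum_of(tl, stratifier)] += 1
    return ContingencyTable(observed=observed, dose=dose, stratifier=stratifier)


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on the dichotomy table.

    No continuity correction; degrees of freedom (r−1)(c−1).  Requires all
    row and column margins to be positive.
    """
    o = table.observed.to_numpy(dtype=float)
    if (o.sum(axis=0) == 0).any() or (o.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    result = stats.chi2_contingency(o, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def adr_prevalence(dataset: AnalysisDataset, dose: int) -> pd.DataFrame:
    """Per-symptom prevalence among dose-``dose`` reporters, by gender and
    age band.  Strata with no reporters are absent from the output."""
    members = stage_members(dataset, "adr", dose)
    groups: dict[tuple[str, str], list[Timeline]] = {}
    for tl in members:
        key = (tl.history.gender, age_band(tl.history.age))
        groups.setdefault(key, []).append(tl)
    rows = []
    for gender in _ordered_labels("gender", [g for g, _ in groups]):
        for band in _ordered_labels("age_band", [b for _, b in groups]):
            group = groups.get((gender, band))
            if not group:
                continue
            for symptom in SYMPTOMS:
                n_with = sum(
                    1
                    for tl in group
                    if symptom in tl.adr_for_dose(dose).record.symptoms
                )
                rows.append(
                    {
                        "dose": dose,
                        "symptom": symptom,
                        "gender": gender,
                        "age_band": band,
                        "n": n_with,
                        "N": len(group),
                        "prevalence": n_with / len(group),
                        "pct": percent(n_with, len(group)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["dose", "symptom", "gender", "age_band", "n", "N", "prevalence", "pct"]
    )


# ---------------------------------------------------------------------------
# Longitudinal flows
# ---------------------------------------------------------------------------


def flow_matrix(dataset: AnalysisDataset) -> FlowMatrix:
    """Symptom-count class flows for complete responders (all three doses)."""
    flows: dict[tuple[int, str, str], int] = {}
    node_totals: dict[tuple[int, str], int] = {}
    complete = 0
    for tl in dataset.timelines:
        if tl.history is None:
            continue
        reports = [tl.adr_for_dose(d) for d in (1, 2, 3)]
        if any(r is None for r in reports):
            continue
        complete += 1
        classes = [symptom_class(r.record) for r in reports]
        for d, cls in enumerate(classes, start=1):
            node_totals[(d, cls)] = node_totals.get((d, cls), 0) + 1
        for d in (1, 2):
            key = (d, classes[d - 1], classes[d])
            flows[key] = flows.get(key, 0) + 1
    return FlowMatrix(flows=flows, node_totals=node_totals, complete_responders=complete)
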