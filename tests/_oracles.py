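"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain scans over dict rows,
sharing no code with the package's curation or analytics paths.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter

import pandas as pd


def _rows(frame: pd.DataFrame) -> list[dict]:
    return frame.to_dict("records")


def oracle_curate(tables: dict[str, pd.DataFrame]):
    """Exhaustively apply the five consistency rules.

    Returns (retained vaccination ids, retained ADR ids ordered per
    respondent, discards as a set of (table, record_id, rule)).
    """
    history_ids = {str(r["respondent_id"]) for r in _rows(tables["histories"])}
    vax_rows = [dict(r) for r in _rows(tables["vaccinations"])]
    adr_rows = [dict(r) for r in _rows(tables["adr_reports"])]
    for r in vax_rows:
        r["_sub"] = dt.datetime.fromisoformat(str(r["submitted_at"]))
        r["_day"] = dt.date.fromisoformat(str(r["administered_at"]))
    for r in adr_rows:
        r["_sub"] = dt.datetime.fromisoformat(str(r["submitted_at"]))

    discards: set[tuple[str, int, str]] = set()
    retained_vax: dict[str, list[int]] = {}
    retained_adr: dict[str, list[int]] = {}
    rids = {str(r["respondent_id"]) for r in vax_rows} | {
        str(r["respondent_id"]) for r in adr_rows
    } | history_ids

    for rid in rids:
        my_vax = sorted(
            (r for r in vax_rows if str(r["respondent_id"]) == rid),
            key=lambda r: (r["_sub"], int(r["record_id"])),
        )
        my_adr = sorted(
            (r for r in adr_rows if str(r["respondent_id"]) == rid),
            key=lambda r: (r["_sub"], int(r["record_id"])),
        )
        if rid not in history_ids:
            for r in my_vax:
                discards.add(("vaccinations", int(r["record_id"]), "R1"))
            my_vax = []
        # R2: per calendar date keep the earliest-submitted.
        kept_by_date: dict[dt.date, dict] = {}
        for r in my_vax:
            if r["_day"] in kept_by_date:
                discards.add(("vaccinations", int(r["record_id"]), "R2"))
            else:
                kept_by_date[r["_day"]] = r
        # R3: strictly increasing dates along submission order.
        survivors = []
        high = None
        for r in my_vax:
            if r["_day"] in kept_by_date and kept_by_date[r["_day"]] is r:
                if high is not None and r["_day"] <= high:
                    discards.add(("vaccinations", int(r["record_id"]), "R3"))
                else:
                    survivors.append(r)
                    high = r["_day"]
        retained_vax[rid] = [int(r["record_id"]) for r in survivors]
        # R4: reports submitted before the first retained vaccination date.
        first_day = survivors[0]["_day"] if survivors else None
        candidates = []
        for r in my_adr:
            if first_day is not None and r["_sub"].date() < first_day:
                discards.add(("adr_reports", int(r["record_id"]), "R4"))
            else:
                candidates.append(r)
        # R5: at most one report per retained vaccination, earliest kept.
        for r in candidates[len(survivors):]:
            discards.add(("adr_reports", int(r["record_id"]), "R5"))
        retained_adr[rid] = [int(r["record_id"]) for r in candidates[: len(survivors)]]

    return retained_vax, retained_adr, discards


def chi_square_formula(observed) -> float:
    """Direct Σ(O−E)²/E on a 2-D table of counts."""
    observed = [list(map(float, row)) for row in observed]
    total = sum(sum(row) for row in observed)
    row_sums = [sum(row) for row in observed]
    col_sums = [sum(row[j] for row in observed) for j in range(len(observed[0]))]
    stat = 0.0
    for i, row in enumerate(observed):
        for j, o in enumerate(row):
            e = row_sums[i] * col_sums[j] / total
            stat += (o - e) ** 2 / e
    return stat


def tally_stage_counts(dataset, stage: str, dose, stratifier: str) -> Counter:
    """Group-by tally over timelines, independent of the analytics path."""
    counts: Counter = Counter()
    for tl in dataset.timelines:
        if tl.history is None:
            continue
        if stage == "admin" and not any(v.dose == dose for v in tl.vaccinations):
            continue
        if stage == "adr" and not any(a.record.dose_ref == dose for a in tl.adr_reports):
            continue
        h = tl.history
        if stratifier == "institution":
            key = h.institution
        elif stratifier == "gender":
            key = h.gender
        else:
            key = "<30" if h.age < 30 else ("30-55" if h.age <= 55 else ">55")
        counts[key] += 1
    return counts


def tally_flows(dataset) -> tuple[Counter, int]:
    """Pairwise transition tally over complete responders."""

    def clazz(symptoms) -> str:
        k = len(symptoms)
        return str(k) if k <= 3 else ">3"

    flows: Counter = Counter()
    complete = 0
    for tl in dataset.timelines:
        if tl.history is None:
            continue
        per_dose = {a.record.dose_ref: a.record.symptoms for a in tl.adr_reports}
        if not all(d in per_dose for d in (1, 2, 3)):
            continue
        complete += 1
        c1, c2, c3 = (clazz(per_dose[d]) for d in (1, 2, 3))
        flows[(1, c1, c2)] += 1
        flows[(2, c2, c3)] += 1
    return flows, complete
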