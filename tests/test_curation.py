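"""Curation: assembly, consistency rules R1–R5, dose labeling."""

import random

import pandas as pd
import pytest

from adrlong.curation import assemble, build_dataset, consistency_filter, label_doses

from _oracles import oracle_curate
from conftest import EXPORT_COLUMNS, empty_tables, random_export


def tables_from(hist_rows, vax_rows, adr_rows):
    return {
        "histories": pd.DataFrame(hist_rows, columns=EXPORT_COLUMNS["histories"]),
        "vaccinations": pd.DataFrame(vax_rows, columns=EXPORT_COLUMNS["vaccinations"]),
        "adr_reports": pd.DataFrame(adr_rows, columns=EXPORT_COLUMNS["adr_reports"]),
    }


def hist_row(rid, **kw):
    row = {
        "respondent_id": rid, "institution": "UniMiB", "gender": "female",
        "age": 30, "conditions": "", "submitted_at": "2021-02-20T08:00:00",
    }
    row.update(kw)
    return row


def vax_row(record_id, rid, day, submitted, vaccine="Comirnaty"):
    return {
        "record_id": record_id, "respondent_id": rid, "vaccine": vaccine,
        "site": "hub", "administered_at": day, "submitted_at": submitted,
    }


def adr_row(record_id, rid, submitted, symptoms="fever"):
    return {
        "record_id": record_id, "respondent_id": rid,
        "symptoms": symptoms, "submitted_at": submitted,
    }


class TestAssemble:
    def test_empty_tables_yield_empty_collection(self):
        assert assemble(empty_tables()) == []

    def test_one_timeline_per_respondent_across_tables(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "b", "2021-03-10", "2021-03-10T12:00:00")],
            [adr_row(1, "c", "2021-03-20T18:00:00")],
        )
        timelines = assemble(tables)
        assert [tl.respondent_id for tl in timelines] == ["a", "b", "c"]

    def test_row_permutation_invariance(self):
        rng = random.Random(5)
        tables = random_export(rng, 30)
        shuffled = {
            name: frame.sample(frac=1.0, random_state=99).reset_index(drop=True)
            for name, frame in tables.items()
        }
        a = build_dataset(tables)
        b = build_dataset(shuffled)
        assert a.to_frame().equals(b.to_frame())
        assert sorted(map(tuple, a.discard_frame().values.tolist())) == sorted(
            map(tuple, b.discard_frame().values.tolist())
        )

    def test_unknown_columns_rejected(self):
        tables = empty_tables()
        tables["histories"]["extra"] = []
        with pytest.raises(ValueError, match="columns"):
            assemble(tables)


class TestConsistencyRules:
    def test_fully_consistent_timeline_unchanged(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00"),
             vax_row(1, "a", "2021-06-01", "2021-06-01T12:00:00")],
            [adr_row(2, "a", "2021-03-17T18:00:00"),
             adr_row(3, "a", "2021-06-08T18:00:00")],
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert log == []
        assert len(filtered.vaccinations) == 2 and len(filtered.adr_reports) == 2

    def test_r1_vaccination_without_history(self):
        tables = tables_from(
            [], [vax_row(0, "ghost", "2021-03-10", "2021-03-10T12:00:00")], []
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert filtered.vaccinations == []
        assert [e.rule for e in log] == ["R1"]

    def test_r2_same_date_keeps_earliest_submitted(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T15:00:00"),
             vax_row(1, "a", "2021-03-10", "2021-03-10T09:00:00")],
            [],
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert [v.record_id for v in filtered.vaccinations] == [1]
        assert [(e.rule, e.record_id) for e in log] == [("R2", 0)]

    def test_r3_backdated_vaccination_dropped(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00"),
             vax_row(1, "a", "2021-03-05", "2021-04-01T12:00:00")],
            [],
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert [v.record_id for v in filtered.vaccinations] == [0]
        assert [(e.rule, e.record_id) for e in log] == [("R3", 1)]

    def test_r4_report_before_first_vaccination_dropped(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00")],
            [adr_row(1, "a", "2021-03-09T18:00:00"),
             adr_row(2, "a", "2021-03-17T18:00:00")],
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert [a.record_id for a in filtered.adr_reports] == [2]
        assert [(e.rule, e.record_id) for e in log] == [("R4", 1)]

    def test_r5_surplus_reports_dropped_earliest_kept(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00")],
            [adr_row(1, "a", "2021-03-17T18:00:00"),
             adr_row(2, "a", "2021-03-19T18:00:00")],
        )
        (timeline,) = assemble(tables)
        filtered, log = consistency_filter(timeline)
        assert [a.record_id for a in filtered.adr_reports] == [1]
        assert [(e.rule, e.record_id) for e in log] == [("R5", 2)]

    def test_randomized_fixtures_match_brute_force_oracle(self):
        rng = random.Random(2021)
        for trial in range(40):
            tables = random_export(rng, 25)
            dataset = build_dataset(tables)
            retained_vax, retained_adr, discards = oracle_curate(tables)
            got_discards = {
                (e.table, e.record_id, e.rule) for e in dataset.discard_log
            }
            assert got_discards == discards, f"trial {trial}"
            for tl in dataset.timelines:
                assert [v.record_id for v in tl.vaccinations] == sorted(
                    retained_vax.get(tl.respondent_id, []),
                    key=lambda r: next(
                        v.record.administered_at for v in tl.vaccinations if v.record_id == r
                    ),
                )
                assert [a.record_id for a in tl.adr_reports] == retained_adr.get(
                    tl.respondent_id, []
                )


class TestDoseLabeling:
    def test_single_vaccination_is_dose_one(self):
        tables = tables_from(
            [hist_row("a")], [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00")], []
        )
        (timeline,) = assemble(tables)
        labeled = label_doses(consistency_filter(timeline)[0])
        assert [v.dose for v in labeled.vaccinations] == [1]

    def test_three_campaign_waves_labeled_in_date_order(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00"),
             vax_row(1, "a", "2021-06-05", "2021-06-05T12:00:00"),
             vax_row(2, "a", "2022-01-10", "2022-01-10T12:00:00")],
            [],
        )
        (timeline,) = assemble(tables)
        labeled = label_doses(consistency_filter(timeline)[0])
        assert [(v.dose, v.out_of_study) for v in labeled.vaccinations] == [
            (1, False), (2, False), (3, False),
        ]

    def test_kth_report_maps_to_kth_dose(self):
        tables = tables_from(
            [hist_row("a")],
            [vax_row(0, "a", "2021-03-10", "2021-03-10T12:00:00"),
             vax_row(1, "a", "2021-06-05", "2021-06-05T12:00:00")],
            [adr_row(2, "a", "2021-03-17T18:00:00")],
        )
        (timeline,) = assemble(tables)
        labeled = label_doses(consistency_filter(timeline)[0])
        assert [a.record.dose_ref for a in labeled.adr_reports] == [1]
        assert labeled.vaccination_for_dose(2) is not None
        assert labeled.adr_for_dose(2) is None

    def test_fourth_dose_flagged_out_of_study(self):
        rows = [
            vax_row(k, "a", f"2021-0{3 + 2 * k}-10", f"2021-0{3 + 2 * k}-10T12:00:00")
            for k in range(3)
        ] + [vax_row(3, "a", "2021-12-10", "2021-12-10T12:00:00")]
        (timeline,) = assemble(tables_from([hist_row("a")], rows, []))
        labeled = label_doses(consistency_filter(timeline)[0])
        assert [(v.dose, v.out_of_study) for v in labeled.vaccinations][-1] == (4, True)


class TestDatasetProperties:
    def test_empty_export_builds_empty_dataset(self):
        dataset = build_dataset(empty_tables())
        assert dataset.timelines == [] and dataset.discard_log == []

    def test_conservation_per_table(self):
        rng = random.Random(77)
        tables = random_export(rng, 60)
        dataset = build_dataset(tables)
        retained_vax = sum(len(tl.vaccinations) for tl in dataset.timelines)
        retained_adr = sum(len(tl.adr_reports) for tl in dataset.timelines)
        dropped = dataset.discard_frame().groupby("table").size().to_dict()
        assert retained_vax + dropped.get("vaccinations", 0) == len(tables["vaccinations"])
        assert retained_adr + dropped.get("adr_reports", 0) == len(tables["adr_reports"])

    def test_recuration_of_retained_export_discards_nothing(self):
        rng = random.Random(88)
        dataset = build_dataset(random_export(rng, 60))
        again = build_dataset(dataset.retained_export())
        assert again.discard_log == []

    def test_funnel_monotonicity(self, calibrated_dataset):
        """#ADR-reporters(d) <= #vaccination-submitters(d) <= #histories."""
        from adrlong.analytics import stage_members

        n_hist = len(stage_members(calibrated_dataset, "history"))
        for dose in (1, 2, 3):
            n_admin = len(stage_members(calibrated_dataset, "admin", dose))
            n_adr = len(stage_members(calibrated_dataset, "adr", dose))
            assert n_adr <= n_admin <= n_hist

    def test_simulated_violations_equal_discard_log(self):
        from adrlong.simulator import default_config, simulate

        config = default_config().model_copy(
            update={
                "n_invited": 600,
                "corruption_rates": {"R1": 0.05, "R2": 0.04, "R3": 0.04, "R4": 0.03, "R5": 0.03},
            }
        )
        stream = simulate(config, seed=17)
        dataset = build_dataset(stream.to_export())
        injected = stream.ground_truth_frame().groupby("rule").size().to_dict()
        observed = dataset.discard_counts()
        assert injected and observed == injected
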