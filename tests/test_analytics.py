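"""Analytics: percentages, stratified tables, chi-square, prevalence, flows."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrlong.analytics import (
    ContingencyTable,
    adr_prevalence,
    age_band,
    chi_square,
    dichotomize,
    disease_prevalence,
    flow_matrix,
    participation_table,
    percent,
    symptom_class,
    vaccine_mix,
)
from adrlong.core_model import AdrReport
from adrlong.curation import AnalysisDataset

from _oracles import chi_square_formula, tally_flows, tally_stage_counts
from conftest import make_timeline, random_dataset


class TestPercent:
    @pytest.mark.parametrize(
        ("n", "N", "expected"),
        [(1676, 2733, 61.3), (2226, 3712, 60.0), (0, 50, 0.0), (5, 4318, 0.1),
         (1, 800, 0.1), (7, 200, 3.5)],
    )
    def test_half_up_to_one_decimal(self, n, N, expected):
        assert percent(n, N) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 5000), st.data())
    def test_stratum_percentages_sum_to_about_100(self, N, data):
        """Σ pct over an exhaustive partition is 100 ± rounding slack."""
        cut1 = data.draw(st.integers(0, N))
        cut2 = data.draw(st.integers(0, cut1))
        parts = [N - cut1, cut1 - cut2, cut2]
        total = sum(percent(p, N) for p in parts)
        assert 100.0 - 0.2 <= total <= 100.0 + 0.2


class TestAgeBands:
    @pytest.mark.parametrize(
        ("age", "band"), [(18, "<30"), (29, "<30"), (30, "30-55"), (55, "30-55"),
                          (56, ">55"), (80, ">55")]
    )
    def test_bands_partition_adult_ages(self, age, band):
        assert age_band(age) == band


class TestSymptomClass:
    @pytest.mark.parametrize(
        ("count", "label"), [(0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, ">3"), (12, ">3")]
    )
    def test_classes_partition_counts(self, count, label):
        assert symptom_class(count) == label
        report = AdrReport(respondent_id="x", symptoms=tuple(f"s{i}" for i in range(count)))
        assert symptom_class(report) == label


class TestParticipationTable:
    def test_known_counts_give_published_shares(self):
        timelines = [make_timeline(f"u{i}", institution="UniMiB") for i in range(1676)]
        timelines += [make_timeline(f"p{i}", institution="PoliMi") for i in range(1057)]
        dataset = AnalysisDataset(timelines=timelines, discard_log=[])
        table = participation_table(dataset, "institution", "history")
        assert table.N == 2733
        assert table.strata == (("UniMiB", 1676, 61.3), ("PoliMi", 1057, 38.7))

    def test_single_stratum_is_100_percent(self):
        dataset = AnalysisDataset(timelines=[make_timeline("a")], discard_log=[])
        table = participation_table(dataset, "gender", "history")
        assert table.strata == (("female", 1, 100.0),)

    def test_empty_stage_raises(self):
        dataset = AnalysisDataset(timelines=[make_timeline("a")], discard_log=[])
        with pytest.raises(ValueError, match="empty"):
            participation_table(dataset, "gender", "adr", 3)

    @pytest.mark.parametrize("stratifier", ["institution", "gender", "age_band"])
    @pytest.mark.parametrize(("stage", "dose"), [("history", None), ("admin", 2), ("adr", 1)])
    def test_counts_match_brute_force_tally(self, stratifier, stage, dose):
        dataset = random_dataset(random.Random(31), 300)
        expected = tally_stage_counts(dataset, stage, dose, stratifier)
        table = participation_table(dataset, stratifier, stage, dose)
        assert {label: n for label, n, _ in table.strata} == dict(expected)
        assert table.N == sum(expected.values())


class TestVaccineMix:
    def test_single_record_is_100_percent(self):
        dataset = AnalysisDataset(
            timelines=[make_timeline("a", doses=[("Comirnaty", "2021-03-10")])],
            discard_log=[],
        )
        assert ("Comirnaty", 1, 100.0) in vaccine_mix(dataset)

    def test_pooled_vs_per_dose_tally(self):
        dataset = random_dataset(random.Random(32), 200)
        pooled = {v: n for v, n, _ in vaccine_mix(dataset)}
        per_dose_sum: dict[str, int] = {}
        for dose in (1, 2, 3):
            for v, n, _ in vaccine_mix(dataset, dose):
                per_dose_sum[v] = per_dose_sum.get(v, 0) + n
        assert pooled == per_dose_sum
        brute = {}
        for tl in dataset.timelines:
            for vax in tl.vaccinations:
                brute[vax.record.vaccine] = brute.get(vax.record.vaccine, 0) + 1
        assert {v: n for v, n in pooled.items() if n} == brute

    def test_simulated_boosters_have_no_vaxzevria(self, calibrated_dataset):
        mix = dict((v, n) for v, n, _ in vaccine_mix(calibrated_dataset, 3))
        assert mix["Vaxzevria"] == 0
        assert mix["Comirnaty"] + mix["moderna-mRNA1273"] > 0


class TestDiseasePrevalence:
    def test_no_flags_give_zero_everywhere(self):
        dataset = AnalysisDataset(
            timelines=[make_timeline("a"), make_timeline("b", gender="male")], discard_log=[]
        )
        frame = disease_prevalence(dataset)
        assert (frame["prevalence"] == 0).all()

    def test_bounded_and_matches_group_means(self):
        dataset = random_dataset(random.Random(33), 250)
        frame = disease_prevalence(dataset)
        assert frame["prevalence"].between(0, 1).all()
        for row in frame.itertuples():
            group = [
                tl for tl in dataset.timelines if tl.history.gender == row.gender
            ]
            n_with = sum(1 for tl in group if row.condition in tl.history.conditions)
            assert row.n == n_with and row.N == len(group)


class TestDichotomyAndChiSquare:
    def test_boundary_three_symptoms_in_ge3_row(self):
        dataset = AnalysisDataset(
            timelines=[
                make_timeline("a", doses=[("Comirnaty", "2021-03-10")],
                              adr_symptom_sets=[["fever", "headache", "nausea"]]),
                make_timeline("b", gender="male", doses=[("Comirnaty", "2021-03-10")],
                              adr_symptom_sets=[["fever", "headache"]]),
            ],
            discard_log=[],
        )
        table = dichotomize(dataset, 1, "gender")
        assert table.observed.loc[">=3", "female"] == 1
        assert table.observed.loc["<3", "male"] == 1
        assert table.df == 1

    def test_matches_brute_force_crosstab(self):
        dataset = random_dataset(random.Random(34), 400)
        table = dichotomize(dataset, 1, "age_band")
        for band in table.observed.columns:
            ge3 = lt3 = 0
            for tl in dataset.timelines:
                adr = tl.adr_for_dose(1)
                if adr is None or age_band(tl.history.age) != band:
                    continue
                if len(adr.record.symptoms) >= 3:
                    ge3 += 1
                else:
                    lt3 += 1
            assert table.observed.loc[">=3", band] == ge3
            assert table.observed.loc["<3", band] == lt3

    def test_homogeneous_table_gives_zero_statistic(self):
        table = ContingencyTable(
            observed=pd.DataFrame([[15, 15], [15, 15]], index=[">=3", "<3"],
                                  columns=["male", "female"]),
            dose=1, stratifier="gender",
        )
        statistic, dof, p = chi_square(table)
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert dof == 1 and p == pytest.approx(1.0)

    def test_known_statistic(self):
        table = ContingencyTable(
            observed=pd.DataFrame([[10, 20], [20, 10]], index=[">=3", "<3"],
                                  columns=["a", "b"]),
            dose=1, stratifier="x",
        )
        statistic, _, _ = chi_square(table)
        assert statistic == pytest.approx(20 / 3, abs=5e-3)

    def test_zero_margin_rejected(self):
        table = ContingencyTable(
            observed=pd.DataFrame([[5, 0], [5, 0]], index=[">=3", "<3"], columns=["a", "b"]),
            dose=1, stratifier="x",
        )
        with pytest.raises(ValueError, match="margin"):
            chi_square(table)

    def test_statistic_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            observed = rng.integers(1, 60, size=(2, rng.integers(2, 4)))
            table = ContingencyTable(
                observed=pd.DataFrame(observed, index=[">=3", "<3"]),
                dose=1, stratifier="x",
            )
            statistic, dof, _ = chi_square(table)
            assert statistic == pytest.approx(chi_square_formula(observed), abs=1e-9)
            assert dof == observed.shape[1] - 1

    def test_expected_totals_match_observed_totals(self):
        dataset = random_dataset(random.Random(35), 150)
        table = dichotomize(dataset, 1, "gender")
        assert table.expected.to_numpy().sum() == pytest.approx(
            table.observed.to_numpy().sum()
        )


class TestAdrPrevalence:
    def test_universal_symptom_is_100_percent(self):
        dataset = AnalysisDataset(
            timelines=[
                make_timeline(f"u{i}", age=20 + i, doses=[("Comirnaty", "2021-03-10")],
                              adr_symptom_sets=[["fever"]])
                for i in range(5)
            ],
            discard_log=[],
        )
        frame = adr_prevalence(dataset, 1)
        fever = frame[frame["symptom"] == "fever"]
        assert (fever["pct"] == 100.0).all()

    def test_matches_per_stratum_means_and_omits_empty_strata(self):
        dataset = random_dataset(random.Random(36), 300)
        frame = adr_prevalence(dataset, 2)
        assert (frame["N"] > 0).all()  # empty strata absent, never zero rows
        for row in frame.head(40).itertuples():
            group = [
                tl for tl in dataset.timelines
                if tl.adr_for_dose(2) is not None
                and tl.history.gender == row.gender
                and age_band(tl.history.age) == row.age_band
            ]
            n_with = sum(
                1 for tl in group if row.symptom in tl.adr_for_dose(2).record.symptoms
            )
            assert row.N == len(group) and row.n == n_with

    def test_female_prevalence_exceeds_male_under_calibrated_model(self, calibrated_dataset):
        """The positive female log-odds offset must surface in estimates."""
        frame = adr_prevalence(calibrated_dataset, 1)
        common = ("injection site pain", "headache", "tiredness", "muscular pain")
        pooled = frame.groupby(["symptom", "gender"])[["n", "N"]].sum()
        for symptom in common:
            female = pooled.loc[(symptom, "female")]
            male = pooled.loc[(symptom, "male")]
            assert female["n"] / female["N"] > male["n"] / male["N"]


class TestFlowMatrix:
    def test_no_complete_responders_gives_empty_flows(self):
        dataset = AnalysisDataset(
            timelines=[make_timeline("a", doses=[("Comirnaty", "2021-03-10")],
                                     adr_symptom_sets=[["fever"]])],
            discard_log=[],
        )
        fm = flow_matrix(dataset)
        assert fm.flows == {} and fm.complete_responders == 0

    def test_single_complete_responder_unit_flows(self):
        dataset = AnalysisDataset(
            timelines=[
                make_timeline(
                    "a",
                    doses=[("Vaxzevria", "2021-03-10"), ("Vaxzevria", "2021-06-05"),
                           ("Comirnaty", "2021-12-10")],
                    adr_symptom_sets=[["fever"], ["fever", "headache"],
                                      ["fever", "headache", "nausea", "dizziness"]],
                )
            ],
            discard_log=[],
        )
        fm = flow_matrix(dataset)
        assert fm.flows == {(1, "1", "2"): 1, (2, "2", ">3"): 1}
        assert fm.complete_responders == 1

    def test_matches_pairwise_tally_and_conserves_flow(self):
        dataset = random_dataset(random.Random(37), 500)
        fm = flow_matrix(dataset)
        expected_flows, expected_complete = tally_flows(dataset)
        assert fm.flows == dict(expected_flows)
        assert fm.complete_responders == expected_complete
        assert fm.level_total(1) == fm.level_total(2) == expected_complete
        for dose in (1, 2, 3):
            assert sum(n for (d, c), n in fm.node_totals.items() if d == dose) == expected_complete
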