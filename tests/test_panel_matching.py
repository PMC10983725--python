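"""Reading, deduplication, matching, exclusion rules and descriptive tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from denomcast.months import index_to_month, month_to_index
from denomcast.panel import (
    ReadError,
    aggregate_duplicates,
    apply_exclusions,
    compute_totals,
    describe,
    match,
    read_ehr,
    read_occupancy,
)
from denomcast.simulate import write_study


def _occ_frame(rows):
    return pd.DataFrame(rows, columns=[
        "centre_id", "year_month", "report_id",
        "n_male_adult", "n_female_adult", "n_male_child", "n_female_child"])


def _ehr_frame(rows):
    df = pd.DataFrame(rows, columns=[
        "centre_id", "year_month", "type", "n_pat", "n_male", "n_female",
        "n_adult", "n_minor", "n_cases_digestive"])
    return df


class TestMonths:
    def test_epoch_and_round_trip(self):
        assert month_to_index("2017-11") == 0
        assert month_to_index("2018-01") == 2
        assert index_to_month(0) == "2017-11"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=-240, max_value=600))
    def test_round_trip_any_index(self, idx):
        assert month_to_index(index_to_month(idx)) == idx

    def test_unparseable_month_rejected(self):
        with pytest.raises(ValueError):
            month_to_index("2020/01")
        with pytest.raises(ValueError):
            month_to_index("2020-13")


class TestReaders:
    def test_round_trip_through_csv(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        ehr = read_ehr(paths["ehr"])
        occ = read_occupancy(paths["occupancy"])
        assert len(ehr) == len(small_study.ehr)
        assert len(occ) == len(small_study.occupancy)
        assert {"month_index", "pct_male_pat", "centre_type"} <= set(ehr.columns)

    def test_missing_column_and_negative_count(self, tmp_path):
        p = tmp_path / "bad.csv"
        _ehr_frame([["A", "2019-01", "REC", 10, 5, 5, 8, 2, 1]]).drop(
            columns="n_pat").to_csv(p, index=False)
        with pytest.raises(ReadError, match="n_pat"):
            read_ehr(p)
        _ehr_frame([["A", "2019-01", "REC", 10, -5, 5, 8, 2, 1]]).to_csv(p, index=False)
        with pytest.raises(ReadError, match="row"):
            read_ehr(p)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        _ehr_frame([]).to_csv(p, index=False)
        assert len(read_ehr(p)) == 0


class TestDuplicates:
    def test_mean_rounds_half_away_from_zero(self):
        occ = _occ_frame([
            ["A", "2019-01", 1, 10, 6, 2, 2],
            ["A", "2019-01", 2, 13, 7, 2, 2],
        ])
        out = aggregate_duplicates(occ)
        assert len(out) == 1
        assert out.loc[0, "n_male_adult"] == 12  # 11.5 -> 12
        assert out.loc[0, "n_female_adult"] == 7  # 6.5 -> 7
        assert out.loc[0, "n_occ"] == 12 + 7 + 2 + 2

    def test_single_report_unchanged_and_idempotent(self):
        occ = _occ_frame([["A", "2019-01", 1, 4, 4, 4, 4],
                          ["B", "2019-02", 1, 1, 2, 3, 4]])
        once = aggregate_duplicates(occ)
        twice = aggregate_duplicates(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))
        assert once.set_index("centre_id").loc["A", "n_male_adult"] == 4

    def test_triple_report_mean(self):
        occ = _occ_frame([["A", "2019-01", i, 4, 0, 0, 0] for i in (1, 2, 3)])
        assert aggregate_duplicates(occ).loc[0, "n_male_adult"] == 4


class TestTotals:
    def test_arithmetic(self):
        occ = _occ_frame([["A", "2019-01", 1, 100, 80, 30, 40]])
        out = compute_totals(occ)
        row = out.iloc[0]
        assert row["n_occ_adult"] == 180 and row["n_occ_child"] == 70
        assert row["n_occ"] == 250
        assert row["pct_adult_occ"] == pytest.approx(72.0)
        assert row["pct_male_occ"] == pytest.approx(52.0)

    def test_degenerate_zero_total_flagged(self):
        out = compute_totals(_occ_frame([["A", "2019-01", 1, 0, 0, 0, 0]]))
        assert out.loc[0, "n_occ"] == 0
        assert np.isnan(out.loc[0, "pct_male_occ"])
        assert bool(out.loc[0, "pct_occ_flag"])

    def test_single_male_adult(self):
        out = compute_totals(_occ_frame([["A", "2019-01", 1, 1, 0, 0, 0]]))
        assert out.loc[0, "n_occ"] == 1
        assert out.loc[0, "pct_male_occ"] == pytest.approx(100.0)

    def test_missing_stratum_rejected(self):
        with pytest.raises(ValueError, match="n_male_child"):
            compute_totals(_occ_frame([["A", "2019-01", 1, 1, 0, 0, 0]])
                           .drop(columns="n_male_child"))


class TestMatch:
    def _streams(self):
        ehr = _ehr_frame([
            ["A", "2019-01", "REC", 100, 60, 40, 80, 20, 9],
            ["A", "2019-02", "REC", 110, 66, 44, 88, 22, 11],
        ])
        ehr = ehr.rename(columns={"type": "centre_type",
                                  "n_cases_digestive": "n_cases"})
        ehr["month_index"] = ehr["year_month"].map(month_to_index)
        occ = compute_totals(_occ_frame([
            ["A", "2019-02", 1, 100, 60, 20, 20],
            ["A", "2019-03", 1, 90, 50, 30, 30],
        ]))
        return ehr, occ

    def test_join_semantics(self):
        ehr, occ = self._streams()
        split = match(ehr, occ)
        assert split.counts()["matched"] == 1
        assert split.matched.loc[0, "year_month"] == "2019-02"
        assert split.ehr_unmatched["year_month"].tolist() == ["2019-01"]
        assert split.occ_unmatched["year_month"].tolist() == ["2019-03"]
        assert split.matched.loc[0, "r"] == pytest.approx(110 / 200)

    def test_disjoint_months_match_nothing(self):
        ehr, occ = self._streams()
        occ = occ[occ["year_month"] == "2019-03"]
        split = match(ehr, occ.reset_index(drop=True))
        assert split.counts()["matched"] == 0
        assert split.counts()["ehr_unmatched"] == 2

    def test_split_partition_recovers_inputs(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        ehr = read_ehr(paths["ehr"])
        occ = aggregate_duplicates(read_occupancy(paths["occupancy"]))
        split = match(ehr, occ)
        c = split.counts()
        assert c["ehr_all"] == c["matched"] + c["ehr_unmatched"]
        assert c["occ_all"] == c["matched"] + c["occ_unmatched"]
        both = pd.concat([
            split.matched[["centre_id", "year_month"]],
            split.ehr_unmatched[["centre_id", "year_month"]]]).sort_values(
                ["centre_id", "year_month"]).reset_index(drop=True)
        orig = ehr[["centre_id", "year_month"]].sort_values(
            ["centre_id", "year_month"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(both, orig)

    def test_conflicting_centre_type_rejected(self):
        ehr, occ = self._streams()
        occ = occ.copy()
        occ["centre_type"] = "REG"
        with pytest.raises(ValueError, match="centre_type"):
            match(ehr, occ)

    def test_duplicate_occupancy_rejected(self):
        ehr, occ = self._streams()
        dup = pd.concat([occ, occ.head(1)], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            match(ehr, dup)


class TestExclusions:
    def _matched(self):
        return pd.DataFrame({
            "centre_id": ["A", "A", "B"],
            "year_month": ["2019-01", "2019-02", "2019-01"],
            "n_pat": [60, 50, 40],
            "n_occ": [40, 100, 90],
            "n_cases": [3, 0, 5],
        })

    def test_main_mode_drops_occ_below_pat(self):
        kept, log = apply_exclusions(self._matched(), mode="main")
        assert len(kept) == 2
        assert log == [("A:2019-01", "occ<pat")]

    def test_full_mode_keeps_everything(self):
        kept, log = apply_exclusions(self._matched(), mode="full")
        assert len(kept) == 3 and log == []

    def test_nonzero_mode_also_drops_zero_cases(self):
        kept, log = apply_exclusions(self._matched(), mode="nonzero")
        assert len(kept) == 1
        assert ("A:2019-02", "zero_cases") in log

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            apply_exclusions(self._matched(), mode="strict")

    def test_survivors_have_ratio_at_most_one(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        split = match(read_ehr(paths["ehr"]),
                      aggregate_duplicates(read_occupancy(paths["occupancy"])))
        kept, _ = apply_exclusions(split.matched, mode="main")
        r = kept["r"].dropna()
        assert ((r > 0) & (r <= 1)).all()


class TestDescribe:
    def test_closed_form_summary(self):
        tab = describe(pd.DataFrame({"n_pat": [1, 2, 3, 4]}))
        row = tab.set_index("variable").loc["n_pat"]
        assert row["mean"] == pytest.approx(2.5)
        assert row["sd"] == pytest.approx(1.2909944)
        assert row["median"] == pytest.approx(2.5)
        assert (row["q1"], row["q3"]) == (pytest.approx(1.75), pytest.approx(3.25))

    def test_constant_column_zero_sd(self):
        tab = describe(pd.DataFrame({"n_pat": [7, 7, 7]}))
        assert tab.set_index("variable").loc["n_pat", "sd"] == 0.0

    def test_empty_dataset_warns(self):
        with pytest.warns(UserWarning):
            tab = describe(pd.DataFrame())
        assert tab.empty

    def test_generator_moments_recovered(self):
        # enough centres that the clustered occupancy levels average out
        from denomcast.simulate import GeneratorConfig, generate_study

        panel = generate_study(GeneratorConfig(n_centres=150, seed=17)).truth.panel
        tab = describe(panel).set_index("variable")
        assert abs(tab.loc["n_occ", "mean"] - 348) / 348 < 0.10
        assert abs(tab.loc["n_pat", "mean"] - 230) / 230 < 0.10
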