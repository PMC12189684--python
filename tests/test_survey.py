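"""CPUE metrics, seasonal summaries, and the length-weight relationship."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from loligosdm import (
    aiw,
    cpue,
    env_range_summary,
    mantle_length_from_weight,
    read_survey_csv,
    seasonal_summary,
    weight_from_mantle_length,
    write_survey_csv,
)
from loligosdm.survey import LW_A, LW_B, station_metrics

from conftest import random_survey


class TestCpueAiw:
    @pytest.mark.parametrize(
        "weight,count,hours,expected",
        [
            (100.0, 4, 1.0, (100.0, 4.0)),
            (100.0, 4, 0.5, (200.0, 8.0)),
            (0.0, 0, 1.0, (0.0, 0.0)),
        ],
    )
    def test_cpue_examples(self, weight, count, hours, expected):
        assert cpue(weight, count, hours) == expected

    def test_cpue_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            cpue(10.0, 1, 0.0)

    @pytest.mark.parametrize(
        "cw,cn,expected",
        [
            (100.0, 4.0, 25.0),
            # single summer L. japonica station: CPUEw 52, CPUEn 2, AIW 26
            (52.0, 2.0, 26.0),
            # the autumn L. japonica station: 13.44 / 5 = 2.688 (prints 2.69)
            (13.44, 5.0, 2.688),
        ],
    )
    def test_aiw_examples(self, cw, cn, expected):
        assert aiw(cw, cn) == pytest.approx(expected)

    def test_aiw_undefined_at_zero_catch(self):
        assert np.isnan(aiw(0.0, 0.0))

    @given(
        w=st.floats(0.1, 5000),
        c=st.integers(1, 400),
        h=st.floats(0.25, 3),
    )
    def test_aiw_invariant_to_effort(self, w, c, h):
        cw, cn = cpue(w, c, h)
        assert aiw(cw, cn) == pytest.approx(w / c)


class TestSeasonalSummary:
    def test_grand_totals_sum_seasonal_totals(self):
        # one station per season carrying the published seasonal CPUE totals
        tbl = pd.DataFrame({
            "station_id": range(4),
            "lat": 30.0, "lon": 123.0,
            "season": ["spring", "summer", "autumn", "winter"],
            "tow_duration": 1.0,
            "count": [9, 52, 525, 14],
            "weight": [205.54, 3202.84, 9495.05, 590.2],
        })
        s = seasonal_summary(tbl)
        assert s.grand_total_cpue_w == pytest.approx(13493.63)
        assert s.grand_total_cpue_n == pytest.approx(600)

    def test_all_absence_season(self):
        tbl = pd.DataFrame({
            "station_id": range(4),
            "lat": 30.0, "lon": 123.0,
            "season": ["spring", "summer", "autumn", "winter"],
            "tow_duration": 1.0,
            "count": 0, "weight": 0.0,
        })
        s = seasonal_summary(tbl)
        assert s.grand_total_cpue_w == 0.0
        assert s.per_season["mean_cpue_w"].isna().all()
        assert (s.per_season["n_collection"] == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_totals_match_brute_force(self, seed):
        tbl = random_survey(seed)
        s = seasonal_summary(tbl)
        for season in s.per_season.index:
            expected_w = expected_n = 0.0
            for _, r in tbl.iterrows():
                if r["season"] == season:
                    expected_w += r["weight"] / r["tow_duration"]
                    expected_n += r["count"] / r["tow_duration"]
            assert s.per_season.loc[season, "total_cpue_w"] == pytest.approx(expected_w)
            assert s.per_season.loc[season, "total_cpue_n"] == pytest.approx(expected_n)

    def test_totals_invariant_to_record_order(self):
        tbl = random_survey(3)
        shuffled = tbl.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a, b = seasonal_summary(tbl), seasonal_summary(shuffled)
        assert a.grand_total_cpue_w == pytest.approx(b.grand_total_cpue_w)
        pd.testing.assert_frame_equal(a.per_season, b.per_season)

    def test_means_use_collection_stations_only(self):
        tbl = pd.DataFrame({
            "station_id": [0, 1, 2],
            "lat": 30.0, "lon": 123.0,
            "season": "autumn",
            "tow_duration": 1.0,
            "count": [0, 2, 4],
            "weight": [0.0, 50.0, 100.0],
        })
        s = seasonal_summary(tbl)
        assert s.per_season.loc["autumn", "mean_cpue_w"] == pytest.approx(75.0)
        assert s.per_season.loc["autumn", "n_collection"] == 2
        # ranges bracket means
        assert (s.per_season.loc["autumn", "min_cpue_w"]
                <= s.per_season.loc["autumn", "mean_cpue_w"]
                <= s.per_season.loc["autumn", "max_cpue_w"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            seasonal_summary(pd.DataFrame(columns=[
                "station_id", "lat", "lon", "season",
                "tow_duration", "count", "weight"]))


class TestEnvRanges:
    def test_singleton_presence_min_equals_max(self):
        tbl = random_survey(1, n=8)
        tbl["count"] = 0
        tbl.loc[0, "count"] = 3
        tbl.loc[0, "season"] = "summer"
        out = env_range_summary(tbl)
        assert out.loc["summer", "sbt_min"] == out.loc["summer", "sbt_max"]
        assert out.loc["summer", "sbt_min"] == tbl.loc[0, "sbt"]

    def test_absent_season_reported_missing(self):
        tbl = random_survey(2, n=12)
        tbl.loc[tbl["season"] == "spring", "count"] = 0
        out = env_range_summary(tbl)
        if "spring" in out.index:
            assert np.isnan(out.loc["spring", "depth_min"])

    @pytest.mark.parametrize("seed", range(5))
    def test_ranges_match_brute_force(self, seed):
        tbl = random_survey(seed, n=30)
        out = env_range_summary(tbl)
        for season in out.index:
            sub = [r for _, r in tbl.iterrows()
                   if r["season"] == season and r["count"] > 0]
            if not sub:
                continue
            lo = min(r["sbt"] for r in sub)
            hi = max(r["sbt"] for r in sub)
            assert out.loc[season, "sbt_min"] == pytest.approx(lo)
            assert out.loc[season, "sbt_max"] == pytest.approx(hi)


class TestLengthWeight:
    def test_round_trip_at_120mm(self):
        w = weight_from_mantle_length(120.0)
        assert mantle_length_from_weight(w) == pytest.approx(120.0, rel=1e-9)

    def test_unit_length_forces_weight_a(self):
        assert mantle_length_from_weight(LW_A) == pytest.approx(1.0)

    def test_direct_evaluation_at_60mm(self):
        w = LW_A * 60.0**LW_B  # independent direct evaluation
        assert mantle_length_from_weight(w) == pytest.approx(60.0, rel=1e-12)

    @pytest.mark.parametrize("func,bad", [
        (mantle_length_from_weight, 0.0),
        (mantle_length_from_weight, -5.0),
        (weight_from_mantle_length, 0.0),
    ])
    def test_nonpositive_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)


class TestIO:
    def test_survey_csv_round_trip(self, tmp_path):
        tbl = random_survey(4)
        path = tmp_path / "survey.csv"
        write_survey_csv(tbl, path)
        back = read_survey_csv(path)
        pd.testing.assert_frame_equal(back, tbl)

    def test_station_metrics_columns(self, survey_table):
        out = station_metrics(survey_table)
        assert {"cpue_w", "cpue_n", "aiw"} <= set(out.columns)
        caught = out[out["count"] > 0]
        np.testing.assert_allclose(caught["aiw"], caught["weight"] / caught["count"])
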