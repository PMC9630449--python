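"""Daily means, population weighting, hotspot rules and day classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firesmoke.exposure import (
    assign_station_to_districts,
    classify_days,
    daily_average,
    daily_hotspot_counts,
    filter_hotspots,
    fire_pm10,
    hotspot_threshold,
    population_weight,
)
from conftest import hourly_frame


class TestDailyAverage:
    @pytest.mark.parametrize(
        "values,expected_mean,expected_n",
        [
            ([50.0] * 24, 50.0, 24),  # complete constant day
            ([float(v) for v in range(1, 19)], 9.5, 18),  # exactly at the 75% rule
        ],
    )
    def test_mean_when_complete_enough(self, values, expected_mean, expected_n):
        out = daily_average(hourly_frame("S1", "North", "2015-01-01", values))
        assert len(out) == 1
        assert out["pm10_daily"].iloc[0] == pytest.approx(expected_mean)
        assert out["n_valid_hours"].iloc[0] == expected_n

    def test_17_valid_hours_is_missing(self):
        values = [10.0] * 17 + [np.nan] * 7
        out = daily_average(hourly_frame("S1", "North", "2015-01-01", values))
        assert np.isnan(out["pm10_daily"].iloc[0])
        assert out["n_valid_hours"].iloc[0] == 17


class TestPopulationWeight:
    def test_uniform_field_independent_of_population(self):
        pop = pd.DataFrame(
            {"district_id": ["D1", "D2"], "province": "N", "population": [10.0, 9000.0]}
        )
        assert population_weight({"D1": 80.0, "D2": 80.0}, pop) == pytest.approx(80.0)

    def test_hand_computed_weighting(self):
        pop = pd.DataFrame(
            {"district_id": ["D1", "D2"], "province": "N", "population": [3.0, 1.0]}
        )
        # (100*3 + 50*1)/4
        assert population_weight({"D1": 100.0, "D2": 50.0}, pop) == pytest.approx(87.5)

    def test_single_district_returns_own_value(self):
        pop = pd.DataFrame(
            {"district_id": ["D1"], "province": "N", "population": [123.0]}
        )
        assert population_weight({"D1": 42.0}, pop) == pytest.approx(42.0)

    def test_zero_total_population_is_error(self):
        pop = pd.DataFrame(
            {"district_id": ["D1"], "province": "N", "population": [0.0]}
        )
        with pytest.raises(ValueError):
            population_weight({"D1": 42.0}, pop)

    def test_missing_district_gives_missing_with_warning(self, caplog):
        pop = pd.DataFrame(
            {"district_id": ["D1", "D2"], "province": "N", "population": [1.0, 1.0]}
        )
        with caplog.at_level("WARNING"):
            out = population_weight({"D1": 42.0}, pop)
        assert np.isnan(out)
        assert "D2" in caplog.text

    @settings(deadline=None, max_examples=50)
    @given(
        conc=st.lists(st.floats(0, 500), min_size=1, max_size=6),
        pops=st.lists(st.floats(1, 1e6), min_size=6, max_size=6),
    )
    def test_weighted_mean_within_district_range(self, conc, pops):
        ids = [f"D{i}" for i in range(len(conc))]
        pop = pd.DataFrame(
            {"district_id": ids, "province": "N", "population": pops[: len(conc)]}
        )
        w = population_weight(dict(zip(ids, conc)), pop)
        assert min(conc) - 1e-9 <= w <= max(conc) + 1e-9

    @settings(deadline=None, max_examples=50)
    @given(conc=st.lists(st.floats(0, 500), min_size=1, max_size=6))
    def test_equal_populations_equal_unweighted_mean(self, conc):
        ids = [f"D{i}" for i in range(len(conc))]
        pop = pd.DataFrame(
            {"district_id": ids, "province": "N", "population": [7.0] * len(conc)}
        )
        w = population_weight(dict(zip(ids, conc)), pop)
        assert w == pytest.approx(np.mean(conc), abs=1e-9)


class TestStationAssignment:
    def stations(self, rows):
        return pd.DataFrame(rows, columns=["station_id", "province", "lat", "lon"])

    def districts(self, rows):
        return pd.DataFrame(rows, columns=["district_id", "province", "lat", "lon"])

    def test_single_station_takes_all_districts(self):
        s = self.stations([("S1", "N", 18.0, 98.0)])
        d = self.districts(
            [("D1", "N", 18.1, 98.0), ("D2", "N", 18.2, 98.3), ("D3", "N", 17.9, 97.9)]
        )
        assert assign_station_to_districts(s, d).tolist() == ["S1"] * 3

    def test_equidistant_tie_breaks_lexicographically(self):
        s = self.stations([("SB", "N", 18.0, 98.2), ("SA", "N", 18.0, 97.8)])
        d = self.districts([("D1", "N", 18.0, 98.0)])
        assert assign_station_to_districts(s, d).loc["D1"] == "SA"

    def test_two_stations_two_districts_nearest_map(self):
        s = self.stations([("S1", "N", 18.0, 98.0), ("S2", "N", 19.0, 99.0)])
        d = self.districts([("D1", "N", 18.1, 98.1), ("D2", "N", 18.9, 98.9)])
        got = assign_station_to_districts(s, d)
        # brute-force check against all pairwise great-circle distances
        from firesmoke.exposure import haversine_km

        for _, row in d.iterrows():
            dists = {
                sid: haversine_km(row["lat"], row["lon"], slat, slon)
                for sid, _, slat, slon in s.itertuples(index=False)
            }
            assert got.loc[row["district_id"]] == min(dists, key=dists.get)
        assert set(got) == {"S1", "S2"}

    def test_province_without_station_is_error(self):
        s = self.stations([("S1", "N", 18.0, 98.0)])
        d = self.districts([("D1", "M", 18.0, 98.0)])
        with pytest.raises(ValueError, match="no monitoring station"):
            assign_station_to_districts(s, d)


class TestHotspotFilterAndThreshold:
    def make(self, confidences):
        return pd.DataFrame(
            {
                "date": pd.Timestamp("2015-03-01"),
                "lat": 18.0,
                "lon": 98.0,
                "confidence": confidences,
            }
        )

    def test_strictly_below_cut_excluded(self):
        out = filter_hotspots(self.make([10.0, 20.0, 80.0]), 20.0)
        assert out["confidence"].tolist() == [20.0, 80.0]

    def test_high_confidence_identity(self):
        df = self.make([100.0, 100.0])
        assert len(filter_hotspots(df)) == 2

    def test_empty_input_empty_output(self):
        assert len(filter_hotspots(self.make([]))) == 0

    def test_nearest_rank_matches_brute_force_oracle(self):
        counts = pd.Series([0] * 100 + [20] * 11)
        # brute-force oracle: sort the multiset, take 1-based rank ceil(0.9*n)
        expected = sorted(counts)[int(np.ceil(0.9 * len(counts))) - 1]
        assert expected == 0
        assert hotspot_threshold(counts, 0.90) == expected

    def test_constant_series_threshold_never_exceeded(self):
        counts = pd.Series([7] * 50)
        assert hotspot_threshold(counts) == 7  # strict "exceeds" ⇒ no burning day

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError):
            hotspot_threshold(pd.Series([], dtype=int))

    @settings(deadline=None, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=200),
        pct=st.floats(0.05, 0.95),
    )
    def test_nearest_rank_property(self, counts, pct):
        got = hotspot_threshold(pd.Series(counts), pct)
        assert got == sorted(counts)[int(np.ceil(pct * len(counts))) - 1]

    def test_daily_counts_zero_filled(self):
        df = self.make([90.0, 90.0])
        counts = daily_hotspot_counts(
            df, pd.Timestamp("2015-02-27"), pd.Timestamp("2015-03-03")
        )
        assert counts.tolist() == [0, 0, 2, 0, 0]


class TestClassifyDays:
    def series(self, pm_values):
        dates = pd.date_range("2015-01-01", periods=len(pm_values), freq="D")
        return pd.DataFrame(
            {"province": "N", "date": dates, "pm10_weighted": pm_values}
        )

    def counts(self, values):
        idx = pd.date_range("2015-01-01", periods=len(values), freq="D")
        return pd.Series(values, index=idx)

    def test_joint_rule_examples(self):
        cal = classify_days(
            self.series([150.0, 90.0, 180.0, 120.0]),
            self.counts([12, 12, 0, 5]),
            threshold=10,
            cutoff=100.0,
        )
        assert cal["label"].tolist() == ["burning", "other", "background", "other"]

    def test_missing_pm10_candidate_is_other_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            cal = classify_days(
                self.series([np.nan]), self.counts([12]), threshold=10, cutoff=100.0
            )
        assert cal["label"].tolist() == ["other"]
        assert "missing PM10" in caplog.text

    def test_every_day_gets_exactly_one_label(self, result):
        cal = result.calendar
        assert cal["label"].isin(["burning", "background", "other"]).all()
        assert not cal.duplicated(subset=["province", "date"]).any()
        n_days = cal["date"].nunique()
        assert (cal.groupby("province").size() == n_days).all()


class TestFirePM10:
    def calendar(self, labels):
        dates = pd.date_range("2015-03-01", periods=len(labels), freq="D")
        return pd.DataFrame(
            {
                "province": "N",
                "date": dates,
                "label": labels,
                "regional_hotspot_count": 99,
            }
        )

    def series(self, values):
        dates = pd.date_range("2015-03-01", periods=len(values), freq="D")
        return pd.DataFrame({"province": "N", "date": dates, "pm10_weighted": values})

    def model(self, mean):
        from firesmoke.exposure import BackgroundModel

        return BackgroundModel(
            province="N",
            df_per_year=5,
            total_df=5,
            dow_effects=pd.Series(0.0, index=range(7)),
            spline_coefficients=np.zeros(5),
            background_mean=mean,
            aic=0.0,
            n_days_fit=100,
        )

    def test_subtraction_and_zero_cases(self):
        out = fire_pm10(
            self.series([150.0, 23.2]), self.model(23.2), self.calendar(["burning"] * 2)
        )
        assert out["fire_pm10"].tolist() == pytest.approx([126.8, 0.0])

    def test_negative_excess_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = fire_pm10(
                self.series([95.0]), self.model(100.0), self.calendar(["burning"])
            )
        assert out["fire_pm10"].tolist() == [0.0]
        assert "clamp" in caplog.text

    def test_missing_burning_day_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = fire_pm10(
                self.series([np.nan, 150.0]),
                self.model(20.0),
                self.calendar(["burning", "burning"]),
            )
        assert len(out) == 1
        assert "dropping" in caplog.text

    def test_defined_only_on_burning_days(self):
        out = fire_pm10(
            self.series([150.0, 200.0, 250.0]),
            self.model(20.0),
            self.calendar(["burning", "background", "other"]),
        )
        assert len(out) == 1
        assert (out["fire_pm10"] >= 0).all()
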