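import numpy as np
import pandas as pd
import pytest

from tomaqual import preprocess as pp

from oracles import quantile_scalar


def make_series(values, start="2024-03-01", freq="1h", variables=None, mask=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    variables = variables or [f"v{i}" for i in range(values.shape[1])]
    if mask is None:
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
    ts = pd.date_range(start, periods=len(values), freq=freq)
    return pp.SensorSeries(ts, values, variables, mask)


class TestBoxplotBounds:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 4, 6, 8, 100], (-2.0, 14.0)),
            ([5, 5, 5, 5], (5.0, 5.0)),
            ([1, 2, 3, 4], (-0.5, 5.5)),  # Q1=1.75, Q3=3.25, IQR=1.5
        ],
    )
    def test_hand_computed_fences(self, values, expected):
        assert pp.boxplot_bounds(values) == pytest.approx(expected)

    def test_planted_outlier_is_flagged(self):
        series = make_series([2, 4, 6, 8, 100])
        flagged, report = pp.flag_outliers(series)
        assert flagged.missing_mask[:, 0].tolist() == [False] * 4 + [True]
        assert report["v0"]["flagged"] == 1

    def test_too_few_finite_values(self):
        with pytest.raises(pp.DegenerateInputError):
            pp.boxplot_bounds([1.0, 2.0, np.nan, np.nan])

    def test_matches_brute_force_quantiles_on_random_inputs(self, rng):
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(4, 20))
            q1, q3 = quantile_scalar(vals, 0.25), quantile_scalar(vals, 0.75)
            iqr = q3 - q1
            lower, upper = pp.boxplot_bounds(vals)
            assert lower == pytest.approx(q1 - 1.5 * iqr, abs=1e-12)
            assert upper == pytest.approx(q3 + 1.5 * iqr, abs=1e-12)


class TestFillGaps:
    def test_linear_midpoint(self):
        series = make_series([10, np.nan, 20])
        filled, counts = pp.fill_gaps(series)
        assert filled.values[1, 0] == pytest.approx(15.0)
        assert counts == {"linear": 1, "historical": 0}
        assert not filled.missing_mask.any()

    def test_linear_segment_reproduces_endpoints_exactly(self):
        vals = np.array([3.0, np.nan, np.nan, np.nan, 11.0])
        filled, _ = pp.fill_gaps(make_series(vals))
        assert filled.values[:, 0] == pytest.approx([3, 5, 7, 9, 11])
        # observed points untouched
        assert filled.values[0, 0] == 3.0 and filled.values[4, 0] == 11.0

    def test_long_gap_copied_from_matching_prior_day(self):
        # two identical diurnal days, then a 6-point gap on day 3
        day = 10 + 5 * np.sin(np.arange(24) / 24 * 2 * np.pi)
        vals = np.concatenate([day, day, day])
        mask = np.zeros((72, 1), dtype=bool)
        mask[50:56] = True  # hours 2..7 of day 3
        series = make_series(vals, mask=mask)
        filled, counts = pp.fill_gaps(series)
        assert counts["historical"] == 6
        assert filled.values[50:56, 0] == pytest.approx(day[2:8])

    def test_no_missing_returns_identical_values(self):
        series = make_series(np.arange(30.0))
        filled, counts = pp.fill_gaps(series)
        np.testing.assert_array_equal(filled.values, series.values)
        assert counts == {"linear": 0, "historical": 0}

    def test_unfillable_leading_gap(self):
        series = make_series([np.nan] * 7 + [1.0] * 17)  # no prior day exists
        with pytest.raises(pp.UnfillableGapError):
            pp.fill_gaps(series)


class TestMinMaxScaling:
    def test_endpoints_and_midpoint(self):
        scaled, scaler = pp.minmax_fit_transform(np.array([[10.0], [20.0], [30.0]]))
        assert scaled[:, 0] == pytest.approx([0.0, 0.5, 1.0])
        assert scaler.data_min[0] == 10 and scaler.data_max[0] == 30

    def test_round_trip_identity(self, rng):
        values = rng.uniform(-5, 40, size=(50, 3))
        scaled, scaler = pp.minmax_fit_transform(values)
        np.testing.assert_allclose(pp.inverse_transform(scaled, scaler), values, atol=1e-9)

    def test_out_of_range_value_is_not_clipped(self):
        _, scaler = pp.minmax_fit_transform(np.array([[10.0], [30.0]]))
        scaled, _ = pp.minmax_fit_transform(np.array([[35.0]]), scaler)
        assert scaled[0, 0] == pytest.approx(1.25)

    def test_constant_variable_raises(self):
        with pytest.raises(pp.DegenerateScaleError):
            pp.minmax_fit_transform(np.ones((5, 1)))


class TestSplitByPlant:
    def _records(self, n_plants, records_per_plant=5):
        plants = np.repeat([f"p{i:03d}" for i in range(n_plants)], records_per_plant)
        base = pd.Timestamp("2024-03-01")
        times = [
            base + pd.Timedelta(days=int(i // records_per_plant), hours=int(i % records_per_plant))
            for i in range(len(plants))
        ]
        return plants, pd.DatetimeIndex(times)

    @pytest.mark.parametrize("n, expected", [(80, (56, 16, 8)), (10, (7, 2, 1))])
    def test_split_sizes(self, n, expected):
        plants, times = self._records(n)
        split = pp.split_by_plant(plants, times, seed=0)
        sizes = tuple(len(split.plants(s)) for s in ("train", "validation", "test"))
        assert sizes == expected

    def test_plant_disjoint_and_temporal_gap(self):
        plants, times = self._records(30)
        split = pp.split_by_plant(plants, times, seed=1)
        all_assigned = split.plants("train") + split.plants("validation") + split.plants("test")
        assert sorted(all_assigned) == sorted(set(all_assigned))  # exactly one split each
        test_plants = split.plants("test")
        test_times = times[np.isin(plants, test_plants)]
        keep = np.ones(len(plants), dtype=bool)
        keep[split.dropped_records] = False
        trainval_times = times[keep & ~np.isin(plants, test_plants)]
        assert trainval_times.max() < test_times.min()

    def test_same_seed_identical_assignment(self):
        plants, times = self._records(20)
        a = pp.split_by_plant(plants, times, seed=7)
        b = pp.split_by_plant(plants, times, seed=7)
        assert a.assignment == b.assignment

    def test_bad_ratios(self):
        plants, times = self._records(12)
        with pytest.raises(ValueError, match="sum to 1"):
            pp.split_by_plant(plants, times, ratios=(0.5, 0.2, 0.1))

    def test_too_few_plants(self):
        plants, times = self._records(5)
        with pytest.raises(ValueError, match="at least 10"):
            pp.split_by_plant(plants, times)


class TestWindowize:
    def test_sample_count_is_length_minus_T(self, rng):
        ds = pp.windowize(rng.random((30, 1)), T=24)
        assert ds.n_samples == 6

    def test_shape_and_alignment(self, rng):
        values = rng.random((120, 3))
        ds = pp.windowize(values, T=24, X=3)
        assert ds.X.shape == (96, 24, 3) and ds.y.shape == (96, 3)
        np.testing.assert_array_equal(ds.X[0], values[:24])
        np.testing.assert_array_equal(ds.y[0], values[24])  # window precedes target

    def test_too_short_series(self, rng):
        with pytest.raises(pp.EmptyDatasetError):
            pp.windowize(rng.random((24, 1)), T=24)


class TestCsvRoundTrip:
    def test_missing_cells_survive(self, tmp_path):
        vals = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, np.nan]])
        series = make_series(vals, variables=["temperature", "humidity"])
        path = tmp_path / "sensors.csv"
        pp.write_sensor_csv(series, path)
        back = pp.read_sensor_csv(path)
        assert back.variables == ["temperature", "humidity"]
        np.testing.assert_array_equal(back.missing_mask, series.missing_mask)
        observed = ~series.missing_mask
        np.testing.assert_allclose(back.values[observed], series.values[observed])


class TestSensorSeriesInvariants:
    def test_rejects_non_increasing_timestamps(self):
        ts = pd.DatetimeIndex(["2024-01-01 02:00", "2024-01-01 01:00"])
        with pytest.raises(ValueError, match="increasing"):
            pp.SensorSeries(ts, np.zeros((2, 1)), ["v"], np.zeros((2, 1), dtype=bool))

    def test_rejects_irregular_step(self):
        ts = pd.DatetimeIndex(["2024-01-01 00:00", "2024-01-01 01:00", "2024-01-01 03:00"])
        with pytest.raises(ValueError, match="constant step"):
            pp.SensorSeries(ts, np.zeros((3, 1)), ["v"], np.zeros((3, 1), dtype=bool))
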