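"""Feature engineering: window statistics, location features, entropy,
sleep index, soft-impute and the missing-data exclusion rule."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from wardsense import (FEATURE_REGISTRY, FeatureConfig, build_feature_series,
                       exclude_participants, impute_missing, location_entropy,
                       location_features, sleep_index_score, soft_impute,
                       total_acceleration, window_stats)
from wardsense.features import (LN4, DataValidationError, cumulative_features,
                                daily_sleep_index)

from conftest import constant_stream


class TestTotalAcceleration:
    @pytest.mark.parametrize("xyz,expected", [
        ((3.0, 4.0, 0.0), 5.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 1.0, 1.0), math.sqrt(3.0)),
    ])
    def test_known_values(self, xyz, expected):
        assert total_acceleration(*xyz) == pytest.approx(expected, abs=1e-12)

    def test_missing_component_propagates(self):
        out = total_acceleration([1.0, np.nan], [1.0, 2.0], [1.0, 2.0])
        assert not np.isnan(out[0]) and np.isnan(out[1])


class TestWindowStats:
    def test_hand_computed_window(self):
        out = window_stats([2.0, 5.0, 3.0])
        expected = [2.0, 3.0, 10.0 / 3.0, 3.0, 5.0, 2.0,
                    statistics.stdev([2.0, 5.0, 3.0]), 3.0]
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_constant_window(self):
        out = window_stats([7.0, 7.0])
        np.testing.assert_allclose(out, [7, 7, 7, 7, 7, 7, 0, 1])

    def test_empty_window_all_missing(self):
        assert np.isnan(window_stats([])).all()

    def test_brute_force_equivalence(self):
        # randomized small windows against naive recomputation
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            v = np.round(rng.normal(70, 10, n), 3)
            out = window_stats(v, nunique_resolution=1.0)
            naive = [v[0], v[-1], statistics.fmean(v), statistics.median(v),
                     max(v), min(v), statistics.stdev(v),
                     len(set(np.round(v / 1.0)))]
            np.testing.assert_allclose(out, naive, rtol=1e-9, atol=1e-9)


class TestSleepIndex:
    @pytest.mark.parametrize("hours,score", [
        (2.0, 30.0),     # at or below the 2.25 h floor
        (2.25, 30.0),
        (9.0, 100.0),    # at or above the 7.5 h ceiling
        (7.5, 100.0),
        (4.875, 65.0),   # midpoint of the linear segment
    ])
    def test_anchor_mapping(self, hours, score):
        assert sleep_index_score(hours) == pytest.approx(score)

    def test_monotone_and_clamped(self):
        d = np.linspace(0.0, 12.0, 241)
        s = sleep_index_score(d)
        assert (np.diff(s) >= -1e-12).all()
        assert s.min() == 30.0 and s.max() == 100.0

    def test_daily_score_from_flags(self):
        stream = constant_stream(n_hours=24)
        stream.data.loc[:6 * 60 - 1, "sleep_flag"] = 1.0  # 6 h flagged
        daily = daily_sleep_index(stream)
        assert daily.iloc[0] == pytest.approx(30 + 70 * (6 - 2.25) / 5.25)


class TestCumulative:
    def test_sum_within_window(self):
        stream = constant_stream(n_hours=2, steps=0.0)
        stream.data.loc[0, "steps"] = 10.0
        stream.data.loc[30, "steps"] = 0.0
        stream.data.loc[59, "steps"] = 25.0
        out = cumulative_features(stream, (stream.data["timestamp"].iloc[0],
                                           stream.data["timestamp"].iloc[60]))
        assert out["steps"] == pytest.approx(35.0)

    def test_adjacent_windows_are_additive(self):
        rng = np.random.default_rng(1)
        stream = constant_stream(n_hours=2)
        stream.data["steps"] = rng.integers(0, 30, len(stream.data)).astype(float)
        t0 = stream.data["timestamp"].iloc[0]
        h = pd.Timedelta(hours=1)
        a = cumulative_features(stream, (t0, t0 + h))["steps"]
        b = cumulative_features(stream, (t0 + h, t0 + 2 * h))["steps"]
        assert a + b == pytest.approx(stream.data["steps"].sum())

    def test_empty_window_contract(self):
        stream = constant_stream(n_hours=1)
        t = stream.data["timestamp"].iloc[0] + pd.Timedelta(days=2)
        out = cumulative_features(stream, (t, t + pd.Timedelta(hours=1)))
        assert out["steps"] == 0.0 and out["distance"] == 0.0
        assert np.isnan(out["sleep_index"])

    def test_negative_increment_rejected(self):
        stream = constant_stream(n_hours=1)
        stream.data.loc[5, "steps"] = -1.0
        with pytest.raises(DataValidationError):
            cumulative_features(stream, (stream.data["timestamp"].iloc[0],
                                         stream.data["timestamp"].iloc[59]))


class TestLocationFeatures:
    def test_single_point_zone(self):
        stream = constant_stream(n_hours=1, zone="room", loc=(3.0, 4.0))
        t0 = stream.data["timestamp"].iloc[0]
        out = location_features(stream, (t0, t0 + pd.Timedelta(hours=1)))
        assert out["location_variance"] == pytest.approx(0.0)
        assert out["place_room"] == 1.0
        assert out["place_hallway"] == 0.0 == out["place_other"]

    def test_half_and_half_zones(self):
        stream = constant_stream(n_hours=1)
        stream.data.loc[30:, "zone"] = "hallway"
        t0 = stream.data["timestamp"].iloc[0]
        out = location_features(stream, (t0, t0 + pd.Timedelta(hours=1)))
        assert out["place_room"] == pytest.approx(0.5)
        assert out["place_hallway"] == pytest.approx(0.5)

    def test_alternating_coordinates_sample_variance(self):
        stream = constant_stream(n_hours=1)
        stream.data.loc[:3, "loc_x"] = [0.0, 2.0, 0.0, 2.0]
        stream.data.loc[:3, "loc_y"] = 0.0
        t0 = stream.data["timestamp"].iloc[0]
        out = location_features(stream, (t0, t0 + pd.Timedelta(minutes=4)))
        assert out["location_variance"] == pytest.approx(4.0 / 3.0)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(2)
        zones = np.array(["room", "hallway", "other", "no_signal"])
        for _ in range(300):
            n = int(rng.integers(2, 20))
            stream = constant_stream(n_hours=1)
            stream.data = stream.data.iloc[:n].copy()
            stream.data["loc_x"] = rng.normal(0, 3, n)
            stream.data["loc_y"] = rng.normal(0, 3, n)
            stream.data["zone"] = zones[rng.integers(0, 4, n)]
            t0 = stream.data["timestamp"].iloc[0]
            out = location_features(stream, (t0, t0 + pd.Timedelta(hours=1)))
            naive_var = (statistics.variance(stream.data["loc_x"])
                         + statistics.variance(stream.data["loc_y"]))
            assert out["location_variance"] == pytest.approx(naive_var, rel=1e-9)
            for z in zones:
                frac = (stream.data["zone"] == z).mean()
                assert out[f"place_{z}"] == pytest.approx(frac, abs=1e-12)


class TestLocationEntropy:
    def test_uniform_occupancy_maximal(self):
        stream = constant_stream(n_hours=24)
        reps = len(stream.data) // 4
        stream.data["zone"] = (["room"] * reps + ["hallway"] * reps
                               + ["other"] * reps + ["no_signal"] * reps)
        ent = location_entropy(stream, "daily")
        assert ent["entropy"].iloc[0] == pytest.approx(LN4, rel=1e-12)
        assert ent["normalized_entropy"].iloc[0] == pytest.approx(1.0)

    def test_single_zone_zero(self):
        ent = location_entropy(constant_stream(n_hours=24), "daily")
        assert ent["entropy"].iloc[0] == 0.0

    def test_two_zone_half_split(self):
        stream = constant_stream(n_hours=8)
        half = len(stream.data) // 2
        stream.data.loc[half:, "zone"] = "hallway"
        ent = location_entropy(stream, "8hr")
        assert ent["entropy"].iloc[0] == pytest.approx(math.log(2), rel=1e-12)
        assert ent["normalized_entropy"].iloc[0] == pytest.approx(0.5)

    def test_bounds_and_brute_force(self):
        rng = np.random.default_rng(3)
        zones = np.array(["room", "hallway", "other", "no_signal"])
        for _ in range(200):
            n = int(rng.integers(1, 50))
            stream = constant_stream(n_hours=1)
            stream.data = stream.data.iloc[:n].copy()
            stream.data["zone"] = zones[rng.integers(0, 4, n)]
            ent = location_entropy(stream, "daily")
            h = ent["entropy"].iloc[0]
            counts = stream.data["zone"].value_counts()
            naive = -sum((c / n) * math.log(c / n) for c in counts)
            assert h == pytest.approx(naive, abs=1e-9)
            assert 0.0 <= h <= LN4 + 1e-12
            uniform = len(counts) == 4 and counts.nunique() == 1
            assert (abs(h - LN4) < 1e-12) == uniform

    def test_period_boundaries(self):
        stream = constant_stream(n_hours=30)
        ent8 = location_entropy(stream, "8hr")
        assert all(ts.hour in (0, 8, 16) for ts in ent8.index)


class TestSoftImpute:
    def test_complete_matrix_unchanged(self):
        X = np.random.default_rng(0).normal(size=(20, 6))
        np.testing.assert_array_equal(soft_impute(X), X)

    def test_rank1_recovery(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=(12, 1)), rng.normal(size=(1, 9))
        X = u @ v
        masked = X.copy()
        masked[4, 5] = np.nan
        out = soft_impute(masked, rank_max=1, lam=0.0, tol=1e-12,
                          max_iter=500, standardize=False)
        assert abs(out[4, 5] - X[4, 5]) < 1e-6

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 5))
        mask = rng.random((15, 5)) < 0.2
        Xm = X.copy()
        Xm[mask] = np.nan
        out = soft_impute(Xm)
        np.testing.assert_array_equal(out[~mask], X[~mask])
        assert not np.isnan(out).any()

    def test_fully_missing_column_names_column(self):
        X = np.ones((5, 3))
        X[:, 1] = np.nan
        with pytest.raises(DataValidationError, match="colB"):
            soft_impute(X, column_names=["colA", "colB", "colC"])

    def test_imputed_bounded_columns_clipped(self):
        df = pd.DataFrame(
            np.random.default_rng(3).normal(0.5, 0.2, size=(30, 29)),
            columns=list(FEATURE_REGISTRY))
        df.iloc[3, df.columns.get_loc("place_room")] = np.nan
        out = impute_missing(df, FeatureConfig())
        assert 0.0 <= out.iloc[3]["place_room"] <= 1.0


class TestExclusion:
    @pytest.mark.parametrize("frac,kept", [(0.51, False), (0.49, True),
                                           (0.0, True), (0.50, True)])
    def test_printed_threshold(self, frac, kept):
        retained, log = exclude_participants({"p": frac})
        assert ("p" in retained) is kept
        assert log["excluded"].iloc[0] is not kept or frac <= 0.5

    def test_bisection_locates_boundary(self):
        lo, hi = 0.0, 1.0 - 1e-9
        for _ in range(40):
            mid = (lo + hi) / 2
            retained, _ = exclude_participants({"p": mid})
            if retained:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(0.50, abs=1e-9)


class TestBuildFeatureSeries:
    def test_shape_and_completeness(self):
        fs = build_feature_series(constant_stream(n_hours=48))
        assert fs.features.shape == (48, 29)
        assert list(fs.features.columns) == list(FEATURE_REGISTRY)
        assert not fs.features.isna().any().any()
        assert fs.missing_fraction == 0.0

    def test_constant_stream_rows_identical(self):
        fs = build_feature_series(constant_stream(n_hours=48))
        rows = fs.features.to_numpy()
        assert np.allclose(rows[1:], rows[1], equal_nan=True)

    def test_too_short_stream_rejected(self):
        stream = constant_stream(n_hours=1)
        stream.data = stream.data.iloc[:30]
        with pytest.raises(DataValidationError):
            build_feature_series(stream)

    def test_simulated_streams_complete_after_imputation(self, tiny_features):
        series, log = tiny_features
        for fs in series.values():
            assert fs.features.shape[1] == 29
            assert not fs.features.isna().any().any()
            ent = fs.features["Location_Normalized_Entropy_Daily"]
            assert ent.between(0.0, 1.0).all()
            for z in ("room", "hallway", "other", "no_signal"):
                assert fs.features[f"place_{z}"].between(0.0, 1.0).all()
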