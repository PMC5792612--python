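"""Song feature derivation, aggregation, frontiers, and vocal deviation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ovensong as ov
from ovensong.acoustics import orthogonal_deviation

PRINTED_SLOPE, PRINTED_INTERCEPT = -79.374, 5066.2


def song_frame(rows):
    return pd.DataFrame(rows, columns=["species", "n_notes", "duration_s",
                                       "max_freq_hz", "min_freq_hz",
                                       "peak_freq_hz"])


def nearest_point_deviation(pace, bw, slope, intercept):
    """Oracle: numeric minimization of the distance to points on the line."""
    from scipy.optimize import minimize_scalar

    def dist(x):
        return math.hypot(x - pace, slope * x + intercept - bw)

    res = minimize_scalar(dist, bounds=(pace - 1e4, pace + 1e4),
                          method="bounded", options={"xatol": 1e-10})
    sign = 1.0 if bw < slope * pace + intercept else -1.0
    return sign * res.fun


class TestDeriveFeatures:
    def test_pace_and_bandwidth(self):
        clean, rejected = ov.derive_song_features(song_frame(
            [("sp1", 10, 2.0, 5000.0, 2000.0, 3000.0)]))
        assert rejected.empty
        assert clean["pace_hz"].iloc[0] == 5.0
        assert clean["bandwidth_hz"].iloc[0] == 3000.0

    def test_rejections_with_reasons(self):
        clean, rejected = ov.derive_song_features(song_frame([
            ("a", 10, 0.0, 5000, 2000, 3000),
            ("b", 10, 2.0, 1000, 2000, 1500),
            ("c", 10, 2.0, 5000, 2000, 3000),
        ]))
        assert len(clean) == 1 and clean["species"].iloc[0] == "c"
        assert list(rejected["reason"]) == [
            "nonpositive duration", "max frequency below min frequency"]

    def test_peak_outside_band_warns_not_rejects(self):
        with pytest.warns(UserWarning, match="peak frequency"):
            clean, rejected = ov.derive_song_features(song_frame(
                [("a", 5, 1.0, 4000, 2000, 6000)]))
        assert len(clean) == 1 and rejected.empty


class TestAggregate:
    def test_mean_then_log(self):
        clean, _ = ov.derive_song_features(song_frame([
            ("sp1", 8, 2.0, 5000, 2000, 3000),   # pace 4
            ("sp1", 12, 2.0, 5000, 2000, 3000),  # pace 6
        ]))
        tab = ov.species_aggregate(clean)
        assert tab.loc["sp1", "pace_hz"] == pytest.approx(5.0)
        assert tab.loc["sp1", "log_pace_hz"] == pytest.approx(math.log(5.0))
        assert tab.loc["sp1", "n_recordings"] == 2

    def test_single_record_species_is_identity(self):
        clean, _ = ov.derive_song_features(song_frame(
            [("solo", 6, 3.0, 4400, 1400, 2000)]))
        tab = ov.species_aggregate(clean)
        assert tab.loc["solo", "bandwidth_hz"] == pytest.approx(3000.0)
        assert tab.loc["solo", "log_bandwidth_hz"] == pytest.approx(
            math.log(3000.0))


class TestUpperBound:
    def test_recovers_printed_frontier_from_collinear_points(self):
        # songs placed exactly on the published line at paces 1, 3, ..., 39
        pace = np.arange(1.0, 40.0, 2.0)
        bw = PRINTED_SLOPE * pace + PRINTED_INTERCEPT
        fit = ov.upper_bound_regression(pace, bw)
        assert fit.slope_ == pytest.approx(PRINTED_SLOPE, abs=1e-6)
        assert fit.intercept_ == pytest.approx(PRINTED_INTERCEPT, abs=1e-6)
        assert fit.n_points_ == 20

    def test_two_bins_gives_perfect_fit(self):
        fit = ov.upper_bound_regression([1.0, 5.0], [4000.0, 3000.0])
        assert fit.n_points_ == 2
        assert fit.r_squared_ == pytest.approx(1.0)

    def test_insufficient_bins(self):
        with pytest.raises(ValueError, match="insufficient bins"):
            ov.upper_bound_regression([1.0, 1.5], [100.0, 200.0])

    def test_tie_breaks_smallest_pace_then_order(self):
        pace = np.array([1.8, 1.2, 1.5, 3.0])
        bw = np.array([3000.0, 3000.0, 2000.0, 1000.0])
        fit = ov.upper_bound_regression(pace, bw)
        assert fit.support_["pace_hz"].iloc[0] == pytest.approx(1.2)

    def test_shuffle_invariance(self, rng):
        pace = rng.uniform(0, 30, 400)
        bw = rng.uniform(0, 4000, 400)
        a = ov.upper_bound_regression(pace, bw)
        perm = rng.permutation(400)
        b = ov.upper_bound_regression(pace[perm], bw[perm])
        assert a.slope_ == pytest.approx(b.slope_)
        assert a.intercept_ == pytest.approx(b.intercept_)

    def test_recovers_generative_frontier_within_ten_percent(self):
        """Triangular clouds of 2000 songs bound by a known frontier."""
        rel_errs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            pace = rng.uniform(0.0, 40.0, 2000)
            cap = PRINTED_INTERCEPT + PRINTED_SLOPE * pace
            bw = rng.uniform(0.0, 1.0, 2000) * cap
            fit = ov.upper_bound_regression(pace, bw)
            rel_errs.append(abs(fit.slope_ - PRINTED_SLOPE)
                            / abs(PRINTED_SLOPE))
        assert np.median(rel_errs) < 0.10


class TestPercentileBound:
    def test_constant_bandwidth(self):
        rng = np.random.default_rng(0)
        pace = rng.uniform(0, 10, 2000)
        fit = ov.percentile_bound(pace, np.full(2000, 1234.0))
        assert fit.slope_ == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept_ == pytest.approx(1234.0)

    def test_sparse_window_excluded(self):
        # 40 songs at pace ~1, 40 at pace ~5, 31 at pace ~9 (excluded)
        pace = np.r_[np.full(40, 1.0), np.full(40, 5.0), np.full(31, 9.0)]
        bw = np.r_[np.full(40, 100.0), np.full(40, 200.0), np.full(31, 900.0)]
        fit = ov.percentile_bound(pace, bw)
        assert not (fit.support_["center_hz"] > 8).any()

    def test_min_count_filter_error(self):
        with pytest.raises(ValueError, match="insufficient windows"):
            ov.percentile_bound(np.full(10, 1.0), np.full(10, 5.0))

    def test_uniform_bandwidth_ninetieth_percentile(self):
        rng = np.random.default_rng(7)
        pace = rng.uniform(0, 10, 100_000)
        bw = rng.uniform(0, 1, 100_000)
        fit = ov.percentile_bound(pace, bw)
        assert abs(fit.slope_) < 0.01
        assert fit.intercept_ == pytest.approx(0.9, abs=0.02)
        assert fit.df_[0] == 1
        assert fit.df_[1] == fit.n_points_ - 2


class TestVocalDeviation:
    def test_zero_on_frontier(self):
        pace = np.array([0.0, 10.0, 35.0])
        bw = PRINTED_SLOPE * pace + PRINTED_INTERCEPT
        d = ov.vocal_deviation(pace, bw, (PRINTED_SLOPE, PRINTED_INTERCEPT))
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_printed_example_value(self):
        d = ov.vocal_deviation(10.0, 3000.0,
                               (PRINTED_SLOPE, PRINTED_INTERCEPT))
        oracle = nearest_point_deviation(10.0, 3000.0,
                                         PRINTED_SLOPE, PRINTED_INTERCEPT)
        assert d == pytest.approx(oracle, abs=1e-4)
        assert d == pytest.approx(16.03, abs=0.01)

    def test_sign_convention(self):
        above = ov.vocal_deviation(10.0, 5000.0,
                                   (PRINTED_SLOPE, PRINTED_INTERCEPT))
        below = ov.vocal_deviation(10.0, 1000.0,
                                   (PRINTED_SLOPE, PRINTED_INTERCEPT))
        assert above < 0 < below

    def test_matches_nearest_point_oracle(self, rng):
        slope, intercept = -3.7, 50.0
        for _ in range(200):
            p = rng.uniform(-20, 60)
            b = rng.uniform(-100, 300)
            got = orthogonal_deviation(p, b, slope, intercept)
            want = nearest_point_deviation(p, b, slope, intercept)
            assert got == pytest.approx(want, abs=1e-6)

    @given(p=st.floats(-50, 50), b=st.floats(-5000, 8000))
    @settings(max_examples=60, deadline=None)
    def test_deviation_scales_with_line_distance(self, p, b):
        d = orthogonal_deviation(p, b, PRINTED_SLOPE, PRINTED_INTERCEPT)
        resid = PRINTED_SLOPE * p - b + PRINTED_INTERCEPT
        assert math.copysign(1, d) == math.copysign(1, resid) or resid == 0

    def test_species_vocal_performance_is_mean_of_songs(self):
        songs = pd.DataFrame({
            "species": ["a", "a", "b"],
            "pace_hz": [10.0, 20.0, 5.0],
            "bandwidth_hz": [1000.0, 2000.0, 4000.0],
        })
        vp = ov.species_vocal_performance(
            songs, (PRINTED_SLOPE, PRINTED_INTERCEPT))
        per_song = ov.vocal_deviation(songs["pace_hz"], songs["bandwidth_hz"],
                                      (PRINTED_SLOPE, PRINTED_INTERCEPT))
        assert vp["a"] == pytest.approx(per_song[:2].mean())
        assert vp["b"] == pytest.approx(per_song[2])


class TestFrontierComparison:
    def test_binned_max_sits_above_percentile_bound(self):
        """The frontier estimate should exceed the within-cloud quantile."""
        diffs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            pace = rng.uniform(0, 30, 3000)
            cap = 4000.0 - 60.0 * pace
            bw = rng.uniform(0, 1, 3000) * cap
            ub = ov.upper_bound_regression(pace, bw)
            pb = ov.percentile_bound(pace, bw)
            diffs.append(ub.intercept_ - pb.intercept_)
        assert np.median(diffs) > 0
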