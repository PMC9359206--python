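import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfcvar.core_io import BoldVolumeSeries, RoiTimeSeries, SeedDefinition
from dfcvar.variability import (
    DegenerateWindowError,
    InsufficientDataError,
    WindowScheme,
    build_windows,
    mean_fc_matrix,
    min_window_length,
    roi_variability_matrix,
    seed_variability_map,
    temporal_variability,
    windowed_correlation,
)


def brute_force_variability(r):
    """Independent loop implementation of the I statistic."""
    total = 0.0
    for k in range(1, len(r)):
        total += (r[k] - r[k - 1]) ** 2
    return total / (len(r) - 1)


class TestMinWindowLength:
    @pytest.mark.parametrize(
        "fmin,tr,expected",
        [(0.01, 2.0, 50), (0.05, 2.0, 10), (0.01, 3.0, 34)],
    )
    def test_ceiling_of_one_period(self, fmin, tr, expected):
        assert min_window_length(fmin, tr) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            min_window_length(0.0, 2.0)
        with pytest.raises(ValueError):
            min_window_length(0.01, -1.0)


class TestBuildWindows:
    def test_250_points_50tr_step1_gives_201(self):
        assert len(build_windows(250, WindowScheme(50, 1))) == 201

    def test_exactly_one_window_at_boundary(self):
        windows = build_windows(50, WindowScheme(50, 1))
        assert len(windows) == 1
        assert list(windows[0]) == list(range(50))

    def test_step_five_starts(self):
        windows = build_windows(60, WindowScheme(50, 5))
        assert [w.start for w in windows] == [0, 5, 10]

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_windows(40, WindowScheme(50, 1))

    def test_window_count_law_matches_enumeration(self):
        # exhaustive check of floor((T - L)/step) + 1 against brute enumeration
        for T in range(2, 61):
            for L in range(2, T + 1):
                for step in range(1, 11):
                    count = 0
                    s = 0
                    while s + L <= T:
                        count += 1
                        s += step
                    assert len(build_windows(T, WindowScheme(L, step))) == count


class TestWindowedCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(120)
        ws = windowed_correlation(x, x, WindowScheme(30, 5))
        np.testing.assert_allclose(ws.r, 1.0, atol=1e-12)

    def test_negated_series_gives_minus_one(self, rng):
        x = rng.standard_normal(120)
        ws = windowed_correlation(x, -x, WindowScheme(30, 5))
        np.testing.assert_allclose(ws.r, -1.0, atol=1e-12)

    def test_matches_per_window_pearson(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        scheme = WindowScheme(4, 4)
        ws = windowed_correlation(x, y, scheme)
        expected = [
            np.corrcoef(x[s : s + 4], y[s : s + 4])[0, 1] for s in (0, 4)
        ]
        np.testing.assert_allclose(ws.r, expected, atol=1e-12)

    def test_degenerate_window_identified(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        y[10:20] = 4.0  # constant stretch covers window index 10 at length 10
        with pytest.raises(DegenerateWindowError):
            windowed_correlation(x, y, WindowScheme(10, 10))


class TestTemporalVariability:
    def test_constant_correlations_give_zero(self):
        assert temporal_variability(np.full(30, 0.6)) == 0.0

    def test_alternating_unit_correlations(self):
        assert temporal_variability(np.array([1.0, -1.0, 1.0])) == pytest.approx(4.0)

    def test_four_point_hand_example(self):
        r = np.array([0.2, 0.5, 0.1, 0.4])
        assert temporal_variability(r) == pytest.approx((0.09 + 0.16 + 0.09) / 3)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            r = rng.uniform(-1, 1, size=rng.integers(2, 40))
            assert temporal_variability(r) == pytest.approx(
                brute_force_variability(r), abs=1e-14
            )

    def test_single_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            temporal_variability(np.array([0.5]))

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_four(self, rs):
        assert 0.0 <= temporal_variability(np.array(rs)) <= 4.0

    def test_invariant_to_affine_rescaling_of_inputs(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        scheme = WindowScheme(25, 5)
        base = temporal_variability(windowed_correlation(x, y, scheme))
        scaled = temporal_variability(
            windowed_correlation(3.7 * x - 2.0, 0.4 * y + 11.0, scheme)
        )
        assert scaled == pytest.approx(base, abs=1e-12)


class TestRoiVariabilityMatrix:
    def _rois(self, rng, T=120, R=4):
        return RoiTimeSeries(
            values=rng.standard_normal((T, R)),
            labels=[f"r{i}" for i in range(R)],
            tr_seconds=2.0,
        )

    def test_identical_columns_give_zero(self, rng):
        x = rng.standard_normal(100)
        rois = RoiTimeSeries(
            values=np.column_stack([x, x]), labels=["a", "b"], tr_seconds=2.0
        )
        vm = roi_variability_matrix(rois, WindowScheme(25, 5))
        assert vm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_equals_looped_pairwise_oracle(self, rng):
        rois = self._rois(rng)
        scheme = WindowScheme(30, 3)
        vm = roi_variability_matrix(rois, scheme)
        for i in range(rois.n_regions):
            for j in range(i + 1, rois.n_regions):
                expected = temporal_variability(
                    windowed_correlation(
                        rois.values[:, i], rois.values[:, j], scheme
                    )
                )
                assert vm.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_column_permutation_equivariance(self, rng):
        rois = self._rois(rng)
        scheme = WindowScheme(30, 3)
        vm = roi_variability_matrix(rois, scheme)
        perm = [2, 0, 3, 1]
        permuted = RoiTimeSeries(
            values=rois.values[:, perm],
            labels=[rois.labels[i] for i in perm],
            tr_seconds=2.0,
        )
        vm_p = roi_variability_matrix(permuted, scheme)
        np.testing.assert_allclose(
            vm_p.values, vm.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_degenerate_pair_named(self, rng):
        values = rng.standard_normal((60, 3))
        values[:, 2] = 1.0
        rois = RoiTimeSeries(values=values, labels=["a", "b", "c"], tr_seconds=2.0)
        with pytest.raises(DegenerateWindowError, match="column 2"):
            roi_variability_matrix(rois, WindowScheme(20, 10))


class TestMeanFcMatrix:
    def test_identical_columns_give_unit_fc(self, rng):
        x = rng.standard_normal(100)
        rois = RoiTimeSeries(
            values=np.column_stack([x, x]), labels=["a", "b"], tr_seconds=2.0
        )
        fc = mean_fc_matrix(rois, WindowScheme(25, 5))
        assert fc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        rois = RoiTimeSeries(
            values=rng.standard_normal((4000, 2)), labels=["a", "b"], tr_seconds=2.0
        )
        fc = mean_fc_matrix(rois, WindowScheme(50, 10))
        assert abs(fc[0, 1]) < 0.05

    def test_static_correlation_recovered_in_windows(self, rng):
        rho = 0.6
        z = rng.standard_normal((2000, 2))
        x = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]])
        rois = RoiTimeSeries(values=x, labels=["a", "b"], tr_seconds=2.0)
        fc = mean_fc_matrix(rois, WindowScheme(50, 1))
        full_r = np.corrcoef(x.T)[0, 1]
        assert fc[0, 1] == pytest.approx(full_r, abs=0.05)


class TestSeedVariabilityMap:
    def _volume(self, rng, shape=(6, 6, 6), T=300):
        seed_series = rng.standard_normal(T)
        data = seed_series + 0.8 * rng.standard_normal((*shape, T))
        return BoldVolumeSeries(data=data, affine=np.eye(4), tr_seconds=2.0), seed_series

    def test_block_boundaries_do_not_change_result(self, rng):
        vol, _ = self._volume(rng)
        seed = SeedDefinition("s", (3, 3, 3))
        scheme = WindowScheme(50, 5)
        full = seed_variability_map(vol, seed, scheme, block_size=10**6)
        small = seed_variability_map(vol, seed, scheme, block_size=7)
        np.testing.assert_array_equal(full.data, small.data)

    def test_seed_neighborhood_set_to_zero(self, rng):
        vol, _ = self._volume(rng)
        seed = SeedDefinition("s", (3, 3, 3))
        vmap = seed_variability_map(vol, seed, WindowScheme(50, 5))
        assert vmap.data[3, 3, 3] == 0.0

    def test_exchangeable_voxels_give_similar_variability(self, rng):
        # every voxel = seed signal + same-sd independent noise, so the map
        # should be roughly uniform away from sampling noise
        vol, _ = self._volume(rng, T=900)
        seed = SeedDefinition("s", (3, 3, 3))
        vmap = seed_variability_map(vol, seed, WindowScheme(50, 2))
        vals = vmap.data[np.isfinite(vmap.data)]
        vals = vals[vals > 0]  # drop the zeroed seed neighborhood
        assert np.all(vals > 0)
        assert vals.std() / vals.mean() < 0.35
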