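import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetherlab.behavior import (
    ArenaSpec,
    MOBILITY_PRESETS,
    MobilityParams,
    OccupancyGrid,
    activity_level,
    band_power,
    behavior_report,
    bootstrap_entropy,
    compute_speed,
    heading_histogram,
    occupancy_histogram,
    shannon_entropy_bits,
    synthetic_trajectory,
)
from tetherlab.errors import DomainError, InsufficientDataError


def make_traj(x, y, z=None, rate=100.0, yaw=None, pitch=None):
    n = len(x)
    return pd.DataFrame(
        {
            "time_s": np.arange(n) / rate,
            "x_m": np.asarray(x, dtype=float),
            "y_m": np.asarray(y, dtype=float),
            "z_m": np.zeros(n) if z is None else np.asarray(z, dtype=float),
            "yaw_deg": np.zeros(n) if yaw is None else np.asarray(yaw, dtype=float),
            "pitch_deg": np.zeros(n) if pitch is None else np.asarray(pitch, dtype=float),
        }
    )


class TestComputeSpeed:
    def test_stationary_all_zero(self):
        traj = make_traj(np.ones(100), np.ones(100))
        assert np.allclose(compute_speed(traj), 0.0)

    def test_straight_line_constant_speed(self):
        # 1 m over 10 s -> 0.1 m/s in the interior
        n = 1000
        traj = make_traj(np.linspace(0, 1, n), np.zeros(n), rate=100.0)
        speed = compute_speed(traj)
        interior = speed[50:-50]
        assert np.allclose(interior, 1.0 / 9.99, rtol=1e-3)

    def test_circular_path_closed_form(self):
        # |v| = 2 pi r / T
        r, T, rate = 0.3, 10.0, 100.0
        t = np.arange(0, 2 * T, 1 / rate)
        traj = make_traj(r * np.cos(2 * np.pi * t / T), r * np.sin(2 * np.pi * t / T))
        speed = compute_speed(traj)
        assert np.allclose(speed[100:-100], 2 * np.pi * r / T, rtol=1e-3)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            compute_speed(make_traj([0.0, 1.0], [0.0, 0.0]))


class TestOccupancyHistogram:
    def test_single_tile_one_bin(self):
        n = 500
        x = 0.1 + 0.001 * np.sin(np.arange(n))  # jiggle inside one bin
        traj = make_traj(x, np.full(n, -0.2))
        grid = occupancy_histogram(
            traj, extent=((-0.8, 0.8), (-0.8, 0.8)),
            stationary_speed_threshold=0.0, exclude_home=False,
        )
        assert np.count_nonzero(grid.counts) == 1
        assert grid.counts.sum() == n

    def test_home_exclusion_removes_argmax_bin(self, rng):
        n = 2000
        x = rng.uniform(-0.7, 0.7, n)
        y = rng.uniform(-0.7, 0.7, n)
        x[:1200] = 0.05  # heavy home bin
        y[:1200] = 0.05
        traj = make_traj(x, y)
        grid = occupancy_histogram(
            traj, extent=((-0.8, 0.8), (-0.8, 0.8)),
            stationary_speed_threshold=0.0, exclude_home=True,
        )
        argmax = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
        assert grid.excluded_bins == {tuple(int(v) for v in argmax)}
        assert not grid.included_mask[argmax]

    def test_stationary_filter_applied_before_binning(self):
        n = 1000
        x = np.concatenate([np.zeros(500), np.linspace(0.0, 0.7, 500)])
        traj = make_traj(x, np.zeros(n))
        grid = occupancy_histogram(
            traj, extent=((-0.8, 0.8), (-0.8, 0.8)),
            stationary_speed_threshold=0.02, exclude_home=False,
        )
        # the parked samples at the origin are excluded
        assert grid.counts.sum() < n - 400

    def test_all_stationary_sets_empty_flag(self):
        traj = make_traj(np.zeros(200), np.zeros(200))
        grid = occupancy_histogram(traj, extent=((-1, 1), (-1, 1)))
        assert grid.empty
        assert grid.counts.sum() == 0

    def test_uniform_sweep_chi_square_sane(self, rng):
        # Multinomial oracle: uniform scatter should not reject uniformity.
        n = 40_000
        traj = make_traj(rng.uniform(-0.8, 0.8, n), rng.uniform(-0.8, 0.8, n))
        grid = occupancy_histogram(
            traj, extent=((-0.8, 0.8), (-0.8, 0.8)),
            stationary_speed_threshold=0.0, exclude_home=False,
        )
        _, p = stats.chisquare(grid.counts.ravel())
        assert p > 1e-3


class TestHeadingHistogram:
    def test_constant_pose_single_bin(self):
        traj = make_traj(np.zeros(300), np.zeros(300),
                         yaw=np.full(300, 123.0), pitch=np.full(300, -10.0))
        grid = heading_histogram(traj)
        assert np.count_nonzero(grid.counts) == 1

    def test_yaw_ends_not_merged(self):
        traj = make_traj(np.zeros(2), np.zeros(2),
                         yaw=[359.9, 0.1], pitch=[0.0, 0.0], rate=1.0)
        # pad to 3 samples for uniformity check
        traj = make_traj(np.zeros(4), np.zeros(4),
                         yaw=[359.9, 0.1, 359.9, 0.1], pitch=np.zeros(4))
        grid = heading_histogram(traj)
        nz = np.nonzero(grid.counts)
        yaw_bins = sorted(set(nz[0].tolist()))
        assert yaw_bins == [0, 39]  # distinct end bins, no circular merge

    def test_pitch_clipped_into_end_bins(self):
        traj = make_traj(np.zeros(4), np.zeros(4),
                         yaw=np.zeros(4), pitch=[80.0, -80.0, 0.0, 0.0])
        grid = heading_histogram(traj)
        assert grid.n_clipped == 2
        assert grid.counts[0, 39] == 1  # +80 clipped to the top pitch bin
        assert grid.counts[0, 0] == 1

    def test_uniform_yaw_sweep_uniform_row(self):
        n, bins = 4000, 40
        yaw = (np.arange(n) * 360.0 / n) % 360.0
        traj = make_traj(np.zeros(n), np.zeros(n), yaw=yaw, pitch=np.full(n, 10.0))
        grid = heading_histogram(traj)
        pitch_bin = np.digitize(10.0, grid.y_edges) - 1
        row = grid.counts[:, pitch_bin]
        assert np.all(row == n // bins)
        assert grid.counts.sum() == n


class TestShannonEntropy:
    def grid_from(self, counts, excluded=()):
        return OccupancyGrid(
            counts=np.asarray(counts), x_edges=np.array([]), y_edges=np.array([]),
            excluded_bins=set(excluded),
        )

    def test_single_bin_zero_bits(self):
        g = self.grid_from(np.array([[100, 0], [0, 0]]))
        assert shannon_entropy_bits(g) == 0.0

    def test_uniform_400_bins(self):
        g = self.grid_from(np.full((20, 20), 7))
        assert shannon_entropy_bits(g) == pytest.approx(math.log2(400))
        assert shannon_entropy_bits(g, normalized=True) == pytest.approx(1.0)

    def test_quarter_three_quarter_split(self):
        # direct evaluation: -(1/4 log2 1/4 + 3/4 log2 3/4) = 2 - 0.75 log2 3
        g = self.grid_from(np.array([[25, 75]]))
        expected = 2.0 - 0.75 * math.log2(3.0)
        assert shannon_entropy_bits(g) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8112781244591328)

    def test_excluded_bins_carry_no_mass(self):
        g = self.grid_from(np.array([[50, 50], [900, 0]]), excluded={(1, 0)})
        # after exclusion: two equal bins over 3 included bins
        assert shannon_entropy_bits(g) == pytest.approx(1.0)
        assert shannon_entropy_bits(g, normalized=True) == pytest.approx(
            1.0 / math.log2(3)
        )

    def test_zero_total_undefined(self):
        g = self.grid_from(np.zeros((2, 2), dtype=int))
        with pytest.raises(DomainError):
            shannon_entropy_bits(g)

    def test_entropy_bounds_property(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=(5, 5))
            if counts.sum() == 0:
                continue
            g = self.grid_from(counts)
            h = shannon_entropy_bits(g)
            assert 0.0 <= h <= math.log2(25) + 1e-12
            assert 0.0 <= shannon_entropy_bits(g, normalized=True) <= 1.0 + 1e-12


class TestBootstrapEntropy:
    def test_degenerate_single_bin_ci_is_zero(self):
        n = 3000  # 30 s at 100 Hz, 10 bins of 3 s
        traj = make_traj(np.full(n, 0.1), np.full(n, 0.1))
        res = bootstrap_entropy(
            traj, time_bin_s=3.0, n_boot=50, seed=0,
            extent=((-1, 1), (-1, 1)), stationary_speed_threshold=0.0,
            exclude_home=False,
        )
        assert res.median == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_ci_contains_median(self, rng):
        n = 6000
        traj = make_traj(rng.uniform(-0.5, 0.5, n), rng.uniform(-0.5, 0.5, n))
        res = bootstrap_entropy(
            traj, time_bin_s=5.0, n_boot=100, seed=1,
            extent=((-1, 1), (-1, 1)), stationary_speed_threshold=0.0,
        )
        assert res.ci_low <= res.median <= res.ci_high

    def test_reproducible_from_seed(self, rng):
        n = 6000
        traj = make_traj(rng.uniform(-0.5, 0.5, n), rng.uniform(-0.5, 0.5, n))
        kw = dict(time_bin_s=5.0, n_boot=60, seed=42, extent=((-1, 1), (-1, 1)))
        a = bootstrap_entropy(traj, **kw)
        b = bootstrap_entropy(traj, **kw)
        assert np.array_equal(a.replicates, b.replicates)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_insufficient_time_bins(self):
        traj = make_traj(np.zeros(100), np.zeros(100))  # 1 s at 100 Hz
        with pytest.raises(InsufficientDataError):
            bootstrap_entropy(traj, time_bin_s=60.0, n_boot=10)


class TestBandPower:
    def test_pure_tone_concentrates_in_band(self):
        fs = 500.0
        t = np.arange(0, 60, 1 / fs)
        sig = np.sin(2 * np.pi * 8.0 * t)
        _, power = band_power(sig, fs, window_s=10.0)
        low = power[(6.0, 10.0)].mean()
        high = power[(30.0, 50.0)].mean()
        assert low / high > 100

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        fs = 500.0
        sig = rng.normal(0, 1, int(600 * fs))
        _, power = band_power(sig, fs, window_s=30.0)
        ratio = power[(30.0, 50.0)].mean() / power[(6.0, 10.0)].mean()
        assert ratio == pytest.approx(20.0 / 4.0, rel=0.15)

    def test_zero_signal_zero_power(self):
        _, power = band_power(np.zeros(10_000), 500.0, window_s=2.0)
        for series in power.values():
            assert np.allclose(series, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(DomainError):
            band_power(np.zeros(5000), 60.0, bands=[(30.0, 50.0)], window_s=1.0)

    def test_signal_shorter_than_window(self):
        with pytest.raises(InsufficientDataError):
            band_power(np.zeros(10), 500.0, window_s=1.0)


class TestActivityLevel:
    def test_constant_gravity_constant_norm(self):
        acc = np.tile([0.0, 0.0, 9.81], (500, 1))
        _, activity = activity_level(acc, 100.0)
        assert np.allclose(activity, 9.81)

    def test_alternating_axis_mean_norm(self):
        a = 2.5
        acc = np.zeros((400, 3))
        acc[::2, 0] = a
        acc[1::2, 0] = -a
        _, activity = activity_level(acc, 100.0)
        assert np.allclose(activity, a)

    def test_rest_active_boundaries(self):
        fs = 100.0
        acc = np.zeros((int(30 * fs), 3))
        acc[int(10 * fs):int(20 * fs), 1] = 5.0  # active block 10-20 s
        times, activity = activity_level(acc, fs)
        active = activity > 2.5
        on = times[np.flatnonzero(np.diff(active.astype(int)) == 1)[0] + 1]
        off = times[np.flatnonzero(np.diff(active.astype(int)) == -1)[0] + 1]
        assert abs(on - 10.0) <= 1.0  # within one smoothing window
        assert abs(off - 20.0) <= 1.0


class TestSyntheticTrajectory:
    def test_zero_speed_stationary_at_home(self, arena):
        params = MobilityParams(median_speed_m_s=0.0, max_speed_m_s=0.0,
                                home_dwell_fraction=0.5)
        traj = synthetic_trajectory(arena, params, 10.0, seed=0)
        assert np.allclose(traj.x_m, arena.home_xy[0])
        assert np.allclose(traj.y_m, arena.home_xy[1])

    def test_positions_never_leave_hexagon(self, arena):
        for preset in ("free", "restricted"):
            traj = synthetic_trajectory(arena, preset, 120.0, seed=3)
            assert all(arena.contains(x, y) for x, y in zip(traj.x_m, traj.y_m))

    def test_deterministic_given_seed(self, arena):
        a = synthetic_trajectory(arena, "free", 30.0, seed=9)
        b = synthetic_trajectory(arena, "free", 30.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_100hz_grid_and_ranges(self, arena):
        traj = synthetic_trajectory(arena, "free", 20.0, seed=1)
        assert np.allclose(np.diff(traj.time_s), 0.01)
        assert traj.yaw_deg.between(0, 360, inclusive="left").all()
        assert traj.pitch_deg.between(-45, 45).all()

    def test_presets_differ_about_twofold_in_median_speed(self, arena):
        meds = {}
        for preset in ("free", "restricted"):
            traj = synthetic_trajectory(arena, preset, 300.0, seed=5)
            speed = compute_speed(traj)
            meds[preset] = np.median(speed[speed >= 0.02])
        assert 1.4 < meds["free"] / meds["restricted"] < 3.0

    def test_free_has_higher_occupancy_entropy(self, arena):
        for seed in range(3):
            hs = {}
            for preset in ("free", "restricted"):
                traj = synthetic_trajectory(arena, preset, 300.0, seed=seed)
                grid = occupancy_histogram(traj, extent=arena.extent)
                hs[preset] = shannon_entropy_bits(grid)
            assert hs["free"] > hs["restricted"]


class TestBehaviorReport:
    def test_report_keys_and_consistency(self, arena):
        traj = synthetic_trajectory(arena, "free", 180.0, seed=2)
        report = behavior_report(traj, arena_extent=arena.extent,
                                 time_bin_s=30.0, n_boot=50, seed=2)
        for key in (
            "median_speed", "max_speed", "occupancy_entropy_bits",
            "occupancy_entropy_normalized", "heading_entropy_normalized",
            "ci_low", "ci_high", "n_boot", "seed",
        ):
            assert key in report
        assert 0.0 <= report["occupancy_entropy_normalized"] <= 1.0
        assert report["ci_low"] <= report["ci_high"]
        assert report["max_speed"] >= report["median_speed"]
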