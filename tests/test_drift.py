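import numpy as np
import pytest
from scipy.optimize import minimize

from msdrift.drift import (
    DriftTrajectory,
    PairwiseShiftMatrix,
    apply_drift_correction,
    bin_frames,
    bin_frames_overlapping,
    estimate_drift,
    fit_trajectory,
    interpolate_drift,
    pairwise_shifts,
)
from msdrift.localization_io import LocalizationTable
from msdrift.meanshift import MSParams, ShiftEstimate


def _matrix(K, entries):
    """Build a PairwiseShiftMatrix from {(i, j): (shift, err)} scalars/1-vectors."""
    out = {}
    for (i, j), (shift, err) in entries.items():
        shift = np.atleast_1d(np.asarray(shift, float))
        err = np.full_like(shift, err)
        out[(i, j)] = ShiftEstimate(shift, err, 100, 3, True, True)
    return PairwiseShiftMatrix(K, len(next(iter(out.values())).shift), out)


class TestBinFrames:
    def test_exact_division(self):
        b = bin_frames(100, 25)
        assert b.K == 4
        np.testing.assert_array_equal(b.edges, [[1, 26], [26, 51], [51, 76], [76, 101]])

    def test_remainder_folds_into_last_bin(self):
        b = bin_frames(105, 25)
        assert b.K == 4
        np.testing.assert_array_equal(b.edges[-1], [76, 106])

    def test_fewer_than_two_bins_raises(self):
        with pytest.raises(ValueError):
            bin_frames(30, 20)

    def test_membership_partitions_all_frames(self):
        b = bin_frames(103, 10)
        frames = np.arange(1, 104)
        masks = b.membership(frames)
        counts = np.sum(masks, axis=0)
        assert np.all(counts == 1)  # every frame in exactly one bin

    def test_overlapping_bins_stride_half(self):
        b = bin_frames_overlapping(100, 20)
        assert b.overlapping
        np.testing.assert_array_equal(b.edges[0], [1, 21])
        np.testing.assert_array_equal(b.edges[1], [11, 31])


class TestFitTrajectory:
    def test_consistent_system_recovered_exactly(self, rng):
        K = 6
        d_true = np.cumsum(rng.uniform(-20, 20, (K, 2)), axis=0)
        d_true -= d_true[0]
        entries = {}
        for i in range(K):
            for j in range(i + 1, K):
                entries[(i, j)] = (d_true[j] - d_true[i], rng.uniform(0.5, 3.0))
        traj = fit_trajectory(_matrix(K, entries), bin_frames(60, 10))
        np.testing.assert_allclose(traj.d, d_true, atol=1e-9)

    def test_redundant_paths_average_matches_brute_force(self):
        # K=3, one axis: Delta_12=10, Delta_23=10, Delta_13=26, equal weights.
        # Independent oracle: numerically minimize the weighted SSE.
        entries = {(0, 1): (10.0, 1.0), (1, 2): (10.0, 1.0), (0, 2): (26.0, 1.0)}

        def sse(d):
            d = np.concatenate([[0.0], d])
            return (10 - (d[1] - d[0])) ** 2 + (10 - (d[2] - d[1])) ** 2 + (26 - (d[2] - d[0])) ** 2

        oracle = minimize(sse, x0=[5.0, 15.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).x
        traj = fit_trajectory(_matrix(3, entries), bin_frames(30, 10))
        np.testing.assert_allclose(traj.d[:, 0], [0.0, *oracle], atol=1e-6)
        np.testing.assert_allclose(traj.d[:, 0], [0.0, 12.0, 24.0], atol=1e-8)

    def test_gauge_anchor_first_control_point_zero(self, rng):
        entries = {(i, j): (rng.normal(), 1.0) for i in range(4) for j in range(i + 1, 4)}
        traj = fit_trajectory(_matrix(4, entries), bin_frames(40, 10))
        np.testing.assert_array_equal(traj.d[0], [0.0])
        np.testing.assert_array_equal(traj.ci68[0], [0.0])

    def test_ci_coverage_calibrated_on_heteroscedastic_noise(self):
        """68% CIs from the weighted normal matrix cover at ~68% when the
        per-pair errors are genuinely independent with known scale."""
        K = 5
        rng = np.random.default_rng(2024)
        d_true = np.array([0.0, 5.0, -3.0, 8.0, 2.0])[:, None]
        hits = total = 0
        for _ in range(400):
            entries = {}
            for i in range(K):
                for j in range(i + 1, K):
                    eps = rng.uniform(0.5, 4.0)
                    entries[(i, j)] = (d_true[j, 0] - d_true[i, 0] + rng.normal(scale=eps), eps)
            traj = fit_trajectory(_matrix(K, entries), bin_frames(50, 10))
            err = np.abs(traj.d[1:, 0] - d_true[1:, 0])
            hits += int(np.sum(err <= traj.ci68[1:, 0]))
            total += K - 1
        assert abs(hits / total - 0.68) < 0.05

    def test_disconnected_graph_raises(self):
        entries = {(0, 1): (1.0, 1.0), (2, 3): (1.0, 1.0)}
        with pytest.raises(ValueError, match="disconnected"):
            fit_trajectory(_matrix(4, entries), bin_frames(40, 10))

    def test_exclude_adjacent_drops_consecutive_pairs(self):
        entries = {
            (0, 1): (999.0, 1.0),  # poisoned adjacent estimates
            (1, 2): (999.0, 1.0),
            (2, 3): (999.0, 1.0),
            (0, 2): (20.0, 1.0),
            (1, 3): (20.0, 1.0),
            (0, 3): (30.0, 1.0),
        }
        traj = fit_trajectory(_matrix(4, entries), bin_frames(40, 10), exclude_adjacent=True)
        np.testing.assert_allclose(traj.d[:, 0], [0.0, 10.0, 20.0, 30.0], atol=1e-9)

    def test_invalid_entries_excluded(self):
        entries = {(0, 1): (10.0, 1.0), (1, 2): (10.0, 1.0), (0, 2): (20.0, 1.0)}
        m = _matrix(3, entries)
        bad = ShiftEstimate(np.array([1e6]), np.array([1.0]), 2, 50, False, False)
        m.entries[(0, 2)] = bad
        traj = fit_trajectory(m, bin_frames(30, 10))
        np.testing.assert_allclose(traj.d[:, 0], [0.0, 10.0, 20.0], atol=1e-9)


class TestInterpolateApply:
    def _traj(self):
        return DriftTrajectory(
            times=np.array([10.0, 20.0, 30.0]),
            d=np.array([[0.0, 0.0], [10.0, -4.0], [6.0, 2.0]]),
            ci68=np.zeros((3, 2)),
        )

    def test_control_points_exact(self):
        np.testing.assert_allclose(interpolate_drift(self._traj(), 20), [10.0, -4.0])

    def test_midpoint_linear(self):
        np.testing.assert_allclose(interpolate_drift(self._traj(), 15), [5.0, -2.0])

    def test_clamped_extrapolation(self):
        np.testing.assert_allclose(interpolate_drift(self._traj(), 1), [0.0, 0.0])
        np.testing.assert_allclose(interpolate_drift(self._traj(), 99), [6.0, 2.0])

    def test_zero_trajectory_identity(self, small_table_2d):
        traj = DriftTrajectory(np.array([1.0, 2.0]), np.zeros((2, 2)), np.zeros((2, 2)))
        out = apply_drift_correction(small_table_2d, traj)
        np.testing.assert_array_equal(out.xy, small_table_2d.xy)
        np.testing.assert_array_equal(out.frame, small_table_2d.frame)
        np.testing.assert_array_equal(out.precision, small_table_2d.precision)

    def test_dimension_mismatch_raises(self, small_table_3d):
        traj = DriftTrajectory(np.array([1.0, 2.0]), np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            apply_drift_correction(small_table_3d, traj)


class TestPairwiseShifts:
    def _translated_bins_table(self):
        """Bin j's points = bin i's points translated by known t_ij, with
        molecules well separated so windows never mix them."""
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 20000, (40, 2))
        shifts = np.array([[0.0, 0.0], [12.0, -8.0], [30.0, 14.0]])
        frames, xy = [], []
        for k, s in enumerate(shifts):
            frames.append(np.full(40, 10 * k + 5))
            xy.append(base + s)
        return (
            LocalizationTable(np.concatenate(frames), np.vstack(xy)),
            shifts,
        )

    def test_exact_translation_between_bins(self):
        table, shifts = self._translated_bins_table()
        binning = bin_frames(30, 10)
        m = pairwise_shifts(table, binning, MSParams(r_initial=150.0, min_pairs=1))
        for (i, j), e in m.entries.items():
            np.testing.assert_allclose(e.shift, shifts[j] - shifts[i], atol=1e-9)

    def test_k2_reduces_to_single_mean_shift(self):
        from msdrift.meanshift import mean_shift

        table, _ = self._translated_bins_table()
        sub = table.select(table.frame <= 16)
        binning = bin_frames(20, 10)
        m = pairwise_shifts(sub, binning, MSParams(r_initial=150.0, min_pairs=1))
        assert set(m.entries) == {(0, 1)}
        direct = mean_shift(sub.xy[sub.frame <= 10], sub.xy[sub.frame > 10],
                            MSParams(r_initial=150.0, min_pairs=1))
        np.testing.assert_allclose(m.entries[(0, 1)].shift, direct.shift)

    def test_empty_bin_flagged_not_fatal(self):
        table = LocalizationTable(
            np.array([1, 1, 21, 21]), np.array([[0.0, 0.0], [50.0, 0.0], [1.0, 1.0], [51.0, 1.0]])
        )
        binning = bin_frames(30, 10)  # middle bin has no localizations
        m = pairwise_shifts(table, binning, MSParams(r_initial=150.0, min_pairs=1))
        assert not m.entries[(0, 1)].valid and not m.entries[(1, 2)].valid
        assert m.entries[(0, 2)].valid


class TestEndToEnd:
    def test_linear_drift_recovered_and_corrected(self):
        """Simulated linear drift: the fitted trajectory matches the truth at
        every control point and correction restores molecule tightness."""
        from dataclasses import replace

        from msdrift.simulate import EASY_2D, simulate_drift_series

        cfg = replace(EASY_2D, density=10.0, mean_locs=40.0, cell_radius=3.0,
                      n_frames=3000, seed=11)
        rate = 0.02  # nm/frame -> 60 nm total
        def curve(frames):
            return np.stack([rate * (frames - 1), -0.5 * rate * (frames - 1)], axis=-1)

        table, truth = simulate_drift_series(cfg, curve)
        params = MSParams(r_initial=150.0, r_window=50.0)
        traj = estimate_drift(table, 600, params)
        t0 = traj.times[0]
        expected = np.stack(
            [np.interp(traj.times, np.arange(1, 3001), truth[:, ax]) for ax in range(2)], axis=-1
        )
        expected -= expected[0]
        assert np.all(np.abs(traj.d - expected) < 3.0)
        corrected = apply_drift_correction(table, traj)
        # re-estimating on the corrected table: residual accrued drift is a
        # small fraction of the original (the clamped edges retain ~rate*bw/4)
        resid = estimate_drift(corrected, 600, params)
        accrued = np.linalg.norm(expected[-1])
        assert np.linalg.norm(resid.d[-1]) < 0.1 * accrued
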