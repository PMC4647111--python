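"""Accumulate / resample / gap-fill engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supersample import (
    ResampledSignal,
    SuperSampledSignal,
    Sweep,
    TimeBase,
    accumulate,
    fill_gaps,
    max_reconstruction_rate_hz,
    resample,
)


def sweep_on_ticks(sweep_id, ticks, values, rate_hz):
    return Sweep(sweep_id, frame_times_s=np.asarray(ticks) / rate_hz, values=values)


class TestAccumulate:
    def test_single_sweep_weights(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=50)
        sw = sweep_on_ticks("a", [0, 10, 20], [1.0, 2.0, 3.0], 1000.0)
        ss = accumulate([sw], [0.0], tb)
        expected_w = np.zeros(50, dtype=int)
        expected_w[[0, 10, 20]] = 1
        np.testing.assert_array_equal(ss.weight, expected_w)
        assert ss.value_sum[10] == 2.0
        assert ss.n_dropped_frames == 0

    def test_two_sweeps_same_ticks_sum_and_count(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=30)
        a = sweep_on_ticks("a", [5, 15], [1.0, 2.0], 1000.0)
        b = sweep_on_ticks("b", [5, 15], [10.0, 20.0], 1000.0)
        ss = accumulate([a, b], [0.0, 0.0], tb)
        assert ss.weight[5] == 2 and ss.weight[15] == 2
        assert ss.value_sum[5] == 11.0 and ss.value_sum[15] == 22.0

    def test_out_of_range_frames_dropped_and_counted(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=10)
        sw = sweep_on_ticks("a", [0, 5, 9], [1.0, 1.0, 1.0], 1000.0)
        ss = accumulate([sw], [0.003], tb)  # +3 ticks pushes tick 9 past the end
        assert ss.n_dropped_frames == 1
        assert ss.total_weight == 2

    def test_weight_conservation_on_model_case(self, model_case):
        case = model_case
        ss = accumulate(case.as_sweeps(), case.alignment_shifts_s(), case.timebase())
        n_frames = case.cfg.n_sweeps * len(case.lr_sweeps[0])
        assert ss.total_weight + ss.n_dropped_frames == n_frames

    def test_colliding_frames_of_one_sweep_error(self):
        tb = TimeBase(rate_hz=100.0, n_ticks=10)  # coarser than the frame spacing
        sw = Sweep("a", frame_times_s=[0.000, 0.004], values=[1.0, 2.0])
        with pytest.raises(ValueError, match="too coarse"):
            accumulate([sw], [0.0], tb)

    def test_shift_count_mismatch(self):
        tb = TimeBase(rate_hz=100.0, n_ticks=10)
        sw = sweep_on_ticks("a", [0], [1.0], 100.0)
        with pytest.raises(ValueError):
            accumulate([sw], [0.0, 0.0], tb)


class TestResample:
    def test_single_sweep_identity_at_lr_rate(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=100)
        values = np.arange(10.0)
        sw = sweep_on_ticks("a", np.arange(10) * 10, values, 1000.0)
        rs = resample(accumulate([sw], [0.0], tb), 100.0)
        np.testing.assert_array_equal(rs.values, values)
        assert not rs.missing_mask.any()

    def test_weighted_mean_in_one_bin(self):
        """Ticks carrying value sums 2 (w=1) and 12 (w=3) merge to (2+12)/(1+3)."""
        tb = TimeBase(rate_hz=1000.0, n_ticks=10)
        ss = SuperSampledSignal(
            tb,
            value_sum=np.array([2.0, 12.0] + [0.0] * 8),
            weight=np.array([1, 3] + [0] * 8),
        )
        rs = resample(ss, 100.0)  # all 10 ticks collapse into one bin
        assert rs.values[0] == pytest.approx(3.5)
        assert rs.bin_weight[0] == 4

    def test_mean_of_identical_sweeps_is_exact(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=100)
        values = np.sin(np.arange(10.0))
        sweeps = [sweep_on_ticks(f"s{i}", np.arange(10) * 10, values, 1000.0) for i in range(5)]
        rs = resample(accumulate(sweeps, [0.0] * 5, tb), 100.0)
        np.testing.assert_allclose(rs.values, values, atol=1e-15)

    def test_rate_above_grid_rejected(self):
        tb = TimeBase(rate_hz=1000.0, n_ticks=10)
        ss = SuperSampledSignal(tb, np.zeros(10), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            resample(ss, 2000.0)

    def test_conservation_at_any_target_rate(self, model_case):
        case = model_case
        ss = accumulate(case.as_sweeps(), case.alignment_shifts_s(), case.timebase())
        for rate in (500.0, 1300.0, 10_000.0):
            rs = resample(ss, rate)
            lhs = np.nansum(rs.values * rs.bin_weight)
            assert lhs == pytest.approx(ss.value_sum.sum(), rel=1e-12)

    def test_noiseless_bins_equal_ideal_on_covered_ticks(self, model_case):
        case = model_case
        ss = accumulate(case.as_sweeps(), case.alignment_shifts_s(), case.timebase())
        rs = resample(ss, case.cfg.hr_rate_hz)
        covered = ~rs.missing_mask
        np.testing.assert_allclose(rs.values[covered], case.ideal[covered], atol=1e-12)

    def test_monotone_coverage_in_sweeps(self, model_case):
        case = model_case
        tb = case.timebase()
        missing_counts = []
        for n in (1, 5, 10, 25, 50):
            ss = accumulate(case.as_sweeps(n), case.alignment_shifts_s(n), tb)
            missing_counts.append(int(resample(ss, 10_000.0).missing_mask.sum()))
        assert all(a >= b for a, b in zip(missing_counts, missing_counts[1:]))


class TestFillGaps:
    def make_rs(self, values, weights):
        values = np.asarray(values, dtype=float)
        weights = np.asarray(weights)
        return ResampledSignal(
            rate_hz=10.0, values=values, bin_weight=weights, missing_mask=weights == 0
        )

    def test_no_missing_is_identity(self):
        rs = self.make_rs([1.0, 2.0, 3.0], [1, 1, 1])
        out = fill_gaps(rs, "linear")
        np.testing.assert_array_equal(out.values, rs.values)
        assert out.filled

    def test_interior_gap_interpolated(self):
        rs = self.make_rs([1.0, np.nan, 3.0], [1, 0, 1])
        out = fill_gaps(rs, "linear")
        np.testing.assert_allclose(out.values, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(out.missing_mask, [False, True, False])

    def test_edge_gaps_held_at_nearest(self):
        rs = self.make_rs([np.nan, 5.0, 7.0, np.nan], [0, 2, 1, 0])
        out = fill_gaps(rs, "linear")
        np.testing.assert_allclose(out.values, [5.0, 5.0, 7.0, 7.0])

    def test_method_none_preserves_nans(self):
        rs = self.make_rs([1.0, np.nan, 3.0], [1, 0, 1])
        out = fill_gaps(rs, "none")
        assert np.isnan(out.values[1]) and not out.filled

    def test_all_missing_errors(self):
        rs = self.make_rs([np.nan, np.nan], [0, 0])
        with pytest.raises(ValueError):
            fill_gaps(rs, "linear")

    def test_single_support_point_errors(self):
        rs = self.make_rs([np.nan, 4.0, np.nan], [0, 1, 0])
        with pytest.raises(ValueError):
            fill_gaps(rs, "linear")


class TestBruteForceOracle:
    """resample must agree with direct binning of every (time, value) pair."""

    @staticmethod
    def oracle(sweeps, shifts_ticks, hr_rate, n_ticks, target_rate):
        bins = {}
        for sw, s in zip(sweeps, shifts_ticks):
            for t, v in zip(sw.frame_times_s, sw.values):
                k = int(round(t * hr_rate)) + s
                if not 0 <= k < n_ticks:
                    continue
                b = (k * int(target_rate)) // int(hr_rate)
                bins.setdefault(b, []).append(v)
        return {b: float(np.mean(vs)) for b, vs in bins.items()}

    @given(st.integers(min_value=0, max_value=99))
    @settings(max_examples=100)
    def test_random_small_instances(self, instance):
        rng = np.random.default_rng(instance)
        hr = 1000
        n_ticks = int(rng.integers(50, 200))
        n_sweeps = int(rng.integers(1, 6))
        target = int(rng.integers(10, hr + 1))
        sweeps, shifts = [], []
        for i in range(n_sweeps):
            n_frames = int(rng.integers(1, 21))
            ticks = np.sort(rng.choice(n_ticks, size=n_frames, replace=False))
            sweeps.append(
                Sweep(f"s{i}", frame_times_s=ticks / hr, values=rng.normal(size=n_frames))
            )
            shifts.append(int(rng.integers(-10, 11)))
        tb = TimeBase(rate_hz=float(hr), n_ticks=n_ticks)
        rs = resample(accumulate(sweeps, np.array(shifts) / hr, tb), float(target))
        expected = self.oracle(sweeps, shifts, hr, n_ticks, target)
        for b in range(rs.n_bins):
            if b in expected:
                assert rs.values[b] == pytest.approx(expected[b], rel=1e-12, abs=1e-12)
            else:
                assert rs.missing_mask[b]


class TestSamplingBound:
    def test_bound_value(self):
        assert max_reconstruction_rate_hz(500.0, 10) == 5000.0

    def test_full_coverage_achievable_at_the_bound(self):
        """Shifts spread over distinct residues fill every 5 kHz bin with 10 sweeps."""
        hr, lr, n_ticks = 10_000.0, 500.0, 400
        tb = TimeBase(rate_hz=hr, n_ticks=n_ticks)
        sweeps = [
            Sweep(f"s{s}", frame_times_s=np.arange(20) / lr, values=np.zeros(20) + s)
            for s in range(10)
        ]
        shifts = [2 * s / hr for s in range(10)]  # ticks 0,2,...,18 modulo 20
        rs = resample(accumulate(sweeps, shifts, tb), 5000.0)
        assert not rs.missing_mask.any()

    def test_missing_guaranteed_above_the_bound(self):
        """More bins than samples: gaps occur for every jitter realization."""
        hr, lr, n_ticks = 10_000.0, 500.0, 400
        tb = TimeBase(rate_hz=hr, n_ticks=n_ticks)
        rng = np.random.default_rng(0)
        for _ in range(20):
            shifts_ticks = rng.integers(0, 50, size=10)
            sweeps = [
                Sweep(f"s{i}", frame_times_s=np.arange(20) / lr, values=np.zeros(20))
                for i in range(10)
            ]
            rs = resample(accumulate(sweeps, -shifts_ticks / hr, tb), 5200.0)
            n_bins = rs.n_bins
            assert n_bins > 10 * 20
            assert rs.missing_mask.sum() >= n_bins - 10 * 20 > 0
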