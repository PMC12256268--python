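"""Signal conditioning, cycle segmentation and phase timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gateqa.errors import ParameterError
from gateqa.respiratory_signal import (
    DegenerateSignalWarning,
    RespiratoryCycle,
    Signal1D,
    average_periodic_signal,
    extract_component,
    minmax_normalize,
    moving_mean_smooth,
    phase_time,
    segment_cycles,
)
from gateqa.synthetic_phantom import SimulationConfig, simulate_motion


def _sig(v, dt=0.04):
    v = np.asarray(v, dtype=float)
    return Signal1D(t=np.arange(v.size) * dt, v=v)


finite_lists = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False).map(
        lambda x: round(x, 6)  # physical signal resolution; avoids denormals
    ),
    min_size=2,
    max_size=50,
)


class TestExtract:
    def test_axis_values_and_shared_time_base(self, default_cfg):
        motion = simulate_motion(default_cfg)
        sz = extract_component(motion, "z")
        sx = extract_component(motion, "x")
        np.testing.assert_array_equal(sz.v, motion.z)
        np.testing.assert_array_equal(sz.t, sx.t)

    def test_unknown_axis(self, default_cfg):
        with pytest.raises(ParameterError, match="axis"):
            extract_component(simulate_motion(default_cfg), "w")


class TestMinMax:
    def test_simple_case(self):
        out = minmax_normalize(_sig([0, 5, 10]))
        assert out.v.tolist() == [0.0, 0.5, 1.0]

    def test_constant_signal_warns_and_returns_zeros(self):
        with pytest.warns(DegenerateSignalWarning):
            out = minmax_normalize(_sig([3, 3, 3]))
        assert out.v.tolist() == [0.0, 0.0, 0.0]

    @given(finite_lists)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_closed_form_and_is_idempotent(self, values):
        s = _sig(values)
        if np.ptp(s.v) == 0:
            return
        out = minmax_normalize(s)
        expected = (s.v - s.v.min()) / (s.v.max() - s.v.min())
        np.testing.assert_allclose(out.v, expected)
        assert out.v.min() == 0.0 and out.v.max() == 1.0
        np.testing.assert_allclose(minmax_normalize(out).v, out.v)


class TestMovingMean:
    def test_shrinking_window_hand_case(self):
        out = moving_mean_smooth(_sig([1, 2, 3, 4, 5]), window=5)
        np.testing.assert_allclose(out.v, [2, 2.5, 3, 3.5, 4])

    def test_window_one_is_identity(self):
        v = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_array_equal(moving_mean_smooth(_sig(v), 1).v, v)

    def test_constant_signal_unchanged(self):
        out = moving_mean_smooth(_sig([2.5] * 9), 5)
        np.testing.assert_allclose(out.v, 2.5)

    def test_linear_ramp_interior_unchanged(self):
        # the centered mean of a linear trend equals the trend away from the ends
        v = np.arange(20, dtype=float)
        out = moving_mean_smooth(_sig(v), 5)
        np.testing.assert_allclose(out.v[2:-2], v[2:-2])

    @pytest.mark.parametrize("window", [0, -1, 2, 4])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ParameterError):
            moving_mean_smooth(_sig([1, 2, 3, 4, 5]), window)

    @given(finite_lists, st.sampled_from([1, 3, 5]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_truncated_means(self, values, window):
        s = _sig(values)
        if window > len(s):
            return
        out = moving_mean_smooth(s, window)
        half = window // 2
        expected = [
            np.mean(s.v[max(0, i - half): i + half + 1]) for i in range(len(s))
        ]
        np.testing.assert_allclose(out.v, expected)


def _brute_local_maxima_with_prominence(v, min_prominence):
    """Exhaustive local-maximum scan with the same prominence rule."""
    peaks = []
    for i in range(1, len(v) - 1):
        if not (v[i] > v[i - 1] and v[i] >= v[i + 1]):
            continue
        if v[i] == v[i + 1]:  # plateau: scipy keeps the left edge of even runs
            continue
        # prominence: height above the higher of the two valley minima,
        # where each side extends to the nearest strictly higher sample
        proms = []
        for step in (-1, 1):
            j = i + step
            valley = v[i]
            while 0 <= j < len(v) and v[j] <= v[i]:
                valley = min(valley, v[j])
                j += step
            proms.append(v[i] - valley)
        if min(proms) >= min_prominence:
            peaks.append(i)
    return peaks


class TestSegmentation:
    def test_noiseless_sinusoid_periods(self):
        cfg = SimulationConfig(period_s=4.0, n_cycles=6, noise_sd=0.0,
                               epid_noise_sd=0.0, seed=None)
        s = minmax_normalize(extract_component(simulate_motion(cfg), "z"))
        cycles = segment_cycles(moving_mean_smooth(s, 5))
        assert len(cycles) == 5
        for c in cycles:
            assert abs(c.period - 4.0) <= 0.04

    def test_constant_signal_yields_empty_list(self):
        assert segment_cycles(_sig([0.5] * 200)) == []

    def test_single_peak_yields_empty_list(self):
        t = np.linspace(0, 4, 101)
        s = Signal1D(t=t, v=np.exp(-((t - 2.0) ** 2)))
        assert segment_cycles(s) == []

    def test_noisy_sinusoid_same_cycle_count_as_noiseless(self):
        clean = SimulationConfig(period_s=4.0, n_cycles=6, noise_sd=0.0,
                                 epid_noise_sd=0.0, seed=None)
        noisy = SimulationConfig(period_s=4.0, n_cycles=6, noise_sd=0.05, seed=42)
        def count(cfg):
            s = minmax_normalize(extract_component(simulate_motion(cfg), "z"))
            return len(segment_cycles(moving_mean_smooth(s, 5)))
        assert count(noisy) == count(clean) == 5

    def test_peaks_equal_exhaustive_scan(self, rng):
        from scipy.signal import find_peaks

        for _ in range(50):
            v = np.convolve(rng.normal(size=60), np.ones(5) / 5, mode="same")
            v = (v - v.min()) / np.ptp(v)
            expected = _brute_local_maxima_with_prominence(v, 0.2)
            got, _ = find_peaks(v, prominence=0.2)
            assert got.tolist() == expected

    def test_cycles_are_contiguous_ordered_and_positive(self, default_cfg):
        s = minmax_normalize(extract_component(simulate_motion(default_cfg), "z"))
        cycles = segment_cycles(moving_mean_smooth(s, 5))
        assert len(cycles) >= 2
        for a, b in zip(cycles, cycles[1:]):
            assert a.t_end == b.t_start  # contiguous interval
            assert a.period > 0


class TestPhaseTime:
    def test_linear_phase_identities(self):
        c = RespiratoryCycle(index=0, t_start=0.0, t_end=4.0)
        assert phase_time(c, 0.25).time == pytest.approx(1.0)
        assert phase_time(c, 0.75).time == pytest.approx(3.0)
        assert phase_time(c, 0.0).time == c.t_start
        assert phase_time(c, 1.0).time == c.t_end

    def test_window_duration_is_half_period_exactly(self):
        # a 5.32 s cycle gives the reference 2.66 s planned window
        c = RespiratoryCycle(index=0, t_start=10.0, t_end=15.32)
        window = phase_time(c, 0.75).time - phase_time(c, 0.25).time
        assert window == pytest.approx(2.66)
        assert window == pytest.approx(0.5 * c.period)

    @pytest.mark.parametrize("bad", [-0.1, 1.01])
    def test_fraction_out_of_range(self, bad):
        c = RespiratoryCycle(index=0, t_start=0.0, t_end=4.0)
        with pytest.raises(ParameterError):
            phase_time(c, bad)


class TestAveragePeriodicSignal:
    def test_identical_cycles_have_zero_sd(self):
        cfg = SimulationConfig(period_s=4.0, n_cycles=6, noise_sd=0.0,
                               epid_noise_sd=0.0, seed=None)
        s = minmax_normalize(extract_component(simulate_motion(cfg), "z"))
        cycles = [RespiratoryCycle(k, k * 4.0, (k + 1) * 4.0) for k in range(5)]
        avg = average_periodic_signal(s, cycles)
        assert avg.n_cycles == 5
        np.testing.assert_allclose(avg.sd_v, 0.0, atol=1e-9)
        # and the mean equals one cycle's resampled shape
        np.testing.assert_allclose(
            avg.mean_v, np.interp(avg.phase_grid * 4.0, s.t, s.v), atol=1e-9
        )

    def test_single_cycle_mean_is_its_own_interpolation(self):
        t = np.arange(200) * 0.04
        s = Signal1D(t=t, v=np.cos(2 * np.pi * t / 4.0))
        avg = average_periodic_signal(s, [RespiratoryCycle(0, 0.0, 4.0)])
        np.testing.assert_allclose(
            avg.mean_v, np.interp(avg.phase_grid * 4.0, t, s.v)
        )
        np.testing.assert_array_equal(avg.sd_v, 0.0)

    def test_noisy_cycles_mean_converges_to_waveform(self, rng):
        # Monte-Carlo: with n cycles of iid noise the grid mean should sit
        # within ~2 sd/sqrt(n) of the true waveform (3 sd margin used)
        T, dt, n_cyc, noise = 4.0, 0.02, 30, 0.05
        t = np.arange(int(n_cyc * T / dt)) * dt
        true = np.cos(2 * np.pi * t / T)
        s = Signal1D(t=t, v=true + rng.normal(0, noise, t.size))
        cycles = [RespiratoryCycle(k, k * T, (k + 1) * T) for k in range(n_cyc)]
        avg = average_periodic_signal(s, cycles)
        expected = np.cos(2 * np.pi * avg.phase_grid)
        assert np.max(np.abs(avg.mean_v - expected)) < 3 * noise / np.sqrt(n_cyc)

    def test_empty_cycles_rejected(self):
        with pytest.raises(ParameterError):
            average_periodic_signal(_sig([1, 2, 3]), [])
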