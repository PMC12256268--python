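"""EPID cine frame analysis: ROI series, thresholding, durations, I/O."""

import json

import numpy as np
import pytest

from gateqa.epid_cine import (
    EpidFrameSeries,
    FrameStack,
    RoiSpec,
    compare_epid_vs_log,
    compute_roi_series,
    detect_beam_on_frames,
    epid_beam_durations,
    epid_duration_stats,
    load_cine_frames,
    write_dicom_stack,
    write_raw_stack,
)
from gateqa.errors import ConfigurationError, EmptyInputError, ParameterError
from gateqa.synthetic_phantom import SimulationConfig, simulate_epid_cine, simulate_gated_beam, simulate_motion


def _stack(frames, fp=0.04, spacing=0.15, sid=150.0, sad=100.0):
    frames = np.asarray(frames, dtype=float)
    return FrameStack(
        frames=frames,
        frame_times=np.arange(frames.shape[0]) * fp,
        pixel_spacing_cm=spacing,
        sid_cm=sid,
        sad_cm=sad,
    )


def _series(norm, fp=0.04):
    norm = np.asarray(norm, dtype=float)
    return EpidFrameSeries(
        frame_times=np.arange(norm.size) * fp,
        frame_period=fp,
        roi_mean=norm,
        roi_mean_norm=norm,
    )


class TestRoiSeries:
    def test_constant_frames(self):
        series = compute_roi_series(_stack(np.full((4, 64, 64), 7.0)))
        np.testing.assert_array_equal(series.roi_mean, 7.0)
        np.testing.assert_array_equal(series.roi_mean_norm, 1.0)

    def test_single_bright_frame_normalizes_to_one(self):
        frames = np.full((5, 64, 64), 1.0)
        frames[2] = 50.0
        series = compute_roi_series(_stack(frames))
        assert np.sum(series.roi_mean_norm == 1.0) == 1
        assert series.roi_mean_norm[2] == 1.0

    def test_projected_roi_extent_uses_magnification(self):
        # 5 cm at iso with SID/SAD = 1.5 and 0.15 cm pixels -> 50x50 block
        roi = RoiSpec()
        assert roi.projected_side_cm == pytest.approx(7.5)
        frames = np.zeros((2, 64, 64))
        frames[:, 7:57, 7:57] = 10.0  # exactly the centered 50x50 block
        series = compute_roi_series(_stack(frames), roi)
        assert series.roi_mean[0] == pytest.approx(10.0)

    def test_matches_bruteforce_pixel_loop(self, rng):
        for _ in range(20):
            frames = rng.random((3, 32, 32))
            stack = _stack(frames, spacing=0.5)
            roi = RoiSpec(side_cm_at_iso=4.0, sad_cm=100.0, sid_cm=100.0)
            series = compute_roi_series(stack, roi)
            n_px = 8  # 4 cm / 0.5 cm, no magnification
            r0 = c0 = 16 - n_px // 2
            for k in range(3):
                acc = 0.0
                for i in range(n_px):
                    for j in range(n_px):
                        acc += frames[k, r0 + i, c0 + j]
                assert series.roi_mean[k] == pytest.approx(acc / n_px**2)

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ParameterError, match="ROI"):
            compute_roi_series(_stack(np.ones((1, 16, 16))), RoiSpec())

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            RoiSpec(sad_cm=150.0, sid_cm=100.0)


class TestThreshold:
    def test_definition_case(self):
        norm = [0.01, 0.02, 0.6, 0.9, 1.0, 0.95, 0.7, 0.3, 0.02, 0.01]
        mask, segments = detect_beam_on_frames(_series(norm))
        assert int(mask.sum()) == 5
        assert segments == [(2, 6)]

    def test_all_below_threshold(self):
        _, segments = detect_beam_on_frames(_series([0.1, 0.4, 0.2]))
        assert segments == []

    def test_strict_inequality_at_threshold(self):
        # a frame exactly at 50% counts as off
        _, segments = detect_beam_on_frames(_series([0.5, 0.51, 0.5]))
        assert segments == [(1, 1)]

    def test_raising_threshold_never_adds_frames(self):
        rng = np.random.default_rng(3)
        norm = rng.random(200)
        counts = [
            detect_beam_on_frames(_series(norm), thr)[0].sum()
            for thr in (0.3, 0.5, 0.7)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestDurations:
    def test_duration_formula(self):
        assert epid_beam_durations([(0, 4)], 0.04) == [pytest.approx(0.2)]

    def test_66_frames_at_cine_rate(self):
        # 66 frames above threshold at 0.04 s -> 2.64 s beam-on time
        assert epid_beam_durations([(10, 75)], 0.04)[0] == pytest.approx(2.64)

    def test_durations_are_frame_period_multiples(self, rng):
        segs = [(int(a), int(a + w)) for a, w in
                zip(rng.integers(0, 50, 10) * 100, rng.integers(0, 80, 10))]
        for d in epid_beam_durations(segs, 0.04):
            assert (d / 0.04) == pytest.approx(round(d / 0.04))

    def test_stats_require_segments(self):
        assert epid_beam_durations([], 0.04) == []
        with pytest.raises(EmptyInputError):
            epid_duration_stats([])


class TestCompare:
    def test_identical_lists(self):
        cmp = compare_epid_vs_log([2.6, 2.6], [2.6, 2.6])
        assert cmp.mode == "paired"
        assert cmp.diffs == [0.0, 0.0]

    def test_single_pair_arithmetic(self):
        cmp = compare_epid_vs_log([2.64], [2.61])
        assert cmp.mean_diff == pytest.approx(0.03)

    def test_count_mismatch_falls_back_to_mean_difference(self):
        cmp = compare_epid_vs_log([2.6, 2.6, 2.6], [2.5, 2.7])
        assert cmp.mode == "mean"
        assert cmp.mean_diff == pytest.approx(0.0)

    def test_empty_sides_rejected(self):
        with pytest.raises(EmptyInputError):
            compare_epid_vs_log([], [])
        with pytest.raises(EmptyInputError):
            compare_epid_vs_log([2.6], [])


class TestSimulatorRoundTrip:
    def test_known_window_recovered_exactly(self):
        # beam on for exactly 50 whole frames, no noise or persistence
        cfg = SimulationConfig(period_s=4.0, gating_window=(0.25, 0.75),
                               latency_on_s=0.0, latency_off_s=0.0,
                               noise_sd=0.0, epid_noise_sd=0.0,
                               epid_frame_period_s=0.04, seed=None)
        motion = simulate_motion(cfg)
        _, truth = simulate_gated_beam(motion, cfg)
        stack = simulate_epid_cine(truth, cfg)
        series = compute_roi_series(stack)
        mask, segments = detect_beam_on_frames(series)
        assert len(segments) == cfg.n_cycles
        for start, end in segments:
            assert end - start + 1 == 50  # 2.0 s / 0.04 s

    def test_duration_within_one_frame_of_truth(self, default_cfg):
        motion = simulate_motion(default_cfg)
        _, truth = simulate_gated_beam(motion, default_cfg)
        stack = simulate_epid_cine(truth, default_cfg)
        _, segments = detect_beam_on_frames(compute_roi_series(stack))
        durations = epid_beam_durations(segments, default_cfg.epid_frame_period_s)
        true_dur = truth.off_times - truth.on_times
        assert len(durations) == len(true_dur)
        for d, td in zip(durations, true_dur):
            assert abs(d - td) <= default_cfg.epid_frame_period_s

    def test_persistence_extends_by_at_most_one_frame(self):
        base = dict(period_s=4.0, latency_on_s=0.0, latency_off_s=0.0,
                    noise_sd=0.0, epid_noise_sd=0.0, seed=None)
        cfg0 = SimulationConfig(**base)
        cfg1 = SimulationConfig(**base, epid_persistence_frames=1)
        motion = simulate_motion(cfg0)
        _, truth = simulate_gated_beam(motion, cfg0)
        for cfg in (cfg0, cfg1):
            stack = simulate_epid_cine(truth, cfg)
            _, segments = detect_beam_on_frames(compute_roi_series(stack))
            durations = epid_beam_durations(segments, cfg.epid_frame_period_s)
            for d, td in zip(durations, truth.off_times - truth.on_times):
                assert td - cfg.epid_frame_period_s <= d
                assert d <= td + cfg.epid_frame_period_s


class TestIO:
    def test_raw_stack_round_trip(self, tmp_path, default_cfg):
        motion = simulate_motion(default_cfg)
        _, truth = simulate_gated_beam(motion, default_cfg)
        stack = simulate_epid_cine(truth, default_cfg)
        write_raw_stack(stack, tmp_path)
        back = load_cine_frames(tmp_path)
        assert back.frames.shape == stack.frames.shape
        np.testing.assert_allclose(back.frame_times, stack.frame_times, atol=1e-9)
        assert back.frame_period == pytest.approx(stack.frame_period)

    def test_dicom_round_trip_orders_by_time(self, tmp_path):
        frames = np.zeros((6, 16, 16))
        for i in range(6):
            frames[i] = i * 100.0
        stack = _stack(frames, spacing=0.5)
        write_dicom_stack(stack, tmp_path)
        back = load_cine_frames(tmp_path)
        assert back.frames.shape == (6, 16, 16)
        np.testing.assert_allclose(back.frame_times, stack.frame_times, atol=1e-6)
        assert back.pixel_spacing_cm == pytest.approx(0.5)
        assert back.sid_cm == pytest.approx(150.0)
        assert back.sad_cm == pytest.approx(100.0)
        np.testing.assert_array_equal(back.frames[3], frames[3])

    def test_missing_sid_falls_back_to_config(self, tmp_path):
        import pydicom

        stack = _stack(np.ones((2, 8, 8)), spacing=0.5)
        for p in write_dicom_stack(stack, tmp_path):
            ds = pydicom.dcmread(p)
            del ds.RTImageSID
            ds.save_as(p, enforce_file_format=True)
        back = load_cine_frames(tmp_path, sid_cm=140.0)
        assert back.sid_cm == pytest.approx(140.0)
        with pytest.raises(ConfigurationError, match="SID"):
            load_cine_frames(tmp_path)

    def test_mixed_geometries_rejected(self, tmp_path):
        write_dicom_stack(_stack(np.ones((1, 8, 8)), spacing=0.5), tmp_path)
        import pydicom

        p = sorted(tmp_path.glob("*.dcm"))[0]
        big = tmp_path / "frame_0001.dcm"
        ds = pydicom.dcmread(p)
        ds.Rows = 12
        ds.PixelData = np.ones((12, 8), dtype=np.uint16).tobytes()
        ds.InstanceNumber = 2
        ds.ContentTime = "000001.000000"
        ds.save_as(big, enforce_file_format=True)
        with pytest.raises(ConfigurationError, match="mixed"):
            load_cine_frames(tmp_path)

    def test_raw_sidecar_carries_timing(self, tmp_path, default_cfg):
        motion = simulate_motion(default_cfg)
        _, truth = simulate_gated_beam(motion, default_cfg)
        stack = simulate_epid_cine(truth, default_cfg)
        manifest = write_raw_stack(stack, tmp_path)
        sidecar = json.loads((tmp_path / "sidecar.json").read_text())
        assert sidecar["frame_period_s"] == pytest.approx(0.04)
        assert manifest["sidecar"].endswith("sidecar.json")
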