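"""Virtual motion phantom with known ground truth.

Emulates a QA session on a programmable motion phantom: a reflector block
moves periodically in the anterior-posterior direction, the gating system
enables the beam while the breathing phase is inside the planned window,
and an EPID records cine frames. Because the motion is analytic, every
quantity the analysis pipeline estimates (cycle boundaries, 25%/75% phase
times, trigger latencies, beam-on durations) has an exact known value, so
the whole pipeline is testable without vendor data.

Defaults describe a regular phantom session: period 5.32 s (so the 25-75%
window lasts 2.66 s), 1 cm motion amplitude sampled at 25 Hz over 6
cycles, small surrogate noise (SD 0.01 normalized units), beam-on latency
+0.03 s and beam-off latency -0.04 s, and a 0.04 s EPID frame period.

Trigger latencies are applied to the exact event times *before* resampling
onto the log clock, so sub-sample latencies are exercised.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .epid_cine import FrameStack, write_raw_stack
from .errors import ParameterError
from .gating_log_io import (
    BeamTriggerTrace,
    GatingLogRecord,
    MotionTrace,
    write_gating_log,
)

__all__ = [
    "SimulationConfig",
    "BeamTruth",
    "simulate_motion",
    "simulate_gated_beam",
    "simulate_epid_cine",
    "simulate_dose_readings",
    "make_fixture_set",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated phantom session.

    ``noise_sd`` and ``epid_noise_sd`` are in normalized units (fractions
    of the motion amplitude / of the beam-on ROI intensity). ``waveform``
    is ``"sine"`` (a cosine peaking at t=0; analytically tractable) or
    ``"cos4"`` (cosine to the fourth power, which dwells at end-exhale
    like real breathing). Latencies shift the beam trigger edges relative
    to the exact phase-window edges and may be negative (early trigger).
    """

    period_s: float = 5.32
    amplitude_cm: float = 1.0
    waveform: str = "sine"
    n_cycles: int = 6
    sample_rate_hz: float = 25.0
    noise_sd: float = 0.01
    gating_window: tuple[float, float] = (0.25, 0.75)
    latency_on_s: float = 0.03
    latency_off_s: float = -0.04
    epid_frame_period_s: float = 0.04
    epid_noise_sd: float = 0.01
    epid_persistence_frames: int = 0
    seed: int | None = 0

    def __post_init__(self):
        if min(self.period_s, self.amplitude_cm, self.sample_rate_hz,
               self.epid_frame_period_s) <= 0:
            raise ParameterError("period, amplitude and rates must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.waveform not in ("sine", "cos4"):
            raise ParameterError(f"unknown waveform {self.waveform!r}")
        lo, hi = self.gating_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ParameterError("gating_window must satisfy 0 <= lo < hi <= 1")
        if max(abs(self.latency_on_s), abs(self.latency_off_s)) > self.period_s / 2:
            raise ParameterError("latency magnitude must not exceed half a period")
        if (self.noise_sd > 0 or self.epid_noise_sd > 0) and self.seed is None:
            raise ParameterError("a seed is required when any noise SD is > 0")
        if self.noise_sd < 0 or self.epid_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")
        if self.epid_persistence_frames < 0:
            raise ParameterError("epid_persistence_frames must be >= 0")


@dataclass
class BeamTruth:
    """Exact event times of the simulated session (for tests only)."""

    t_peaks: np.ndarray  # exact 0%-phase (end-inhale) times, one per cycle
    t25: np.ndarray  # exact window-open phase times
    t75: np.ndarray  # exact window-close phase times
    on_times: np.ndarray  # trigger rising edges = t25 + latency_on
    off_times: np.ndarray  # trigger falling edges = t75 + latency_off
    latency_on_s: float
    latency_off_s: float


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams per output so e.g. EPID noise does not
    # perturb the motion trace
    return np.random.default_rng([int(cfg.seed or 0), stream])


def simulate_motion(cfg: SimulationConfig) -> MotionTrace:
    """Periodic AP motion of the reflector block, with optional noise.

    ``z(t) = A * w(t)`` with ``w`` peaking at t = 0, plus Gaussian noise of
    SD ``noise_sd * A``; x and y are zero. Deterministic given the seed.
    """
    dt = 1.0 / cfg.sample_rate_hz
    n = int(round(cfg.n_cycles * cfg.period_s * cfg.sample_rate_hz))
    t = np.arange(n) * dt
    if cfg.waveform == "sine":
        z = cfg.amplitude_cm * np.cos(2 * np.pi * t / cfg.period_s)
    else:  # cos4
        z = cfg.amplitude_cm * np.cos(np.pi * t / cfg.period_s) ** 4
    if cfg.noise_sd > 0:
        z = z + _rng(cfg, 0).normal(0.0, cfg.noise_sd * cfg.amplitude_cm, n)
    zeros = np.zeros(n)
    return MotionTrace(t=t, x=zeros, y=zeros.copy(), z=z, sample_period=dt)


def simulate_gated_beam(
    motion: MotionTrace, cfg: SimulationConfig
) -> tuple[BeamTriggerTrace, BeamTruth]:
    """Gated beam flags for ``motion``, with exact event times retained.

    The true phase of the simulated motion is ``(t mod T) / T``; the beam
    is planned on while the phase is inside ``gating_window``. Rising
    edges are delayed by ``latency_on_s`` and falling edges by
    ``latency_off_s`` (in continuous time), then the flag is sampled onto
    the motion clock: a sample is on iff it falls inside a shifted
    [on, off) interval.
    """
    lo, hi = cfg.gating_window
    T = cfg.period_s
    k = np.arange(cfg.n_cycles)
    t_peaks = k * T
    t25 = t_peaks + lo * T
    t75 = t_peaks + hi * T
    on_times = t25 + cfg.latency_on_s
    off_times = t75 + cfg.latency_off_s
    if np.any(off_times <= on_times):
        raise ParameterError(
            "latencies collapse the beam-on interval (off edge before on edge)"
        )
    flags = np.zeros(len(motion), dtype=bool)
    dt = motion.sample_period
    n = len(motion)
    # sample events onto the clock by index so that a sample lying exactly
    # on an event time is the first sample of the new state (robust to
    # float representation of the time grid)
    for a, b in zip(on_times, off_times):
        i0 = max(0, int(np.ceil(a / dt - 1e-9)))
        i1 = max(0, int(np.ceil(b / dt - 1e-9)))
        flags[i0:min(i1, n)] = True
    return (
        BeamTriggerTrace(t=motion.t.copy(), on=flags),
        BeamTruth(
            t_peaks=t_peaks,
            t25=t25,
            t75=t75,
            on_times=on_times,
            off_times=off_times,
            latency_on_s=cfg.latency_on_s,
            latency_off_s=cfg.latency_off_s,
        ),
    )


def simulate_epid_cine(truth: BeamTruth, cfg: SimulationConfig) -> FrameStack:
    """Cine frame stack consistent with the true beam events.

    Frame k covers [k*fp, (k+1)*fp); its signal level is the fraction of
    that interval during which the beam was on (so partial frames at the
    segment edges have intermediate intensity). An optional exponential
    persistence tail with time constant ``epid_persistence_frames`` frames
    models detector lag; Gaussian pixel noise is seeded. In-field pixels
    sit at background + 1000 x signal; background is 10.
    """
    fp = cfg.epid_frame_period_s
    total = cfg.n_cycles * cfg.period_s
    n_frames = int(round(total / fp))
    starts = np.arange(n_frames) * fp
    frac = np.zeros(n_frames)
    for a, b in zip(truth.on_times, truth.off_times):
        overlap = np.minimum(starts + fp, b) - np.maximum(starts, a)
        frac += np.clip(overlap, 0.0, fp) / fp
    frac = np.clip(frac, 0.0, 1.0)
    if cfg.epid_persistence_frames > 0:
        alpha = float(np.exp(-1.0 / cfg.epid_persistence_frames))
        out = np.empty_like(frac)
        carry = 0.0
        for i, f in enumerate(frac):
            carry = max(f, alpha * carry)
            out[i] = carry
        frac = out
    rows = cols = 64
    amp = 1000.0
    frames = np.full((n_frames, rows, cols), 10.0)
    frames += amp * frac[:, None, None]
    if cfg.epid_noise_sd > 0:
        frames += _rng(cfg, 1).normal(0.0, cfg.epid_noise_sd * amp, frames.shape)
    frames = np.clip(frames, 0.0, None)
    return FrameStack(
        frames=frames,
        frame_times=starts,
        pixel_spacing_cm=0.15,
        sid_cm=150.0,
        sad_cm=100.0,
    )


def simulate_dose_readings(
    n: int,
    cfg: SimulationConfig,
    nominal_cgy: float = 99.95,
    noise_sd_cgy: float = 0.10,
) -> list[float]:
    """Ion-chamber readings for a 100 MU delivery (~1 cGy/MU calibration).

    The delivered MU is identical with and without gating, so readings in
    both modes share the nominal value; only measurement noise differs.
    """
    if n < 1:
        raise ParameterError("need n >= 1 readings")
    rng = _rng(cfg, 2)
    return [float(v) for v in rng.normal(nominal_cgy, noise_sd_cgy, n)]


def make_fixture_set(
    cfg: SimulationConfig,
    out_dir: str | os.PathLike,
    session_id: str = "sim-session",
) -> dict[str, str]:
    """Write a complete simulated session to ``out_dir``.

    Produces the gating log (CSV dialect), the EPID raw stack
    (frames.npy + sidecar.json) and a ground-truth JSON holding the exact
    cycle/event times and latencies (consumed only by tests). Returns a
    manifest of the written paths.
    """
    out = Path(os.fspath(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    motion = simulate_motion(cfg)
    beam, truth = simulate_gated_beam(motion, cfg)
    record = GatingLogRecord(
        motion=motion,
        beam=beam,
        session_id=session_id,
        metadata={
            "session_id": session_id,
            "machine": "virtual-phantom",
            "planned_mu": "100.0",
            "gating_window": f"{cfg.gating_window[0]:.2f}-{cfg.gating_window[1]:.2f}",
        },
    )
    log_path = out / "gating_log.csv"
    write_gating_log(record, log_path)
    stack = simulate_epid_cine(truth, cfg)
    epid_dir = out / "epid"
    epid_manifest = write_raw_stack(stack, epid_dir)
    truth_path = out / "ground_truth.json"
    cfg_dict = asdict(cfg)
    cfg_dict["gating_window"] = list(cfg.gating_window)
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": cfg_dict,
                "t_peaks_s": truth.t_peaks.tolist(),
                "t25_s": truth.t25.tolist(),
                "t75_s": truth.t75.tolist(),
                "on_times_s": truth.on_times.tolist(),
                "off_times_s": truth.off_times.tolist(),
                "latency_on_s": truth.latency_on_s,
                "latency_off_s": truth.latency_off_s,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {
        "gating_log": str(log_path),
        "epid_dir": str(epid_dir),
        "epid_frames": epid_manifest["frames"],
        "epid_sidecar": epid_manifest["sidecar"],
        "ground_truth": str(truth_path),
    }
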