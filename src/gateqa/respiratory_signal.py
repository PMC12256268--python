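"""Respiratory-signal conditioning and cycle segmentation.

The anterior-posterior (AP) surrogate signal is min-max normalized, smoothed
with a centered moving mean, and divided into respiratory cycles anchored
peak-to-peak (0% phase = end-inhale peak, the usual 4D-CT phase convention;
the 25-75% window is then the end-exhale half-cycle used in phase gating).
Phase is linear in time within a cycle, so the planned window edges are
``t_start + 0.25 * period`` and ``t_start + 0.75 * period``.

Detected peak samples are refined to sub-sample precision with a local
parabolic fit, so phase times are not quantized to the log's sample clock.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError
from .gating_log_io import MotionTrace

__all__ = [
    "Signal1D",
    "RespiratoryCycle",
    "PhaseEvent",
    "AveragePeriodicSignal",
    "DegenerateSignalWarning",
    "extract_component",
    "minmax_normalize",
    "moving_mean_smooth",
    "estimate_period_samples",
    "segment_cycles",
    "phase_time",
    "average_periodic_signal",
]

logger = logging.getLogger(__name__)


class DegenerateSignalWarning(UserWarning):
    """Raised when a signal is constant and cannot be meaningfully normalized."""


@dataclass
class Signal1D:
    """A sampled 1-D signal: time in seconds, value in cm or normalized units."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ParameterError("Signal1D: t and v must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ParameterError("Signal1D: t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class RespiratoryCycle:
    """One peak-to-peak respiratory cycle."""

    index: int
    t_start: float
    t_end: float

    @property
    def period(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ParameterError(
                f"cycle {self.index}: t_start {self.t_start} >= t_end {self.t_end}"
            )


@dataclass(frozen=True)
class PhaseEvent:
    """The time at which a cycle reaches a given phase fraction."""

    cycle_index: int
    fraction: float
    time: float


@dataclass
class AveragePeriodicSignal:
    """Cycle-averaged waveform on a uniform phase grid (0..1)."""

    phase_grid: np.ndarray
    mean_v: np.ndarray
    sd_v: np.ndarray
    n_cycles: int


def extract_component(motion: MotionTrace, axis: str) -> Signal1D:
    """Pull one motion axis out of a trace, keeping the original time base."""
    if axis not in ("x", "y", "z"):
        raise ParameterError(f"unknown motion axis {axis!r}; expected x, y or z")
    return Signal1D(t=motion.t.copy(), v=getattr(motion, axis).copy())


def minmax_normalize(s: Signal1D) -> Signal1D:
    """Min-max normalize to [0, 1].

    ``v' = (v - min v) / (max v - min v)``; the output attains both 0 and 1.
    A constant signal is degenerate: all zeros are returned and a
    :class:`DegenerateSignalWarning` is emitted.
    """
    if len(s) < 2:
        raise ParameterError("minmax_normalize requires at least 2 samples")
    lo = float(np.min(s.v))
    hi = float(np.max(s.v))
    if hi == lo:
        warnings.warn(
            "constant signal: min-max normalization is degenerate, returning zeros",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return Signal1D(t=s.t.copy(), v=np.zeros_like(s.v))
    return Signal1D(t=s.t.copy(), v=(s.v - lo) / (hi - lo))


def moving_mean_smooth(s: Signal1D, window: int = 5) -> Signal1D:
    """Centered moving mean with shrinking windows at the ends.

    Endpoint windows truncate to the available samples, so output length
    equals input length (the behaviour of MATLAB's ``movmean``). ``window``
    must be an odd positive integer no longer than the signal.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd positive integer, got {window}")
    if window > len(s):
        raise ParameterError(
            f"window {window} exceeds signal length {len(s)}"
        )
    smoothed = (
        pd.Series(s.v).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return Signal1D(t=s.t.copy(), v=smoothed)


def estimate_period_samples(v: np.ndarray) -> int | None:
    """Coarse period estimate (in samples) from the autocorrelation maximum.

    Returns the positive lag of the largest local maximum of the (biased)
    autocorrelation, or None for signals with no periodic structure.
    """
    x = np.asarray(v, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        return None
    return int(peaks[np.argmax(ac[peaks])])


def _parabola_vertex(t: np.ndarray, v: np.ndarray, idx: int, half_width: int):
    """Vertex time of a local least-squares parabola around ``idx``.

    Returns (vertex_time, window_start_time, window_end_time), or None when
    the window is too short or the fit is not concave.
    """
    lo = max(idx - half_width, 0)
    hi = min(idx + half_width + 1, v.size)
    if hi - lo < 3:
        return None
    tt = t[lo:hi] - t[idx]
    a, b, _ = np.polyfit(tt, v[lo:hi], 2)
    if a >= 0:
        return None
    return float(t[idx] - b / (2 * a)), float(t[lo]), float(t[hi - 1])


def _refine_peak_time(t: np.ndarray, v: np.ndarray, idx: int, half_width: int) -> float:
    """Sub-sample peak time via the local parabola.

    Falls back to the sample time when the fit is not concave or the vertex
    leaves the fit window (both indicate the local shape is not peak-like).
    """
    fit = _parabola_vertex(t, v, idx, half_width)
    if fit is None:
        return float(t[idx])
    vertex, w_lo, w_hi = fit
    if not (w_lo <= vertex <= w_hi):
        return float(t[idx])
    return vertex


def _harmonic_anchor(t: np.ndarray, v: np.ndarray, idx: int,
                     period_s: float) -> float | None:
    """Peak time near sample ``idx`` from a single-harmonic least-squares fit.

    Fits ``a cos(wt) + b sin(wt) + c`` over one period around the candidate
    (clipped to the trace) and returns the fitted crest time closest to the
    candidate sample. Used for anchors near the trace edges, where a local
    parabola has no symmetric support; the harmonic fit averages over many
    samples and may legitimately place the crest just outside the trace
    (which the caller then rejects as a partial cycle). Returns None when
    the fit has no usable oscillatory component.
    """
    half = period_s / 2
    mask = (t >= t[idx] - half) & (t <= t[idx] + half)
    if int(mask.sum()) < 8:
        return None
    w = 2 * np.pi / period_s
    tt = t[mask]
    design = np.column_stack([np.cos(w * tt), np.sin(w * tt), np.ones(tt.size)])
    (a, b, _), *_ = np.linalg.lstsq(design, v[mask], rcond=None)
    amplitude = float(np.hypot(a, b))
    if amplitude < 0.05 * max(np.ptp(v), 1e-12):
        return None
    crest = float(np.arctan2(b, a) / w)
    return crest + round((t[idx] - crest) / period_s) * period_s


def segment_cycles(
    s: Signal1D,
    min_prominence: float = 0.2,
    min_separation_fraction: float = 0.4,
    anchor: str = "peak",
    refine: bool = True,
    refine_fraction: float = 0.12,
) -> list[RespiratoryCycle]:
    """Divide a normalized, smoothed signal into peak-to-peak cycles.

    A coarse period estimate from the autocorrelation maximum sets the
    minimum peak separation (``min_separation_fraction`` x estimate); peaks
    are then detected with the given prominence, optionally refined to
    sub-sample times, and successive peaks become cycle boundaries. Leading
    and trailing partial cycles are implicitly discarded. Fewer than two
    peaks yields an empty list (with a log diagnostic), never an exception.

    ``anchor="trough"`` segments valley-to-valley instead (the signal is
    negated for detection only).
    """
    if anchor not in ("peak", "trough"):
        raise ParameterError(f"anchor must be 'peak' or 'trough', got {anchor!r}")
    if not 0 < min_separation_fraction <= 1:
        raise ParameterError("min_separation_fraction must be in (0, 1]")
    v = s.v if anchor == "peak" else -s.v
    if np.ptp(v) == 0:
        logger.info("segment_cycles: constant signal, no cycles")
        return []
    period = estimate_period_samples(v)
    if period is None:
        logger.info("segment_cycles: no periodic structure detected")
        return []
    distance = max(1, int(round(min_separation_fraction * period)))
    # pad with a below-minimum sentinel so a peak lying exactly on the first
    # or last sample (common for phantom traces started at end-inhale) is
    # still detected; find_peaks ignores boundary extrema otherwise
    pad = v.min() - 1.0
    peaks, _ = find_peaks(np.r_[pad, v, pad], prominence=min_prominence,
                          distance=distance)
    peaks = peaks - 1
    half_width = max(2, int(round(refine_fraction * period)))
    dt = float(np.median(np.diff(s.t)))
    n = v.size
    interior = [int(i) for i in peaks
                if half_width <= i <= n - 1 - half_width]
    edge = [int(i) for i in peaks if i not in interior]
    if refine:
        interior_times = [_refine_peak_time(s.t, v, i, half_width)
                          for i in interior]
    else:
        interior_times = [float(s.t[i]) for i in interior]
    # the interior anchor spacing gives a precise period for the edge fits
    if len(interior_times) >= 2:
        period_s = float(np.median(np.diff(interior_times)))
    else:
        period_s = period * dt
    times = list(interior_times)
    for i in edge:
        # an extremum at the trace edge is a genuine whole-cycle anchor only
        # if the fitted crest lies inside the trace (half-sample slack); a
        # trace ending mid-rise places the crest beyond the edge and the
        # candidate is dropped as a partial cycle
        crest = _harmonic_anchor(s.t, v, i, period_s)
        if crest is None:
            continue
        if s.t[0] - dt / 2 <= crest <= s.t[-1] + dt / 2:
            times.append(crest)
    times = np.sort(np.asarray(times))
    if times.size < 2:
        logger.info(
            "segment_cycles: %d usable peak(s), need >= 2 for a cycle", times.size
        )
        return []
    # anchors closer than the separation floor indicate an estimation
    # breakdown; fall back to the raw sample times of the detected peaks
    if np.any(np.diff(times) <= distance * dt / 2):
        times = s.t[peaks]
    return [
        RespiratoryCycle(index=i, t_start=float(times[i]), t_end=float(times[i + 1]))
        for i in range(times.size - 1)
    ]


def phase_time(cycle: RespiratoryCycle, fraction: float) -> PhaseEvent:
    """Time at which ``cycle`` reaches phase ``fraction`` (linear in time)."""
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"phase fraction must be in [0, 1], got {fraction}")
    return PhaseEvent(
        cycle_index=cycle.index,
        fraction=float(fraction),
        time=cycle.t_start + fraction * cycle.period,
    )


def average_periodic_signal(
    s: Signal1D,
    cycles: list[RespiratoryCycle],
    grid_points: int = 101,
) -> AveragePeriodicSignal:
    """Average the signal over cycles on a common phase grid.

    Each cycle is linearly resampled at ``grid_points`` uniformly spaced
    phase fractions; the per-grid-point mean and population SD across
    cycles form the average periodic signal.
    """
    if not cycles:
        raise ParameterError("average_periodic_signal requires at least one cycle")
    if grid_points < 2:
        raise ParameterError("grid_points must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_points)
    rows = np.empty((len(cycles), grid_points))
    for i, c in enumerate(cycles):
        rows[i] = np.interp(c.t_start + grid * c.period, s.t, s.v)
    return AveragePeriodicSignal(
        phase_grid=grid,
        mean_v=rows.mean(axis=0),
        sd_v=rows.std(axis=0, ddof=0),
        n_cycles=len(cycles),
    )
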