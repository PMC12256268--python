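"""Per-cycle synchronization metrics and session aggregation.

The quantity of interest is the latency between the gating system's planned
phase-window edges and the actual beam triggers: for each respiratory cycle
with window edges t25 and t75 (the 25% and 75% phase times) and a paired
beam interval [t_on, t_off],

    delta_on  = t_on  - t25      (positive: beam turned on late)
    delta_off = t_off - t75      (positive: beam turned off late)

so ``delta_on - delta_off == trigger_duration - window_duration`` holds as
an algebraic identity per record. Aggregates use the population SD
(divisor n) by default; rounding to 2 decimals, half away from zero, is
applied only at the reporting layer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import AggregateStats, aggregate_stats, round_half_away
from .errors import EmptyInputError, PairingError, ParameterError
from .respiratory_signal import RespiratoryCycle, phase_time
from .trigger_analysis import BeamInterval

__all__ = [
    "AggregateStats",
    "aggregate_stats",
    "round_half_away",
    "CycleSyncRecord",
    "PairingResult",
    "SessionResult",
    "DoseComparison",
    "pair_cycles_intervals",
    "build_session_result",
    "duration_comparison",
    "dose_comparison",
    "reproducibility_trend",
    "session_to_frame",
]


@dataclass(frozen=True)
class CycleSyncRecord:
    """Per-cycle timing comparison between phase window and beam interval."""

    cycle_index: int
    t25: float
    t75: float
    t_on: float
    t_off: float

    @property
    def delta_on(self) -> float:
        return self.t_on - self.t25

    @property
    def delta_off(self) -> float:
        return self.t_off - self.t75

    @property
    def window_duration(self) -> float:
        return self.t75 - self.t25

    @property
    def trigger_duration(self) -> float:
        return self.t_off - self.t_on

    def __post_init__(self):
        if not self.t75 > self.t25:
            raise ParameterError(
                f"cycle {self.cycle_index}: window duration must be positive"
            )
        if not self.t_off > self.t_on:
            raise ParameterError(
                f"cycle {self.cycle_index}: trigger duration must be positive"
            )
        for v in (self.t25, self.t75, self.t_on, self.t_off):
            if not np.isfinite(v):
                raise ParameterError("non-finite time in CycleSyncRecord")


@dataclass
class PairingResult:
    records: list[CycleSyncRecord]
    unmatched_cycles: list[int]
    unmatched_intervals: list[BeamInterval]


@dataclass
class SessionResult:
    """One session's per-cycle records and their aggregates."""

    session_id: str
    records: list[CycleSyncRecord]
    aggregates: dict[str, AggregateStats]
    duration_gap: float  # mean window_duration - mean trigger_duration
    unmatched_cycles: list[int] = field(default_factory=list)
    unmatched_intervals: list[BeamInterval] = field(default_factory=list)


@dataclass
class DoseComparison:
    """Ion-chamber doses with vs without gating (cGy)."""

    reference_doses: list[float]
    gated_doses: list[float]
    paired_diffs: list[float] | None
    reference_stats: AggregateStats
    gated_stats: AggregateStats
    diff_stats: AggregateStats | None


def pair_cycles_intervals(
    cycles: list[RespiratoryCycle],
    intervals: list[BeamInterval],
    window: tuple[float, float] = (0.25, 0.75),
) -> PairingResult:
    """Assign each complete beam interval to the cycle it overlaps most.

    The score is the overlap of [t_on, t_off] with the cycle's planned
    window [t25, t75]; assignment is one-to-one, greedy by overlap, with
    ties broken toward the earlier cycle (then the earlier interval).
    Unmatched cycles and intervals are reported, never silently dropped.
    Raises :class:`~gateqa.errors.PairingError` when nothing pairs.
    """
    if not cycles:
        raise ParameterError("pair_cycles_intervals requires at least one cycle")
    complete = [iv for iv in intervals if iv.complete]
    if not complete:
        raise ParameterError("pair_cycles_intervals requires a complete interval")
    lo, hi = window
    edges = [
        (phase_time(c, lo).time, phase_time(c, hi).time) for c in cycles
    ]
    candidates = []
    for ci, (t25, t75) in enumerate(edges):
        for ii, iv in enumerate(complete):
            overlap = min(iv.t_off, t75) - max(iv.t_on, t25)
            if overlap > 0:
                candidates.append((-overlap, ci, ii))
    candidates.sort()
    used_c: set[int] = set()
    used_i: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, ci, ii in candidates:
        if ci in used_c or ii in used_i:
            continue
        used_c.add(ci)
        used_i.add(ii)
        pairs.append((ci, ii))
    if not pairs:
        raise PairingError(
            f"no beam interval overlaps any planned window: "
            f"{len(cycles)} cycle(s), {len(complete)} complete interval(s); "
            f"first window [{edges[0][0]:.3f}, {edges[0][1]:.3f}] s, "
            f"first interval [{complete[0].t_on:.3f}, {complete[0].t_off:.3f}] s"
        )
    pairs.sort()
    records = [
        CycleSyncRecord(
            cycle_index=cycles[ci].index,
            t25=edges[ci][0],
            t75=edges[ci][1],
            t_on=complete[ii].t_on,
            t_off=complete[ii].t_off,
        )
        for ci, ii in pairs
    ]
    unmatched_cycles = [cycles[ci].index for ci in range(len(cycles))
                        if ci not in used_c]
    unmatched_intervals = [complete[ii] for ii in range(len(complete))
                           if ii not in used_i]
    return PairingResult(records, unmatched_cycles, unmatched_intervals)


_METRICS = ("delta_on", "delta_off", "window_duration", "trigger_duration")


def build_session_result(
    session_id: str,
    pairing: PairingResult,
    sd_mode: str = "population",
) -> SessionResult:
    """Aggregate a pairing result into a per-session summary."""
    if not pairing.records:
        raise EmptyInputError("session has no paired cycle records")
    aggregates = {
        m: aggregate_stats([getattr(r, m) for r in pairing.records], sd_mode=sd_mode)
        for m in _METRICS
    }
    return SessionResult(
        session_id=session_id,
        records=pairing.records,
        aggregates=aggregates,
        duration_gap=aggregates["window_duration"].mean
        - aggregates["trigger_duration"].mean,
        unmatched_cycles=pairing.unmatched_cycles,
        unmatched_intervals=pairing.unmatched_intervals,
    )


def duration_comparison(
    session: SessionResult, sd_mode: str = "population"
) -> tuple[float, AggregateStats]:
    """Planned-window vs trigger-on duration, per cycle and aggregated.

    Returns the session's duration gap (mean window minus mean trigger
    duration) and the aggregate of per-cycle gaps.
    """
    gaps = [r.window_duration - r.trigger_duration for r in session.records]
    return session.duration_gap, aggregate_stats(gaps, sd_mode=sd_mode)


def dose_comparison(
    reference: list[float],
    gated: list[float],
    paired: bool = True,
    sd_mode: str = "population",
) -> DoseComparison:
    """Compare gated vs non-gated ion-chamber readings (cGy).

    In paired mode per-index differences (gated - reference) are
    aggregated; in unpaired mode only the two arms are summarized.
    """
    ref = [float(v) for v in reference]
    gat = [float(v) for v in gated]
    if any(v <= 0 for v in ref + gat):
        raise ParameterError("dose readings must be positive (cGy)")
    diffs = None
    diff_stats = None
    if paired:
        if len(ref) != len(gat):
            raise ParameterError(
                f"paired dose comparison needs equal lengths "
                f"({len(ref)} reference vs {len(gat)} gated)"
            )
        diffs = [g - r for g, r in zip(gat, ref)]
        diff_stats = aggregate_stats(diffs, sd_mode=sd_mode)
    return DoseComparison(
        reference_doses=ref,
        gated_doses=gat,
        paired_diffs=diffs,
        reference_stats=aggregate_stats(ref, sd_mode=sd_mode),
        gated_stats=aggregate_stats(gat, sd_mode=sd_mode),
        diff_stats=diff_stats,
    )


def reproducibility_trend(
    sessions: list[SessionResult],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Multi-session trend table and the max drift of each metric's mean.

    Returns a DataFrame with one row per session (mean and SD of the four
    timing metrics, in session order) and a dict mapping each metric to the
    maximum absolute difference between any two session means.
    """
    if not sessions:
        raise ParameterError("reproducibility_trend requires at least one session")
    rows = []
    for s in sessions:
        row: dict[str, object] = {"session_id": s.session_id, "n_cycles": len(s.records)}
        for m in _METRICS:
            row[f"{m}_mean"] = s.aggregates[m].mean
            row[f"{m}_sd"] = s.aggregates[m].sd
        rows.append(row)
    table = pd.DataFrame(rows)
    drift = {
        m: float(table[f"{m}_mean"].max() - table[f"{m}_mean"].min())
        for m in _METRICS
    }
    return table, drift


def session_to_frame(session: SessionResult) -> pd.DataFrame:
    """Per-cycle records as a DataFrame (one row per cycle)."""
    return pd.DataFrame(
        {
            "cycle_index": [r.cycle_index for r in session.records],
            "t25_s": [r.t25 for r in session.records],
            "t75_s": [r.t75 for r in session.records],
            "t_on_s": [r.t_on for r in session.records],
            "t_off_s": [r.t_off for r in session.records],
            "delta_on_s": [r.delta_on for r in session.records],
            "delta_off_s": [r.delta_off for r in session.records],
            "window_duration_s": [r.window_duration for r in session.records],
            "trigger_duration_s": [r.trigger_duration for r in session.records],
        }
    )


def session_to_dict(session: SessionResult) -> dict:
    """JSON-serializable session summary (full precision)."""
    return {
        "session_id": session.session_id,
        "n_cycles": len(session.records),
        "records": session_to_frame(session).to_dict(orient="records"),
        "aggregates": {
            m: {
                "mean": st.mean,
                "sd": st.sd,
                "median": st.median,
                "n": st.n,
                "sd_mode": st.sd_mode,
            }
            for m, st in session.aggregates.items()
        },
        "duration_gap_s": session.duration_gap,
        "unmatched_cycles": list(session.unmatched_cycles),
        "unmatched_intervals": [
            {"t_on": iv.t_on, "t_off": iv.t_off, "complete": iv.complete}
            for iv in session.unmatched_intervals
        ],
    }


def write_session_json(session: SessionResult, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(session_to_dict(session), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
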