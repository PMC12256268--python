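"""Beam-on interval extraction from the trigger flag sequence.

A rising edge is the first sample where the flag transitions 0->1 and the
edge time is that sample's timestamp (falling edges analogously). This
sample-level convention has a reproducible, resolution-bounded bias of less
than one sample period. A trace that begins with the flag already high is
treated as an interval whose true rising edge was not observed (flagged,
and demotable to incomplete with ``strict_edges``); a trace that ends while
on yields a final incomplete interval excluded from duration statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import AggregateStats, aggregate_stats
from .errors import EmptyInputError
from .gating_log_io import BeamTriggerTrace

__all__ = ["BeamInterval", "detect_beam_intervals", "interval_duration_stats"]


@dataclass(frozen=True)
class BeamInterval:
    """One beam-on period delimited by a rising and a falling trigger edge."""

    t_on: float
    t_off: float | None
    complete: bool
    leading_edge_seen: bool = True

    @property
    def duration(self) -> float | None:
        if not self.complete or self.t_off is None:
            return None
        return self.t_off - self.t_on


def detect_beam_intervals(
    beam: BeamTriggerTrace, strict_edges: bool = False
) -> list[BeamInterval]:
    """Extract ordered beam-on intervals from a trigger trace.

    An all-off trace yields an empty list. With ``strict_edges=True`` an
    interval whose rising edge precedes the trace is marked incomplete
    rather than merely warned about.
    """
    on = beam.on.astype(np.int8)
    t = beam.t
    intervals: list[BeamInterval] = []
    if on.size == 0:
        return intervals
    diff = np.diff(on)
    rises = list(np.flatnonzero(diff == 1) + 1)
    falls = list(np.flatnonzero(diff == -1) + 1)
    starts_on = bool(on[0])
    if starts_on:
        rises.insert(0, 0)
        warnings.warn(
            "trace starts with beam on: leading rising edge not observed",
            UserWarning,
            stacklevel=2,
        )
    for k, r in enumerate(rises):
        leading_seen = not (starts_on and k == 0)
        fall_after = next((f for f in falls if f > r), None)
        if fall_after is None:
            intervals.append(
                BeamInterval(t_on=float(t[r]), t_off=None, complete=False,
                             leading_edge_seen=leading_seen)
            )
        else:
            complete = leading_seen or not strict_edges
            intervals.append(
                BeamInterval(t_on=float(t[r]), t_off=float(t[fall_after]),
                             complete=complete, leading_edge_seen=leading_seen)
            )
    return intervals


def interval_duration_stats(
    intervals: list[BeamInterval], sd_mode: str = "population"
) -> AggregateStats:
    """Aggregate the durations of the complete intervals.

    Raises :class:`~gateqa.errors.EmptyInputError` when no complete
    interval is present.
    """
    durations = [iv.duration for iv in intervals if iv.complete]
    if not durations:
        raise EmptyInputError("no complete beam intervals to aggregate")
    return aggregate_stats(durations, sd_mode=sd_mode)
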