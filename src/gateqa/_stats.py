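"""Shared aggregate statistics.

Lives in its own module so both :mod:`gateqa.trigger_analysis` and
:mod:`gateqa.sync_metrics` can use it without a circular import; the public
entry point is :func:`gateqa.sync_metrics.aggregate_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import EmptyInputError, ParameterError

__all__ = ["AggregateStats", "aggregate_stats", "round_half_away"]


@dataclass(frozen=True)
class AggregateStats:
    """Mean / SD / median / count of a list of measurements.

    ``sd`` is the population standard deviation (divisor ``n``) by default,
    matching the convention of per-cycle QA tables; ``sd_mode`` records which
    divisor was used.
    """

    mean: float
    sd: float
    median: float
    n: int
    sd_mode: str = "population"

    def rounded(self, ndigits: int = 2) -> "AggregateStats":
        """Reporting-layer copy rounded half away from zero."""
        return AggregateStats(
            mean=round_half_away(self.mean, ndigits),
            sd=round_half_away(self.sd, ndigits),
            median=round_half_away(self.median, ndigits),
            n=self.n,
            sd_mode=self.sd_mode,
        )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (0.025 -> 0.03, -0.025 -> -0.03).

    Python's built-in ``round`` is banker's rounding; QA tables conventionally
    round half away from zero, so we go through ``Decimal``.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_stats(values, sd_mode: str = "population") -> AggregateStats:
    """Mean, SD, median and count of ``values``.

    Parameters
    ----------
    values
        Sequence of finite numbers (seconds or cGy); must be non-empty.
        Missing entries must be removed by the caller before this call.
    sd_mode
        ``"population"`` (divisor n, the default) or ``"sample"`` (n-1).

    Raises
    ------
    EmptyInputError
        If ``values`` is empty.
    ParameterError
        If any value is non-finite or ``sd_mode`` is unknown.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("aggregate_stats requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("aggregate_stats received non-finite values")
    if sd_mode == "population":
        ddof = 0
    elif sd_mode == "sample":
        if arr.size < 2:
            raise ParameterError("sample SD requires at least two values")
        ddof = 1
    else:
        raise ParameterError(f"unknown sd_mode {sd_mode!r}")
    return AggregateStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=ddof)),
        median=float(np.median(arr)),
        n=int(arr.size),
        sd_mode=sd_mode,
    )
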