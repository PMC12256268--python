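"""Read, validate and write gating-session logs.

A gating log is one treatment session's record of the respiratory surrogate
(motion amplitudes on three orthogonal axes, z = anterior-posterior by
convention) and the beam on/off flag, sampled on a common clock. Vendor
offline-review exports are proprietary; this module defines a documented
plain-text CSV dialect that such exports map onto:

* UTF-8 CSV; metadata lines start with ``#`` as ``# key: value``;
* header row exactly ``time_s,amp_x_cm,amp_y_cm,amp_z_cm,beam_on``;
* ``beam_on`` is 0 or 1; times in seconds, amplitudes in cm.

Validation is strict at read time: non-monotone time axes and sampling gaps
beyond 10% of the nominal period are rejected, because downstream phase
times are computed by linear interpolation on the time axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import LogFormatError, LogValidationError

__all__ = [
    "HEADER",
    "MotionTrace",
    "BeamTriggerTrace",
    "GatingLogRecord",
    "read_gating_log",
    "write_gating_log",
]

HEADER = "time_s,amp_x_cm,amp_y_cm,amp_z_cm,beam_on"

#: tolerated deviation of any sample interval from the nominal period
UNIFORMITY_TOL = 0.1


@dataclass
class MotionTrace:
    """Time-stamped respiratory amplitudes on three orthogonal axes.

    ``t`` is strictly increasing and near-uniform: every interval must lie
    within ``UNIFORMITY_TOL`` x ``sample_period`` of ``sample_period``.
    Amplitudes are in cm; ``z`` is the anterior-posterior axis.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_period: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.t.size
        if n < 2:
            raise LogValidationError("motion trace needs at least 2 samples")
        for name in ("x", "y", "z"):
            if getattr(self, name).size != n:
                raise LogValidationError(
                    f"motion axis {name!r} length {getattr(self, name).size} != time length {n}"
                )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise LogValidationError(
                f"time axis not strictly increasing at sample {i + 1} "
                f"(t={self.t[i]:.6f} -> t={self.t[i + 1]:.6f})"
            )
        if self.sample_period <= 0:
            raise LogValidationError("sample_period must be positive")
        dev = np.abs(dt - self.sample_period)
        if np.max(dev) > UNIFORMITY_TOL * self.sample_period:
            i = int(np.argmax(dev))
            raise LogValidationError(
                f"non-uniform sampling at sample {i + 1}: interval "
                f"{dt[i]:.6f} s vs nominal {self.sample_period:.6f} s "
                f"(tolerance {UNIFORMITY_TOL:.0%})"
            )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BeamTriggerTrace:
    """Beam on/off flag sampled on the same clock as the motion trace."""

    t: np.ndarray
    on: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.on = np.asarray(self.on, dtype=bool)
        if self.on.size != self.t.size:
            raise LogValidationError(
                f"beam flag length {self.on.size} != time length {self.t.size}"
            )
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise LogValidationError("beam trace time axis not strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class GatingLogRecord:
    """One gating session: motion trace, beam trace, id and metadata."""

    motion: MotionTrace
    beam: BeamTriggerTrace
    session_id: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        m, b = self.motion, self.beam
        if b.t[-1] < m.t[0] or m.t[-1] < b.t[0]:
            raise LogValidationError(
                "motion and beam time ranges do not overlap"
            )


def read_gating_log(path: str | os.PathLike) -> GatingLogRecord:
    """Parse a gating log in the documented CSV dialect.

    Metadata lines (``# key: value``) become the record's metadata map;
    other ``#`` lines are ignored as comments. The first non-comment line
    must be the exact header. Malformed content raises
    :class:`~gateqa.errors.LogFormatError` naming the line (and column);
    a well-formed file that violates a data-model invariant raises
    :class:`~gateqa.errors.LogValidationError`.
    """
    path = os.fspath(path)
    metadata: dict[str, str] = {}
    t, x, y, z, on = [], [], [], [], []
    colnames = HEADER.split(",")
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in metadata:
                        raise LogFormatError(
                            f"{path}: line {lineno}: duplicate metadata key {key!r}"
                        )
                    metadata[key] = value.strip()
                continue
            if not header_seen:
                if line.strip() != HEADER:
                    raise LogFormatError(
                        f"{path}: line {lineno}: malformed header "
                        f"{line.strip()!r}; expected {HEADER!r}"
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 5:
                raise LogFormatError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            row = []
            for col, val in zip(colnames[:4], fields[:4]):
                try:
                    row.append(float(val))
                except ValueError:
                    raise LogFormatError(
                        f"{path}: line {lineno}, column {col!r}: "
                        f"cannot parse {val.strip()!r} as a number"
                    ) from None
            flag = fields[4].strip()
            if flag not in ("0", "1"):
                raise LogFormatError(
                    f"{path}: line {lineno}, column 'beam_on': "
                    f"expected 0 or 1, got {flag!r}"
                )
            t.append(row[0])
            x.append(row[1])
            y.append(row[2])
            z.append(row[3])
            on.append(flag == "1")
    if not header_seen:
        raise LogFormatError(f"{path}: missing header line {HEADER!r}")
    if len(t) < 2:
        raise LogValidationError(f"{path}: needs at least 2 data rows, got {len(t)}")
    ta = np.asarray(t)
    if np.any(np.diff(ta) <= 0):
        raise LogValidationError(f"{path}: time column not strictly increasing")
    sample_period = float(np.median(np.diff(ta)))
    motion = MotionTrace(t=ta, x=np.asarray(x), y=np.asarray(y), z=np.asarray(z),
                         sample_period=sample_period)
    beam = BeamTriggerTrace(t=ta.copy(), on=np.asarray(on))
    session_id = metadata.get(
        "session_id", os.path.splitext(os.path.basename(path))[0]
    )
    return GatingLogRecord(motion=motion, beam=beam, session_id=session_id,
                           metadata=metadata)


def write_gating_log(record: GatingLogRecord, path: str | os.PathLike) -> str:
    """Write ``record`` in the documented dialect (6 decimal places).

    Metadata is written in insertion order as ``# key: value`` lines before
    the header. Returns the path written. Writing then re-reading then
    writing again is byte-stable.
    """
    path = os.fspath(path)
    m, b = record.motion, record.beam
    lines = [f"# {k}: {v}" for k, v in record.metadata.items()]
    lines.append(HEADER)
    for i in range(len(m)):
        lines.append(
            f"{m.t[i]:.6f},{m.x[i]:.6f},{m.y[i]:.6f},{m.z[i]:.6f},{int(b.on[i])}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
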