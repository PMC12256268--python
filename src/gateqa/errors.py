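"""Exception hierarchy for the gating-QA pipeline.

All pipeline errors derive from :class:`GatingQAError` so callers can catch
one base class; format/validation errors additionally derive from
:class:`ValueError` for idiomatic use.
"""


class GatingQAError(Exception):
    """Base class for all gateqa errors."""


class LogFormatError(GatingQAError, ValueError):
    """A gating log file does not conform to the documented CSV dialect.

    The message names the offending line (and column, where applicable).
    """


class LogValidationError(GatingQAError, ValueError):
    """A parsed log violates a data-model invariant (monotonicity, sampling
    uniformity, length mismatch)."""


class ParameterError(GatingQAError, ValueError):
    """An operation was called with an out-of-contract parameter."""


class EmptyInputError(GatingQAError, ValueError):
    """A statistic was requested over an empty collection."""


class PairingError(GatingQAError, RuntimeError):
    """No respiratory cycle could be paired with any beam interval."""


class ConfigurationError(GatingQAError, ValueError):
    """Required configuration (e.g. frame timing for a raw EPID stack) is
    missing or inconsistent."""


class StageError(GatingQAError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
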