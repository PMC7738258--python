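"""Exception hierarchy.

All validation failures raise :class:`ValidationError` so callers can
distinguish bad input (exit code 1 in the CLI) from runtime faults.
"""


class ActisleepError(Exception):
    """Base class for all package errors."""


class ValidationError(ActisleepError, ValueError):
    """Input violates a documented contract (range, schema, monotonicity)."""


class GapError(ValidationError):
    """An intensity series read from disk is not epoch-contiguous.

    Attributes
    ----------
    gaps : list of (timestamp, timestamp)
        The missing spans, as (end of epoch before gap, start of epoch after).
    """

    def __init__(self, message, gaps):
        super().__init__(message)
        self.gaps = list(gaps)


class NoSleepError(ActisleepError):
    """No qualifying sustained sleep run was found inside a night window."""


class EmptyAggregateError(ValidationError):
    """Zero nights survived filtering; no aggregate can be formed."""


class InsufficientPairsError(ValidationError):
    """Fewer than two paired observations; the test statistic is undefined."""
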