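"""Exception hierarchy shared across the package.

All domain errors derive from :class:`HRVGuideError` so callers (and the
command-line layer) can distinguish validation problems (exit code 2) from
ordinary I/O failures (exit code 3).
"""


class HRVGuideError(Exception):
    """Base class for all errors raised by hrvguide."""


class ValidationError(HRVGuideError, ValueError):
    """Input violates a precondition or a domain invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested computation."""


class CorrectionImpossibleError(ValidationError):
    """Artifact correction cannot proceed (e.g. too few clean beats)."""


class CalibrationError(ValidationError):
    """A synthetic-data configuration is internally infeasible."""


class UndefinedStatisticError(HRVGuideError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. ln of rMSSD 0)."""
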