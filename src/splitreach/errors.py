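"""Exception hierarchy for splitreach.

All package errors derive from :class:`SplitreachError` so callers can catch
pipeline failures with a single except clause while still distinguishing
configuration problems from data problems.
"""


class SplitreachError(Exception):
    """Base class for all splitreach errors."""


class ConfigError(SplitreachError, ValueError):
    """A configuration object failed validation; the message names the field."""


class DataIntegrityError(SplitreachError, ValueError):
    """Trial table violates ordering/uniqueness preconditions."""


class SchemaError(SplitreachError, ValueError):
    """A CSV input is missing columns or contains malformed values."""


class NoMovementError(SplitreachError):
    """No trajectory sample ever exceeded the displacement threshold."""


class GeometryError(SplitreachError, ValueError):
    """Degenerate geometry (e.g. zero-length direct path)."""


class TransformError(SplitreachError, ValueError):
    """Log transform requested on a nonpositive value."""


class InsufficientDataError(SplitreachError, ValueError):
    """Too few observations for the requested statistic."""


class EstimationError(SplitreachError):
    """Reliability estimation impossible (e.g. < 3 eligible participants)."""


class UndefinedReliabilityError(SplitreachError, ZeroDivisionError):
    """True reliability undefined because tau^2 = sigma^2 = 0."""
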