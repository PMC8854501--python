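"""Exception hierarchy shared across the package."""


class TofcastError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TofcastError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(TofcastError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class SeriesTooShortError(TofcastError, ValueError):
    """A TOFR series is too short for the requested operation."""


class EmptySeriesError(TofcastError, ValueError):
    """A series contains no observed values."""


class InsufficientDataError(TofcastError, ValueError):
    """Not enough supervised patterns to train or window."""


class SchemaError(TofcastError, ValueError):
    """A cohort file violates the documented CSV schema."""


class ShapeError(TofcastError, ValueError):
    """An array argument has the wrong shape or length."""
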