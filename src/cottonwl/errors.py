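"""Exception hierarchy for cottonwl."""


class CottonwlError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CottonwlError):
    """A registry or table file violates the expected schema."""


class DomainError(CottonwlError, ValueError):
    """An argument is outside its physical or mathematical domain."""


class RankError(CottonwlError):
    """Too few distinct design points to identify the model."""


class InitializationError(CottonwlError):
    """No usable starting point for an iterative fit."""


class UndefinedRSquaredError(CottonwlError):
    """R-squared is undefined (zero variance in the response)."""


class ControlMeanError(CottonwlError):
    """The control (0-day) mean is missing or zero for a parameter."""


class CensoredResult(CottonwlError):
    """The requested quantity is censored (milestone not reached in window)."""
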