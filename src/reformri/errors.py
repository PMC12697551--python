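"""Exception hierarchy used across the package.

Errors that can legitimately occur mid-sweep (e.g. model fits failing in a
small calibration set) derive from :class:`FitError` so the experiment
harness can record them as failed trials instead of aborting.
"""


class ReformError(Exception):
    """Base class for all package errors."""


class SchemaError(ReformError):
    """A required column is missing or a configured level set is violated."""


class RowParseError(ReformError):
    """A data row holds an unparseable numeric value."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ExtrapolationError(ReformError):
    """Evaluation requested outside the supported covariate range."""


class DomainError(ReformError):
    """A distribution function was evaluated outside its valid domain."""


class ConfigError(ReformError):
    """Invalid configuration (unknown preset, infeasible sizes, bad option)."""


class FitError(ReformError):
    """A model fit failed; carries whatever diagnostic trace is available."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
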