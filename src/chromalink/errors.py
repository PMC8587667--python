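"""Exception types shared across the package.

All are ``ValueError`` subclasses so callers that do not care about the
distinction can catch one base class.
"""


class ChromalinkError(ValueError):
    """Base class for all chromalink-specific errors."""


class ParameterError(ChromalinkError):
    """An argument or configuration field is outside its valid domain."""


class FormatError(ChromalinkError):
    """An on-disk file violates the expected text format."""


class PreconditionError(ChromalinkError):
    """An operation was called on data that does not satisfy its preconditions."""


class DegenerateDataError(ChromalinkError):
    """Numerically degenerate input (e.g. a zero-variance trace) where a
    statistic is undefined."""
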