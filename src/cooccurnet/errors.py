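"""Exception hierarchy shared by all modules.

Every error raised on bad data or bad parameters derives from
:class:`CooccurError`, which the CLI maps to exit code 2. Usage errors
(unknown flags, missing arguments) are handled by the CLI layer itself
and map to exit code 1.
"""


class CooccurError(Exception):
    """Base class for all data/parameter errors raised by this package."""


class SchemaError(CooccurError):
    """An input file does not have the expected columns."""


class ParseError(CooccurError):
    """A row of an input file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IntegrityError(CooccurError):
    """Input violates an integrity constraint (e.g. duplicate subject)."""


class ParameterError(CooccurError):
    """A parameter is outside its valid domain."""


class UndefinedCoefficientError(CooccurError):
    """A correlation-style coefficient is undefined (zero variance)."""


class FitError(CooccurError):
    """Maximum-likelihood fitting failed to converge."""
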