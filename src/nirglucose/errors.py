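"""Exception hierarchy shared across the package.

Validation problems (bad configs, malformed files, schema breaches) raise
:class:`ValidationError` subclasses so the CLI can map them to exit code 1;
everything else propagates as an ordinary runtime failure (exit code 2).
"""


class NirGlucoseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NirGlucoseError):
    """Invalid user input: configuration, file contents, or schema."""


class ConfigurationError(ValidationError):
    """A configuration value is missing, unknown, or out of range."""


class ParseError(ValidationError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, path, line_number, message):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class SchemaError(ValidationError):
    """A table is missing required columns or violates a column invariant."""


class DegenerateIntervalError(NirGlucoseError):
    """An interval statistic is undefined (fewer than two members, or zero
    variance); callers fall back to the identity adjustment factor."""


class CoverageError(NirGlucoseError):
    """A record maps to a glucose interval the adjustment model does not
    cover."""
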