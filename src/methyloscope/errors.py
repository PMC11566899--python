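"""Exception hierarchy.

``ConfigError`` signals a bad parameter or missing input (CLI exit code 2);
``ValidationError``/``ParseError``/``DataError`` signal malformed or
contract-violating data (CLI exit code 3).
"""


class MethyloscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(MethyloscopeError):
    """Invalid configuration or parameter combination."""


class ValidationError(MethyloscopeError):
    """Data violates a documented invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DataError(MethyloscopeError):
    """Well-formed input that cannot be processed (e.g. degenerate model fit)."""
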