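"""Typed errors raised by validation and parsing.

Every malformed input raises one of these; silent fixes are limited to
empty-cell -> 0, which is logged by the reader.
"""


class UromicsError(Exception):
    """Base class for all package errors."""


class ValidationError(UromicsError, ValueError):
    """Input violates a structural invariant (duplicates, bad enums, ...)."""


class ParseError(UromicsError, ValueError):
    """File could not be parsed into a table (ragged rows, non-numeric cells)."""


class ParameterError(UromicsError, ValueError):
    """A tuning parameter is outside its legal range."""
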