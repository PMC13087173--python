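"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 1, I/O and schema problems to
exit code 2 (see :mod:`ecotox.io_cli`).
"""


class EcotoxError(Exception):
    """Base class for all package errors."""


class ValidationError(EcotoxError, ValueError):
    """A value violates a domain invariant (non-positive mass, bad enum, ...)."""


class ConfigurationError(EcotoxError, ValueError):
    """A reference-table or generator config is malformed (duplicate keys, ...)."""


class SchemaError(EcotoxError, ValueError):
    """An input table does not match the expected header/schema."""


class UndefinedRatioError(ValidationError):
    """A ratio with a zero denominator was requested (e.g. BCF with c_water=0)."""


class UndefinedCorrelationError(ValidationError):
    """Correlation requested on a zero-variance sample."""
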