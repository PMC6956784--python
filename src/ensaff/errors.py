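"""Exception hierarchy shared across the package."""


class EnsaffError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EnsaffError, ValueError):
    """A structure or file could not be parsed."""


class ValidationError(EnsaffError, ValueError):
    """An input violates a documented precondition."""


class SchemaError(ValidationError):
    """A table is missing required columns or has conflicting keys."""


class DegenerateInputError(ValidationError):
    """The input is structurally valid but degenerate (e.g. zero denominator)."""


class MissingValueError(ValidationError):
    """A required value is absent or non-finite in strict mode."""
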