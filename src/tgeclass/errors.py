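"""Exception hierarchy shared across the pipeline.

Validation and schema problems raise :class:`ValidationError` (CLI exit
code 2); file-format problems raise :class:`FormatError` (also treated as
validation); I/O failures propagate as :class:`OSError` (exit code 3).
"""


class TgeClassError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TgeClassError, ValueError):
    """Input violates a documented contract (bad value, bad coordinates)."""


class SchemaError(ValidationError):
    """A tabular input is missing mandatory columns."""


class FormatError(ValidationError):
    """A file does not conform to its declared format."""


class ContractError(TgeClassError, RuntimeError):
    """An operation was called outside its documented precondition."""
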