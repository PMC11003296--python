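"""Exception types shared across the package."""


class PhoskitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhoskitError):
    """A tabular input is missing required columns."""


class IntegrityError(PhoskitError):
    """Duplicate or mutually inconsistent records in an input table."""


class DomainError(PhoskitError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class EmptyDrawingError(PhoskitError):
    """A drawing mask has no foreground left (e.g. after spec cleaning)."""


class ReferencePulseError(PhoskitError):
    """A participant has no standard-pulse drawings to normalize against."""


class CollinearityError(PhoskitError):
    """A regression design matrix is rank deficient."""
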