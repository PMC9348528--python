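"""Exception and warning types shared across the package."""


class NanoreleaseError(Exception):
    """Base class for all package errors."""


class DomainError(NanoreleaseError, ValueError):
    """An argument lies outside the mathematical/physical domain of an operation."""


class ValidationError(NanoreleaseError, ValueError):
    """A domain object violates its invariants."""


class SchemaError(NanoreleaseError, ValueError):
    """A tabular file does not match the documented schema."""


class ParseError(NanoreleaseError, ValueError):
    """A row of a table could not be parsed."""


class FitError(NanoreleaseError, RuntimeError):
    """A least-squares or network fit failed or produced invalid parameters."""


class GenerationError(NanoreleaseError, RuntimeError):
    """Synthetic-data generation produced responses irreparably out of range."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the training hull."""


class DegenerateVariableWarning(UserWarning):
    """A constant variable was normalized to the interval midpoint."""
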