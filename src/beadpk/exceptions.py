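"""Exception hierarchy for beadpk.

All errors raised on purpose by this package derive from :class:`BeadPKError`
so callers can catch domain failures without masking programming errors.
"""


class BeadPKError(Exception):
    """Base class for all beadpk errors."""


class DomainError(BeadPKError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(BeadPKError, ValueError):
    """Too few usable (quantifiable) points for the requested computation."""


class SchemaError(BeadPKError, ValueError):
    """An input table does not match the documented column schema."""


class RowValidationError(BeadPKError, ValueError):
    """A data row violates an invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PairingError(BeadPKError, ValueError):
    """A subject lacks the matching phase needed for a paired computation."""
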