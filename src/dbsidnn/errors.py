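"""Exception hierarchy shared across the package.

Validation errors signal malformed or inconsistent *inputs*; format errors
signal files that cannot be interpreted; domain errors signal requests that
are mathematically undefined (e.g. an ROC curve with a single class).
"""


class DbsidnnError(Exception):
    """Base class for all package errors."""


class ValidationError(DbsidnnError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(DbsidnnError, ValueError):
    """A file on disk does not match its expected format."""


class DomainError(DbsidnnError, ValueError):
    """The requested quantity is undefined for this input."""


class NumericalError(DbsidnnError, RuntimeError):
    """A numerical routine failed in a way that cannot be recovered."""
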