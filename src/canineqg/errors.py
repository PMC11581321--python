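"""Exception hierarchy for the toolkit.

All errors derive from :class:`CanineqgError` so callers can catch the
package's failures with a single except clause; subclasses distinguish
configuration mistakes, file-format problems, data-integrity violations,
and numerical failures.
"""


class CanineqgError(Exception):
    """Base class for all package errors."""


class ConfigError(CanineqgError, ValueError):
    """Invalid or inconsistent configuration / argument values."""


class FormatError(CanineqgError, ValueError):
    """Malformed input file (wrong magic bytes, ragged line, bad allele...)."""


class IntegrityError(CanineqgError, ValueError):
    """Data violates a structural contract (cycle, unknown parent, dup id)."""


class QcError(CanineqgError, ValueError):
    """Quality control cannot proceed (empty panel, undefined test...)."""


class NumericalError(CanineqgError, ArithmeticError):
    """A numerical operation failed (singular blend, non-PSD matrix...)."""


class IdentifiabilityError(NumericalError):
    """Variance components not separable from the given relationship matrix."""
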