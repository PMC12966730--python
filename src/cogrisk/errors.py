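"""Exception hierarchy shared across the pipeline stages."""


class CogriskError(Exception):
    """Base class for all package errors."""


class ConfigError(CogriskError):
    """Invalid configuration (bad probability, unknown item, collision, ...)."""


class UnscorableError(CogriskError):
    """A participant has no observed items for a score, or the prorating
    denominator is not positive; a silent zero would bias score distributions."""


class DegenerateDistributionError(CogriskError):
    """Standardization requested on a constant (zero-variance) sample."""


class SeparationError(CogriskError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class DegenerateOutcomeError(CogriskError):
    """A binary outcome with only one observed class."""


class ConvergenceError(CogriskError):
    """Optimizer failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class DataError(CogriskError):
    """Structurally invalid input data (e.g. a follow-up visit without a
    baseline visit)."""
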