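"""Exception hierarchy for thermnorm.

All package errors derive from :class:`ThermnormError` so callers can catch
one base class at pipeline boundaries.
"""


class ThermnormError(Exception):
    """Base class for all thermnorm errors."""


class InvalidInputError(ThermnormError, ValueError):
    """A scalar input violates its preconditions (nonpositive count, bad level...)."""


class InvalidParameterError(ThermnormError, ValueError):
    """A reaction-norm parameter set violates its invariants (w <= 0, a <= 0...)."""


class SchemaError(ThermnormError, ValueError):
    """A tabular input does not match the assay-table schema."""


class InsufficientDataError(ThermnormError, ValueError):
    """Too few observations to support the requested fit."""


class NonConvergenceError(ThermnormError, RuntimeError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class RankDeficientError(ThermnormError, ValueError):
    """The linear-model design matrix is rank deficient; names the column."""


class UndefinedFitnessError(ThermnormError, ZeroDivisionError):
    """Relative fitness is undefined because the reference rate is <= 0."""
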