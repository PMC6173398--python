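"""Error types raised across the pipeline.

Every degenerate input the analyses can encounter maps to a named error;
nothing is silently imputed, dropped or returned half-converged.
"""


class TransmetaError(Exception):
    """Base class for all package errors."""


class SingularDesignError(TransmetaError, ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"singular design matrix; collinear columns: {self.columns}"
        )


class InsufficientDataError(TransmetaError, ValueError):
    """Fewer observations than parameters (plus one residual df)."""


class SeparationError(TransmetaError, RuntimeError):
    """Perfect or quasi-perfect separation in a logistic or Cox fit."""


class ConvergenceError(TransmetaError, RuntimeError):
    """Iterative fit exhausted its iteration budget without converging."""


class MonomorphicSNPError(TransmetaError, ValueError):
    """Genotype dosage has no variation in the analysis subset."""


class ZeroVarianceError(TransmetaError, ValueError):
    """Response (or another required column) is constant."""


class NoEventsError(TransmetaError, ValueError):
    """Survival data contain no events."""


class PartitionExplosionError(TransmetaError, ValueError):
    """Too many populations for exhaustive partition enumeration."""


class DegenerateBootstrapError(TransmetaError, RuntimeError):
    """More than the tolerated share of bootstrap resamples were singular."""


class CohortValidationError(TransmetaError, ValueError):
    """A cohort file violates the declared column invariants."""
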