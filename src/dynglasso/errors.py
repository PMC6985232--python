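"""Exception hierarchy for dynglasso."""

from __future__ import annotations


class DynGLassoError(Exception):
    """Base class for all dynglasso errors."""


class ShapeError(DynGLassoError, ValueError):
    """Inconsistent dimensions across inputs."""


class DegenerateInputError(DynGLassoError, ValueError):
    """Input that makes the requested computation ill-posed.

    Examples: a zero-variance column before standardization, a singular
    sample covariance matrix with no sparsity penalty to regularize it,
    or an all-true / all-false truth vector handed to a ROC sweep.
    """


class DomainError(DynGLassoError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class NumericalError(DynGLassoError, ArithmeticError):
    """Numerical failure (e.g. a covariance matrix that cannot be repaired)."""


class ConvergenceError(DynGLassoError, RuntimeError):
    """ADMM failed to reach the requested tolerances within ``max_iter``.

    Carries the last iterate and the final residuals so callers can inspect
    or restart from the partial solution.
    """

    def __init__(self, message, last_iterate=None, primal_residual=None,
                 dual_residual=None, n_iter=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.primal_residual = primal_residual
        self.dual_residual = dual_residual
        self.n_iter = n_iter


class GenerationError(DynGLassoError, RuntimeError):
    """Synthetic-data rejection loop exhausted without meeting its contract."""


class ImproperPriorError(DynGLassoError, ValueError):
    """Prior normalizing constant requested for a zero penalty weight."""
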