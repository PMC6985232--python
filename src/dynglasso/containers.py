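"""Core in-memory containers shared across the package.

The estimator never sees raw single-cell tables: its sufficient statistics
are the per-time-point standardized (correlation-scale) sample covariance
matrices together with the per-time sample sizes, held in
:class:`StandardizedCovarianceSequence`.  Estimates travel as
:class:`PrecisionSequence` objects, one symmetric positive-definite matrix
per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, ShapeError

__all__ = [
    "StandardizedCovarianceSequence",
    "PrecisionSequence",
    "Hyperparameters",
    "PenaltyMask",
    "SolverSettings",
]

_SYM_TOL_COV = 1e-10
_SYM_TOL_PREC = 1e-8


def _as_square(mat, what: str) -> np.ndarray:
    a = np.asarray(mat, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError(f"{what} must be a square matrix, got shape {a.shape}")
    return a


@dataclass
class StandardizedCovarianceSequence:
    """Per-time correlation-scale sample covariance matrices with sample sizes.

    Parameters
    ----------
    S : sequence of (p, p) arrays
        Standardized (unit-diagonal) sample covariance matrix per time point.
    n : sequence of int
        Number of samples behind each ``S[t]``.
    labels : sequence, optional
        Time labels (e.g. minutes after stimulation).
    names : sequence of str, optional
        Variable (marker) names, length ``p``.
    """

    S: Sequence[np.ndarray]
    n: Sequence[int]
    labels: Optional[Sequence] = None
    names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.S = [_as_square(s, "S[t]") for s in self.S]
        self.n = np.asarray(self.n, dtype=int)
        if len(self.S) < 1:
            raise ShapeError("need at least one time point")
        if len(self.S) != len(self.n):
            raise ShapeError(
                f"len(S)={len(self.S)} does not match len(n)={len(self.n)}")
        if np.any(self.n <= 0):
            raise DomainError("sample sizes must be positive")
        p = self.S[0].shape[0]
        for t, s in enumerate(self.S):
            if s.shape[0] != p:
                raise ShapeError(
                    f"S[{t}] has dimension {s.shape[0]}, expected {p}")
            if np.max(np.abs(s - s.T)) > _SYM_TOL_COV:
                raise DomainError(f"S[{t}] is not symmetric within {_SYM_TOL_COV}")
            if np.max(np.abs(np.diag(s) - 1.0)) > _SYM_TOL_COV:
                raise DomainError(f"S[{t}] does not have a unit diagonal")
            off = s[~np.eye(p, dtype=bool)]
            if off.size and np.max(np.abs(off)) > 1.0 + _SYM_TOL_COV:
                raise DomainError(
                    f"S[{t}] has off-diagonal entries outside [-1, 1]")
        if self.labels is not None and len(self.labels) != len(self.S):
            raise ShapeError("labels length does not match number of time points")
        if self.names is not None and len(self.names) != p:
            raise ShapeError("names length does not match dimension p")

    @property
    def T(self) -> int:
        return len(self.S)

    @property
    def p(self) -> int:
        return self.S[0].shape[0]

    def stacked(self) -> np.ndarray:
        """Return the matrices as one (T, p, p) array."""
        return np.stack(self.S)


@dataclass
class PrecisionSequence:
    """A sequence of symmetric positive-definite precision matrices."""

    theta: Sequence[np.ndarray]

    def __post_init__(self):
        self.theta = [_as_square(th, "theta[t]") for th in self.theta]
        if len(self.theta) < 1:
            raise ShapeError("need at least one time point")
        p = self.theta[0].shape[0]
        for t, th in enumerate(self.theta):
            if th.shape[0] != p:
                raise ShapeError(
                    f"theta[{t}] has dimension {th.shape[0]}, expected {p}")
            if np.max(np.abs(th - th.T)) > _SYM_TOL_PREC:
                raise DomainError(
                    f"theta[{t}] is not symmetric within {_SYM_TOL_PREC}")
            # smallest eigenvalue check; eigvalsh on the symmetrized matrix
            w = np.linalg.eigvalsh((th + th.T) / 2.0)
            if w[0] <= 0:
                raise DomainError(
                    f"theta[{t}] is not positive definite "
                    f"(smallest eigenvalue {w[0]:.3e})")

    @property
    def T(self) -> int:
        return len(self.theta)

    @property
    def p(self) -> int:
        return self.theta[0].shape[0]

    def stacked(self) -> np.ndarray:
        return np.stack(self.theta)

    def __iter__(self):
        return iter(self.theta)

    def __getitem__(self, t):
        return self.theta[t]


@dataclass(frozen=True)
class Hyperparameters:
    """Sparsity penalty ``lam`` (λ) and smoothing penalty ``rho`` (ρ)."""

    lam: float
    rho: float = 0.0

    def __post_init__(self):
        if self.lam < 0:
            raise DomainError(f"lam must be nonnegative, got {self.lam}")
        if self.rho < 0:
            raise DomainError(f"rho must be nonnegative, got {self.rho}")


@dataclass
class PenaltyMask:
    """Per-time boolean matrices marking entries exempt from the λ penalty.

    The diagonal is always exempt; the smoothing (ρ) penalty is never
    masked.  Used by the second stage of the two-stage refit, where edges
    selected in the first stage are re-estimated without sparsity shrinkage.
    """

    exempt: Sequence[np.ndarray]

    def __post_init__(self):
        mats = []
        for t, m in enumerate(self.exempt):
            a = np.asarray(m, dtype=bool)
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ShapeError(f"exempt[{t}] must be square, got {a.shape}")
            if not np.array_equal(a, a.T):
                raise DomainError(f"exempt[{t}] must be symmetric")
            a = a.copy()
            np.fill_diagonal(a, True)
            mats.append(a)
        p = mats[0].shape[0]
        for t, a in enumerate(mats):
            if a.shape[0] != p:
                raise ShapeError(f"exempt[{t}] dimension mismatch")
        self.exempt = mats

    @property
    def T(self) -> int:
        return len(self.exempt)

    @property
    def p(self) -> int:
        return self.exempt[0].shape[0]


@dataclass
class SolverSettings:
    """Knobs of the ADMM solver.

    ``tol_primal`` / ``tol_dual`` are relative residual tolerances,
    ``admm_penalty`` the initial augmented-Lagrangian weight (adapted by
    residual balancing unless ``adapt_penalty`` is off), and ``init`` an
    optional warm start for the consensus variable.
    """

    tol_primal: float = 1e-6
    tol_dual: float = 1e-6
    max_iter: int = 2000
    admm_penalty: float = 1.0
    init: Optional[PrecisionSequence] = None
    adapt_penalty: bool = True
    inner_tol: float = 1e-11
    inner_max_iter: int = 2000
    over_relax: float = 1.6

    def __post_init__(self):
        if self.tol_primal <= 0 or self.tol_dual <= 0:
            raise DomainError("tolerances must be positive")
        if self.max_iter < 1:
            raise DomainError("max_iter must be at least 1")
        if self.admm_penalty <= 0:
            raise DomainError("admm_penalty must be positive")
        if not (1.0 <= self.over_relax < 2.0):
            raise DomainError("over_relax must lie in [1, 2)")
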