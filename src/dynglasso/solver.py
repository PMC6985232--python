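"""Penalized log-likelihood and the ADMM solver for the joint program.

The estimator maximizes, over symmetric positive-definite matrices
Θ_1, …, Θ_T,

    Φ(Θ) = Σ_t (n_t/2) [log det Θ_t − Tr(S_t Θ_t)]
           − (λ/2) Σ_t ‖Θ_t‖₁ − (ρ/2) Σ_{t≥2} ‖Θ_t − Θ_{t−1}‖₁,

where ‖·‖₁ is the entrywise absolute sum over the full matrix.  The
problem is convex with a unique optimum.  λ controls within-time sparsity
and ρ penalizes changes between consecutive time points; the entrywise
L1 on the differences drives many entries to stay *identical* across
time, stabilizing the sequence of inferred networks.

The solver is a two-block ADMM: the likelihood block is separable over
time points and solved by the standard log-det proximal step (one
eigendecomposition per time point per iteration), while the penalty block
is the exact sparse+fused chain prox of :mod:`dynglasso._prox`.  The
returned matrices are the consensus copy, so penalized entries are
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._prox import FusedChainProx, soft_threshold
from .containers import (Hyperparameters, PenaltyMask, PrecisionSequence,
                         SolverSettings, StandardizedCovarianceSequence)
from .errors import ConvergenceError, DegenerateInputError, DomainError, ShapeError

__all__ = ["objective", "solve", "partial_correlations", "SolverInfo"]

#: entries with |partial correlation| above this are treated as edges
NONZERO_TOL = 1e-8

_MIN_EIG_ML = 1e-10


@dataclass
class SolverInfo:
    """Diagnostics of one ADMM run."""

    n_iter: int
    primal_residual: float
    dual_residual: float
    penalty: float
    converged: bool


def _l1_weights(T: int, p: int, mask: Optional[PenaltyMask],
                penalize_diagonal: bool) -> np.ndarray:
    """Per-entry λ weights as full (T, p, p) 0/1 arrays.

    The mask exempts off-diagonal entries only; the diagonal's treatment
    always follows ``penalize_diagonal``, so a refit with an empty edge
    selection coincides with the plain solve.
    """
    w = np.ones((T, p, p))
    idx = np.arange(p)
    if not penalize_diagonal:
        w[:, idx, idx] = 0.0
    if mask is not None:
        if mask.T != T or mask.p != p:
            raise ShapeError("penalty mask dimensions do not match covariance")
        off = ~np.eye(p, dtype=bool)
        for t in range(T):
            w[t][mask.exempt[t] & off] = 0.0
    return w


def objective(theta: PrecisionSequence,
              cov: StandardizedCovarianceSequence,
              hp: Hyperparameters,
              mask: Optional[PenaltyMask] = None,
              penalize_diagonal: bool = True) -> float:
    """Evaluate Φ(Θ) for a candidate precision sequence.

    Raises :class:`DomainError` if any Θ_t fails positive definiteness
    (the log-determinant is undefined there).
    """
    if theta.T != cov.T or theta.p != cov.p:
        raise ShapeError("theta dimensions do not match covariance sequence")
    T, p = cov.T, cov.p
    w = _l1_weights(T, p, mask, penalize_diagonal)
    total = 0.0
    for t in range(T):
        th = theta[t]
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0 or np.linalg.eigvalsh((th + th.T) / 2)[0] <= 0:
            raise DomainError(f"theta[{t}] is not positive definite")
        total += 0.5 * cov.n[t] * (logdet - float(np.sum(cov.S[t] * th)))
        total -= 0.5 * hp.lam * float(np.sum(w[t] * np.abs(th)))
        if t >= 1:
            total -= 0.5 * hp.rho * float(np.sum(np.abs(th - theta[t - 1])))
    return total


def partial_correlations(theta: PrecisionSequence) -> List[np.ndarray]:
    """Partial correlations r_t(i,j) = −Θ_t(i,j)/√(Θ_t(i,i)Θ_t(j,j)).

    The diagonal is set to 1; outputs are symmetric with entries in
    [−1, 1].
    """
    out = []
    for t, th in enumerate(theta):
        d = np.diag(th)
        if np.any(d <= 0):
            raise DomainError(
                f"theta[{t}] has a non-positive diagonal entry")
        scale = np.sqrt(d)
        r = -th / np.outer(scale, scale)
        np.fill_diagonal(r, 1.0)
        out.append(np.clip((r + r.T) / 2.0, -1.0, 1.0))
    return out


def _ml_estimate(cov: StandardizedCovarianceSequence) -> PrecisionSequence:
    theta = []
    for t, s in enumerate(cov.S):
        theta.append(np.linalg.inv(s))
    return PrecisionSequence([(th + th.T) / 2 for th in theta])


def _check_ml_exists(cov: StandardizedCovarianceSequence) -> None:
    for t, s in enumerate(cov.S):
        w = np.linalg.eigvalsh(s)
        if w[0] < _MIN_EIG_ML:
            raise DegenerateInputError(
                f"S[{t}] is (near-)singular (smallest eigenvalue "
                f"{w[0]:.3e}); with lam = 0 the maximum-likelihood "
                "estimate does not exist — use a positive sparsity penalty")


def solve(cov: StandardizedCovarianceSequence,
          hp: Hyperparameters,
          mask: Optional[PenaltyMask] = None,
          settings: Optional[SolverSettings] = None,
          penalize_diagonal: bool = True,
          return_info: bool = False,
          ):
    """Maximize Φ subject to Θ_t ≻ 0 and return the estimate.

    Entries exempted by ``mask`` are excluded from the λ term only; the
    smoothing term is never masked.  With ``lam == rho == 0`` the unique
    optimum is the maximum-likelihood estimate Θ_t = S_t⁻¹, returned
    directly (each S_t must then be invertible).

    With ``return_info=True`` a ``(PrecisionSequence, SolverInfo)`` tuple
    is returned.
    """
    settings = settings or SolverSettings()
    T, p = cov.T, cov.p
    if hp.lam == 0.0:
        _check_ml_exists(cov)
    if hp.lam == 0.0 and hp.rho == 0.0:
        est = _ml_estimate(cov)
        info = SolverInfo(0, 0.0, 0.0, settings.admm_penalty, True)
        return (est, info) if return_info else est

    iu = np.triu_indices(p)
    m = iu[0].size
    w_full = _l1_weights(T, p, mask, penalize_diagonal)
    mu_ch = 0.5 * hp.lam * np.stack([w_full[t][iu] for t in range(T)])

    beta = float(settings.admm_penalty)
    S = cov.stacked()
    n = cov.n.astype(float)

    if settings.init is not None:
        if settings.init.T != T or settings.init.p != p:
            raise ShapeError("warm-start dimensions do not match covariance")
        Z = settings.init.stacked().copy()
    else:
        Z = np.tile(np.eye(p), (T, 1, 1))
    U = np.zeros((T, p, p))
    Theta = Z.copy()

    prox = FusedChainProx(T, m, beta, 0.5 * hp.rho,
                          tol=settings.inner_tol,
                          max_iter=settings.inner_max_iter)

    sqrt_dim = np.sqrt(T * p * p)
    converged = False
    r_norm = d_norm = np.inf
    r_rel = 1.0
    for it in range(1, settings.max_iter + 1):
        # inexact inner solves far from convergence, exact near it
        inner_tol = min(1e-4, max(settings.inner_tol, 1e-3 * r_rel))
        # --- likelihood block: batched eigendecomposition update
        M = Z - U - (n[:, None, None] / (2.0 * beta)) * S
        M = (M + np.transpose(M, (0, 2, 1))) / 2.0
        d, Q = np.linalg.eigh(M)
        lam_eig = 0.5 * (d + np.sqrt(d * d + 2.0 * n[:, None] / beta))
        Theta = Q @ (lam_eig[:, :, None] * np.transpose(Q, (0, 2, 1)))
        Theta = (Theta + np.transpose(Theta, (0, 2, 1))) / 2.0

        # --- penalty block: exact sparse+fused chain prox
        # (with standard over-relaxation of the consensus step)
        alpha = settings.over_relax
        Theta_hat = alpha * Theta + (1.0 - alpha) * Z
        A = Theta_hat + U
        a_ch = A[:, iu[0], iu[1]]
        z_ch = prox(a_ch, mu_ch, tol=inner_tol)
        Z_old = Z
        Z = np.zeros_like(A)
        Z[:, iu[0], iu[1]] = z_ch
        Z[:, iu[1], iu[0]] = z_ch

        U = U + Theta_hat - Z

        r_norm = float(np.linalg.norm(Theta - Z))
        d_norm = beta * float(np.linalg.norm(Z - Z_old))
        scale_pri = max(np.linalg.norm(Theta), np.linalg.norm(Z), sqrt_dim)
        eps_pri = settings.tol_primal * scale_pri
        eps_dual = settings.tol_dual * max(
            beta * np.linalg.norm(U), sqrt_dim)
        r_rel = max(r_norm / scale_pri, d_norm / max(
            beta * np.linalg.norm(U), sqrt_dim))
        if r_norm <= eps_pri and d_norm <= eps_dual:
            converged = True
            break

        # residual balancing (Boyd et al. §3.4.1)
        if settings.adapt_penalty and it % 10 == 0 and it < settings.max_iter // 2:
            if r_norm > 10.0 * d_norm and beta < 1e6:
                beta *= 2.0
                U /= 2.0
                prox.set_penalty(beta)
            elif d_norm > 10.0 * r_norm and beta > 1e-6:
                beta /= 2.0
                U *= 2.0
                prox.set_penalty(beta)

    if not converged:
        raise ConvergenceError(
            f"ADMM did not converge in {settings.max_iter} iterations "
            f"(primal residual {r_norm:.3e}, dual residual {d_norm:.3e})",
            last_iterate=Z, primal_residual=r_norm, dual_residual=d_norm,
            n_iter=settings.max_iter)

    est = PrecisionSequence([Z[t] for t in range(T)])
    info = SolverInfo(it, r_norm, d_norm, beta, True)
    return (est, info) if return_info else est
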