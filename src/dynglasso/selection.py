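"""Model selection: critical penalty values, BIC score, grid search, refit.

Two closed-form critical values bound the useful hyperparameter region:
above λ* every off-diagonal entry of every estimate is zero (fully
disconnected graphs), and above ρ* the estimates are identical across
time.  The search is therefore restricted to (0, λ*] × (0, ρ*].  Within
that box a greedy log-grid search minimizes a BIC score derived from the
Laplace-prior (MAP) reading of the penalized likelihood:

    BIC(λ, ρ) = Σ_t −(n_t/2)[log det Θ̂_t − Tr(S_t Θ̂_t)]
                + Σ_t (k_t/2) log(n_t / 2π)
                + (λ/2) Σ_t ‖Θ̂_t‖₁ + (ρ/2) Σ_{t≥2} ‖Θ̂_t − Θ̂_{t−1}‖₁
                − c(λ, ρ, T, p),

with k_t the number of unique nonzero entries of Θ̂_t (upper triangle
including the diagonal) and c(λ, ρ, T, p) a data-independent constant
from the prior normalization; see :func:`prior_constant`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import (Hyperparameters, PenaltyMask, PrecisionSequence,
                         SolverSettings, StandardizedCovarianceSequence)
from .errors import (ConvergenceError, DomainError, DynGLassoError,
                     ImproperPriorError, ShapeError)
from .solver import NONZERO_TOL, partial_correlations, solve

__all__ = [
    "lambda_star", "rho_star", "prior_constant", "bic",
    "BICComponents", "ModelSelectionResult", "grid_search", "two_stage_refit",
]


def lambda_star(cov: StandardizedCovarianceSequence) -> float:
    """Critical sparsity penalty λ* = max_{t,i≠j} n_t |S_t(i,j)|.

    For any λ ≥ λ* (with ρ = 0) every estimated graph is totally
    disconnected.
    """
    if cov.p < 2:
        raise DomainError("lambda_star requires p >= 2")
    best = 0.0
    off = ~np.eye(cov.p, dtype=bool)
    for t in range(cov.T):
        best = max(best, cov.n[t] * float(np.max(np.abs(cov.S[t][off]))))
    return best


def rho_star(cov: StandardizedCovarianceSequence) -> float:
    """Critical smoothing penalty.

    ρ* = max_{t≥2} [ max(n_t, n_{t−1}) · max_{i≠j} |S_t(i,j) − S_{t−1}(i,j)| ],
    taken jointly over consecutive pairs.  For ρ ≥ ρ* the optimum is the
    same estimate at every time point.
    """
    if cov.T < 2:
        raise DomainError("rho_star requires at least two time points")
    off = ~np.eye(cov.p, dtype=bool)
    best = 0.0
    for t in range(1, cov.T):
        diff = float(np.max(np.abs((cov.S[t] - cov.S[t - 1])[off])))
        best = max(best, max(cov.n[t], cov.n[t - 1]) * diff)
    return best


def prior_constant(hp: Hyperparameters, T: int, p: int) -> float:
    """Log normalizing constant of the product-Laplace prior.

    Under an entrywise-independence approximation each of the
    m = p(p+1)/2 free entries carries a Laplace factor exp(−(λ/2)|x|)
    with normalizer 4/λ (and likewise ρ for the T−1 difference blocks):

        c(λ, ρ, T, p) = T·m·log(λ/4) + (T−1)·m·log(ρ/4).

    This closed form is deliberately isolated in this one function so an
    alternative construction can be swapped in.
    """
    if T < 1 or p < 2:
        raise DomainError("prior_constant requires T >= 1 and p >= 2")
    if hp.lam <= 0:
        raise ImproperPriorError(
            "prior normalizer undefined for lam = 0 (improper prior); "
            "search over strictly positive grids")
    if T >= 2 and hp.rho <= 0:
        raise ImproperPriorError(
            "prior normalizer undefined for rho = 0 with T >= 2")
    m = p * (p + 1) // 2
    c = T * m * math.log(hp.lam / 4.0)
    if T >= 2:
        c += (T - 1) * m * math.log(hp.rho / 4.0)
    return c


@dataclass
class BICComponents:
    """Additive pieces of the BIC score for one (λ, ρ) fit."""

    neg_loglik: float
    complexity: float
    l1_term: float
    fused_term: float
    prior_const: float
    total: float
    k: List[int]

    def to_dict(self) -> dict:
        return {
            "neg_loglik": self.neg_loglik, "complexity": self.complexity,
            "l1_term": self.l1_term, "fused_term": self.fused_term,
            "prior_const": self.prior_const, "total": self.total,
            "k": list(map(int, self.k)),
        }


def _count_unique_nonzero(th: np.ndarray) -> int:
    """Unique nonzero entries: upper triangle including the diagonal."""
    iu = np.triu_indices(th.shape[0])
    return int(np.count_nonzero(th[iu]))


def bic(theta_hat: PrecisionSequence,
        cov: StandardizedCovarianceSequence,
        hp: Hyperparameters) -> BICComponents:
    """Compute the BIC components at a fitted precision sequence.

    When λ (or ρ) is exactly zero, the corresponding prior-normalizer part
    of c(λ, ρ, T, p) is dropped — the flat-prior limit where the constant
    no longer depends on the data or the estimate.
    """
    if theta_hat.T != cov.T or theta_hat.p != cov.p:
        raise ShapeError("theta dimensions do not match covariance sequence")
    T, p = cov.T, cov.p
    m = p * (p + 1) // 2
    neg_loglik = 0.0
    complexity = 0.0
    l1 = 0.0
    fused = 0.0
    k = []
    for t in range(T):
        th = theta_hat[t]
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0:
            raise DomainError(f"theta[{t}] is not positive definite")
        neg_loglik += -0.5 * cov.n[t] * (logdet - float(np.sum(cov.S[t] * th)))
        k_t = _count_unique_nonzero(th)
        k.append(k_t)
        complexity += 0.5 * k_t * math.log(cov.n[t] / (2.0 * math.pi))
        l1 += 0.5 * hp.lam * float(np.sum(np.abs(th)))
        if t >= 1:
            fused += 0.5 * hp.rho * float(np.sum(np.abs(th - theta_hat[t - 1])))
    c = 0.0
    if hp.lam > 0:
        c += T * m * math.log(hp.lam / 4.0)
    if hp.rho > 0 and T >= 2:
        c += (T - 1) * m * math.log(hp.rho / 4.0)
    total = neg_loglik + complexity + l1 + fused - c
    return BICComponents(neg_loglik=neg_loglik, complexity=complexity,
                         l1_term=l1, fused_term=fused, prior_const=c,
                         total=total, k=k)


@dataclass
class GridPoint:
    lam: float
    rho: float
    components: BICComponents
    theta: Optional[PrecisionSequence] = None

    def to_dict(self) -> dict:
        return {"lam": self.lam, "rho": self.rho,
                "bic": self.components.to_dict()}


@dataclass
class ModelSelectionResult:
    """All evaluated grid points plus the BIC-minimizing model."""

    grid: List[GridPoint]
    selected: Hyperparameters
    theta_selected: PrecisionSequence
    lambda_star: float
    rho_star: float

    def to_dict(self) -> dict:
        return {
            "lambda_star": self.lambda_star,
            "rho_star": self.rho_star,
            "selected": {"lam": self.selected.lam, "rho": self.selected.rho},
            "grid": [g.to_dict() for g in self.grid],
        }

    def to_json(self, path=None, indent: int = 2):
        payload = json.dumps(self.to_dict(), indent=indent)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)
        return None


_GRID_EPS = 1e-3
# fallback penalty when a critical value degenerates to zero (e.g. S_t = I):
# any positive value then yields the same trivial estimate
_DEGENERATE_PENALTY = 1e-6


def _log_grid(lo: float, hi: float, k: int) -> np.ndarray:
    if hi <= 0:
        return np.array([_DEGENERATE_PENALTY])
    lo = max(lo, hi * 1e-12)
    return np.geomspace(lo, hi, k)


def grid_search(cov: StandardizedCovarianceSequence,
                n_lambda: int = 8,
                n_rho: int = 8,
                settings: Optional[SolverSettings] = None,
                penalize_diagonal: bool = True,
                store_estimates: bool = False,
                ) -> ModelSelectionResult:
    """Greedy BIC minimization over (0, λ*] × (0, ρ*].

    A log-spaced base grid over (ε·λ*, λ*] × (ε·ρ*, ρ*] (ε = 1e−3) is
    evaluated first, each solve warm-started from its grid neighbor; the
    ±1-cell window around the running minimum is then re-gridded at double
    resolution, repeating until the minimum is interior to its window or
    three refinement rounds have run.  Deterministic given the inputs.
    """
    if n_lambda < 2 or n_rho < 2:
        raise DomainError("n_lambda and n_rho must be at least 2")
    settings = settings or SolverSettings()
    lam_max = lambda_star(cov)
    rho_max = rho_star(cov) if cov.T >= 2 else 0.0
    lams = _log_grid(_GRID_EPS * lam_max, lam_max, n_lambda)
    rhos = _log_grid(_GRID_EPS * rho_max, rho_max, n_rho)

    evaluated: List[GridPoint] = []
    seen = set()
    failures: List[str] = []

    def _eval(lam: float, rho: float, warm: Optional[PrecisionSequence]
              ) -> Optional[GridPoint]:
        key = (round(math.log(max(lam, 1e-300)), 12),
               round(math.log(max(rho, 1e-300)), 12))
        if key in seen:
            return None
        seen.add(key)
        local = SolverSettings(
            tol_primal=settings.tol_primal, tol_dual=settings.tol_dual,
            max_iter=settings.max_iter, admm_penalty=settings.admm_penalty,
            init=warm, adapt_penalty=settings.adapt_penalty,
            inner_tol=settings.inner_tol,
            inner_max_iter=settings.inner_max_iter)
        try:
            th = solve(cov, Hyperparameters(lam, rho), settings=local,
                       penalize_diagonal=penalize_diagonal)
        except DynGLassoError as exc:  # keep searching; report in aggregate
            failures.append(f"(lam={lam:.4g}, rho={rho:.4g}): {exc}")
            return None
        comps = bic(th, cov, Hyperparameters(lam, rho))
        gp = GridPoint(lam, rho, comps, th if store_estimates else None)
        gp._theta_cache = th  # warm-start chain during the search
        evaluated.append(gp)
        return gp

    warm = None
    for lam in lams:
        for rho in rhos:
            gp = _eval(lam, rho, warm)
            if gp is not None:
                warm = gp._theta_cache

    if not evaluated:
        raise ConvergenceError(
            "every grid-point solve failed:\n" + "\n".join(failures))

    def _argmin() -> GridPoint:
        return min(evaluated, key=lambda g: g.components.total)

    lam_lo_bound, rho_lo_bound = lams[0], rhos[0]
    for _round in range(3):
        best = _argmin()
        lam_sorted = np.array(sorted({g.lam for g in evaluated}))
        rho_sorted = np.array(sorted({g.rho for g in evaluated}))
        li = int(np.searchsorted(lam_sorted, best.lam))
        ri = int(np.searchsorted(rho_sorted, best.rho))
        interior = (0 < li < len(lam_sorted) - 1
                    and 0 < ri < len(rho_sorted) - 1)
        lam_lo = lam_sorted[max(li - 1, 0)]
        lam_hi = min(lam_sorted[min(li + 1, len(lam_sorted) - 1)], lam_max)
        rho_lo = rho_sorted[max(ri - 1, 0)]
        rho_hi = min(rho_sorted[min(ri + 1, len(rho_sorted) - 1)],
                     max(rho_max, rho_sorted[-1]))
        new_lams = _log_grid(max(lam_lo, lam_lo_bound), lam_hi, 5)
        new_rhos = _log_grid(max(rho_lo, rho_lo_bound), rho_hi, 5)
        warm = best._theta_cache
        for lam in new_lams:
            for rho in new_rhos:
                gp = _eval(lam, rho, warm)
                if gp is not None:
                    warm = gp._theta_cache
        if interior:
            break

    best = _argmin()
    return ModelSelectionResult(
        grid=evaluated,
        selected=Hyperparameters(best.lam, best.rho),
        theta_selected=best._theta_cache,
        lambda_star=lam_max,
        rho_star=rho_max,
    )


def two_stage_refit(cov: StandardizedCovarianceSequence,
                    hp: Hyperparameters,
                    edge_threshold: float = 1e-3,
                    settings: Optional[SolverSettings] = None,
                    penalize_diagonal: bool = True,
                    threshold_on: str = "partial_correlation",
                    return_stage1: bool = False,
                    ):
    """De-biasing refit: select edges, then re-solve without shrinking them.

    Stage 1 solves at (λ, ρ) and marks entry (i, j) at time t as a selected
    edge when its |partial correlation| (or |precision entry| with
    ``threshold_on='precision'``) exceeds ``edge_threshold``.  Stage 2
    re-solves with those entries exempt from the λ penalty, keeping the
    smoothing parameter ρ unchanged, and returns the stage-2 estimate.
    """
    if edge_threshold <= 0:
        raise DomainError("edge_threshold must be positive")
    if threshold_on not in ("partial_correlation", "precision"):
        raise DomainError(
            "threshold_on must be 'partial_correlation' or 'precision'")
    settings = settings or SolverSettings()
    stage1 = solve(cov, hp, settings=settings,
                   penalize_diagonal=penalize_diagonal)
    exempt = []
    if threshold_on == "partial_correlation":
        scores = partial_correlations(stage1)
    else:
        scores = list(stage1)
    for t in range(cov.T):
        sel = np.abs(scores[t]) > edge_threshold
        np.fill_diagonal(sel, True)
        exempt.append(sel)
    mask = PenaltyMask(exempt)
    warm = SolverSettings(
        tol_primal=settings.tol_primal, tol_dual=settings.tol_dual,
        max_iter=settings.max_iter, admm_penalty=settings.admm_penalty,
        init=stage1, adapt_penalty=settings.adapt_penalty,
        inner_tol=settings.inner_tol, inner_max_iter=settings.inner_max_iter)
    stage2 = solve(cov, hp, mask=mask, settings=warm,
                   penalize_diagonal=penalize_diagonal)
    if return_stage1:
        return stage2, stage1, mask
    return stage2
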