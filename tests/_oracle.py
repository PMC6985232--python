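"""Independent reference computations used only by the tests.

The main piece is a generic convex-optimization oracle for the penalized
log-likelihood: it parametrizes the upper triangles of the precision
matrices, replaces each absolute value by the smooth surrogate
sqrt(x^2 + eps^2) - eps, and minimizes the negated objective with
L-BFGS-B under an eps continuation schedule.  The final point is scored
with the exact nonsmooth objective, giving an independent upper bound on
the optimum that a correct solver must match closely.  None of this
shares code with the package's ADMM path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["exact_objective", "oracle_objective", "mann_whitney_auroc"]


def _unpack(x, T, p, iu):
    thetas = np.zeros((T, p, p))
    m = iu[0].size
    for t in range(T):
        v = x[t * m:(t + 1) * m]
        thetas[t][iu] = v
        thetas[t][iu[1], iu[0]] = v
    return thetas


def exact_objective(thetas, S, n, lam, rho, penalize_diagonal=True):
    """Φ(Θ) computed directly from its definition (no package code)."""
    T, p = len(S), S[0].shape[0]
    total = 0.0
    for t in range(T):
        th = thetas[t]
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0:
            return -np.inf
        total += 0.5 * n[t] * (logdet - np.trace(S[t] @ th))
        pen = np.abs(th).sum()
        if not penalize_diagonal:
            pen -= np.abs(np.diag(th)).sum()
        total -= 0.5 * lam * pen
        if t:
            total -= 0.5 * rho * np.abs(th - thetas[t - 1]).sum()
    return total


def oracle_objective(S, n, lam, rho, penalize_diagonal=True,
                     eps_schedule=(1e-3, 1e-5, 1e-7)):
    """Optimal value of the program, via smoothed-L1 L-BFGS-B continuation."""
    S = [np.asarray(s, float) for s in S]
    T, p = len(S), S[0].shape[0]
    iu = np.triu_indices(p)
    m = iu[0].size
    # duplication weights: off-diagonal upper-tri entries appear twice in
    # the full-matrix norms and trace products
    dup = np.where(iu[0] == iu[1], 1.0, 2.0)
    lam_w = lam * dup * (1.0 if penalize_diagonal else
                         (iu[0] != iu[1]).astype(float))
    if not penalize_diagonal:
        lam_w = lam * dup * (iu[0] != iu[1])

    def negobj_and_grad(x, eps):
        thetas = _unpack(x, T, p, iu)
        val = 0.0
        grad = np.zeros_like(x)
        # positive-definiteness guard: push back toward the cone
        for t in range(T):
            w, V = np.linalg.eigh(thetas[t])
            if w[0] <= 1e-10:
                v = V[:, 0]
                pen_grad = -np.outer(v, v)
                g = pen_grad[iu] * dup
                out = np.zeros_like(x)
                out[t * m:(t + 1) * m] = 1e6 * g
                return 1e9 + 1e6 * (1e-10 - w[0]), out
        for t in range(T):
            th = thetas[t]
            inv = np.linalg.inv(th)
            _, logdet = np.linalg.slogdet(th)
            val -= 0.5 * n[t] * (logdet - np.trace(S[t] @ th))
            g_full = -0.5 * n[t] * (inv - S[t])
            grad[t * m:(t + 1) * m] += g_full[iu] * dup
            v = x[t * m:(t + 1) * m]
            sm = np.sqrt(v * v + eps * eps)
            val += 0.5 * np.sum(lam_w * (sm - eps))
            grad[t * m:(t + 1) * m] += 0.5 * lam_w * v / sm
            if t:
                d = v - x[(t - 1) * m:t * m]
                sm = np.sqrt(d * d + eps * eps)
                val += 0.5 * rho * np.sum(dup * (sm - eps))
                gd = 0.5 * rho * dup * d / sm
                grad[t * m:(t + 1) * m] += gd
                grad[(t - 1) * m:t * m] -= gd
        return val, grad

    x0 = np.zeros(T * m)
    eye = np.eye(p)[iu]
    for t in range(T):
        x0[t * m:(t + 1) * m] = eye
    for eps in eps_schedule:
        res = minimize(negobj_and_grad, x0, args=(eps,), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 20000, "maxfun": 50000,
                                "ftol": 1e-15, "gtol": 1e-10})
        x0 = res.x
    thetas = _unpack(x0, T, p, iu)
    return exact_objective(thetas, S, n, lam, rho,
                           penalize_diagonal=penalize_diagonal)


def mann_whitney_auroc(scores, truth):
    """AUROC via exhaustive pairwise comparison of true/false scores."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = 0.0
    for a in pos:
        wins += np.sum(a > neg) + 0.5 * np.sum(a == neg)
    return wins / (len(pos) * len(neg))
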