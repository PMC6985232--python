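"""Proximal operator of the sparse + fused penalty along a time chain.

The consensus (Z) update of the ADMM solves, independently for every
unique matrix entry, a one-dimensional fused-lasso problem along the
T time points:

    min_z  (beta/2) ||z - a||^2  +  sum_t mu_t |z_t|
                                 +  gamma * sum_{t>=2} |z_t - z_{t-1}|

with entry- and time-specific sparsity weights ``mu`` (zero for exempted
or unpenalized entries) and a single fusion weight ``gamma``.  With
``gamma == 0`` the solution is plain soft-thresholding.  Otherwise the
problem is solved by a small inner ADMM over the chain, vectorized
across all entries at once and warm-started between calls; the returned
solution is the soft-thresholded copy, so entries killed by the sparsity
weight are *exactly* zero (no post-hoc rounding).

The inner loop is compiled with numba when available; a pure-numpy
implementation of the identical iteration is used otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_threshold", "FusedChainProx"]


def soft_threshold(x: np.ndarray, thresh) -> np.ndarray:
    """Entrywise soft-thresholding; exact zeros for |x| <= thresh."""
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


def _inner_chain_admm(a, mu, Minv, beta, tau, gamma, s, w, us, uw,
                      tol, max_iter):
    """One warm-started inner ADMM run; mutates s, w, us, uw in place."""
    T, m = a.shape
    thresh_w = gamma / tau
    for it in range(max_iter):
        rhs = np.empty((T, m))
        for t in range(T):
            for k in range(m):
                v = beta * a[t, k] + tau * (s[t, k] - us[t, k])
                if t < T - 1:
                    v -= tau * (w[t, k] - uw[t, k])
                if t > 0:
                    v += tau * (w[t - 1, k] - uw[t - 1, k])
                rhs[t, k] = v
        z = Minv @ rhs
        check = (it % 4 == 3) or (it == max_iter - 1)
        r = 0.0
        d = 0.0
        for t in range(T):
            for k in range(m):
                x = z[t, k] + us[t, k]
                th = mu[t, k] / tau
                sv = 0.0
                if x > th:
                    sv = x - th
                elif x < -th:
                    sv = x + th
                if check:
                    dd = abs(sv - s[t, k])
                    if dd > d:
                        d = dd
                s[t, k] = sv
                us[t, k] = x - sv
                rr = abs(z[t, k] - sv)
                if check and rr > r:
                    r = rr
        for t in range(T - 1):
            for k in range(m):
                dz = z[t + 1, k] - z[t, k]
                x = dz + uw[t, k]
                wv = 0.0
                if x > thresh_w:
                    wv = x - thresh_w
                elif x < -thresh_w:
                    wv = x + thresh_w
                if check:
                    dd = abs(wv - w[t, k])
                    if dd > d:
                        d = dd
                w[t, k] = wv
                uw[t, k] = x - wv
                rr = abs(dz - wv)
                if check and rr > r:
                    r = rr
        if check and r < tol and tau * d < tol:
            break
    return it + 1


try:  # compiled fast path
    from numba import njit

    _inner_chain_admm = njit(cache=True, nogil=True)(_inner_chain_admm)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


class FusedChainProx:
    """Warm-started prox of the chain penalty, vectorized over entries.

    Parameters
    ----------
    T, m : int
        Chain length (time points) and number of independent chains
        (unique matrix entries).
    beta : float
        Quadratic weight of the prox (the outer ADMM penalty).
    gamma : float
        Fusion weight (rho / 2 in the outer problem).
    tol, max_iter : float, int
        Inner stopping rule: max-norm residuals below ``tol`` relative to
        max(1, |a|).  Callers may pass a looser per-call tolerance while
        the outer iteration is still far from convergence.
    """

    def __init__(self, T: int, m: int, beta: float, gamma: float,
                 tol: float = 1e-11, max_iter: int = 2000):
        self.T, self.m = T, m
        self.gamma = float(gamma)
        self.tol = tol
        self.max_iter = max_iter
        self._s = np.zeros((T, m))
        self._w = np.zeros((max(T - 1, 0), m))
        self._us = np.zeros((T, m))
        self._uw = np.zeros((max(T - 1, 0), m))
        self.tau = None
        self.set_penalty(beta)

    def set_penalty(self, beta: float) -> None:
        """Change the quadratic weight; rescales inner dual variables."""
        beta = float(beta)
        old_tau = self.tau
        self.beta = beta
        self.tau = beta  # inner penalty tied to the outer one
        if old_tau is not None and old_tau != self.tau:
            scale = old_tau / self.tau
            self._us *= scale
            self._uw *= scale
        if self.gamma > 0 and self.T > 1:
            T = self.T
            D = np.diff(np.eye(T), axis=0)
            M = (self.beta + self.tau) * np.eye(T) + self.tau * (D.T @ D)
            self._Minv = np.ascontiguousarray(np.linalg.inv(M))

    def __call__(self, a: np.ndarray, mu: np.ndarray,
                 tol: float | None = None) -> np.ndarray:
        """Return the prox at ``a`` (shape (T, m)) with weights ``mu``."""
        if self.gamma == 0.0 or self.T == 1:
            return soft_threshold(a, mu / self.beta)
        scale = max(1.0, float(np.abs(a).max())) if a.size else 1.0
        eff_tol = (tol if tol is not None else self.tol) * scale
        _inner_chain_admm(
            np.ascontiguousarray(a), np.ascontiguousarray(mu),
            self._Minv, self.beta, self.tau, self.gamma,
            self._s, self._w, self._us, self._uw,
            eff_tol, self.max_iter)
        return self._s.copy()
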