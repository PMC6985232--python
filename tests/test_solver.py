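import numpy as np
import pytest
from sklearn.covariance import graphical_lasso

from dynglasso import (ConvergenceError, DegenerateInputError, DomainError,
                       Hyperparameters, PenaltyMask, PrecisionSequence,
                       SolverSettings, StandardizedCovarianceSequence,
                       objective, partial_correlations, solve, standardize)
from dynglasso.solver import NONZERO_TOL

from _oracle import exact_objective, oracle_objective
from conftest import random_cov


# --------------------------------------------------------------- objective

def test_objective_identity_case():
    p, T = 4, 3
    cov = StandardizedCovarianceSequence([np.eye(p)] * T, [10, 20, 30])
    theta = PrecisionSequence([np.eye(p)] * T)
    val = objective(theta, cov, Hyperparameters(0.0, 0.0))
    assert val == pytest.approx(-(p / 2) * (10 + 20 + 30))


def test_single_time_point_ignores_rho(small_cov, rng):
    cov = random_cov(4, 1, seed=3)
    th = PrecisionSequence([np.linalg.inv(cov.S[0]) + 0.5 * np.eye(4)])
    v1 = objective(th, cov, Hyperparameters(1.0, 0.0))
    v2 = objective(th, cov, Hyperparameters(1.0, 99.0))
    assert v1 == v2


def test_objective_matches_brute_force(rng):
    cov = random_cov(4, 3, seed=11)
    base = [np.linalg.inv(s) for s in cov.S]
    theta = PrecisionSequence([b + 0.3 * np.eye(4) for b in base])
    lam, rho = 1.7, 0.9
    got = objective(theta, cov, Hyperparameters(lam, rho))
    want = exact_objective(theta.stacked(), cov.S, cov.n, lam, rho)
    assert got == pytest.approx(want, rel=1e-12)


def test_objective_rejects_indefinite_theta(small_cov):
    # bypass construction-time validation to exercise the domain check
    bad = object.__new__(PrecisionSequence)
    bad.theta = [np.eye(5), np.diag([1.0, 1.0, -0.5, 1.0, 1.0]), np.eye(5)]
    with pytest.raises(DomainError):
        objective(bad, small_cov, Hyperparameters(0.0, 0.0))


# -------------------------------------------------------------------- solve

def test_ml_reduction_at_zero_penalties():
    cov = random_cov(5, 3, n=100, seed=1)
    theta = solve(cov, Hyperparameters(0.0, 0.0))
    for t in range(3):
        assert np.allclose(theta[t], np.linalg.inv(cov.S[t]), atol=1e-10)


def test_admm_path_consistent_with_ml_limit(tight_settings):
    # a vanishing penalty must land next to the closed-form ML estimate
    cov = random_cov(4, 2, n=200, seed=5)
    theta = solve(cov, Hyperparameters(1e-6, 1e-6), settings=tight_settings)
    ml = solve(cov, Hyperparameters(0.0, 0.0))
    for t in range(2):
        assert np.allclose(theta[t], ml[t], atol=1e-4)


def test_singular_covariance_refused_without_sparsity():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((4, 8))  # n < p: singular correlation matrix
    cov = standardize([x])
    with pytest.raises(DegenerateInputError):
        solve(cov, Hyperparameters(0.0, 0.0))
    # a positive sparsity penalty regularizes the same problem
    theta = solve(cov, Hyperparameters(2.0, 0.0))
    assert np.linalg.eigvalsh(theta[0])[0] > 0


def test_lambda_star_disconnects_every_graph(tight_settings):
    from dynglasso import lambda_star

    for seed in range(4):
        cov = random_cov(6, 3, seed=seed)
        lam = lambda_star(cov)
        theta = solve(cov, Hyperparameters(lam, 0.0), settings=tight_settings)
        for th in theta:
            off = th - np.diag(np.diag(th))
            assert np.max(np.abs(off)) <= 1e-8


def test_rho_star_freezes_time_variation(tight_settings):
    from dynglasso import lambda_star, rho_star

    for seed in range(4):
        cov = random_cov(6, 3, seed=100 + seed)
        hp = Hyperparameters(0.3 * lambda_star(cov), rho_star(cov))
        theta = solve(cov, hp, settings=tight_settings)
        for t in range(1, 3):
            assert np.max(np.abs(theta[t] - theta[0])) <= 1e-5


def test_exact_zeros_not_rounding(small_cov):
    theta = solve(small_cov, Hyperparameters(20.0, 5.0))
    z = theta.stacked()
    off = z[:, ~np.eye(5, dtype=bool)]
    assert np.any(off == 0.0)  # bitwise zero, no epsilon rounding


def test_glasso_reduction_matches_independent_solvers(tight_settings):
    """rho = 0 must equal T independent per-time graphical lassos."""
    cov = random_cov(5, 3, n=120, seed=21)
    lam = 8.0
    joint = solve(cov, Hyperparameters(lam, 0.0), settings=tight_settings,
                  penalize_diagonal=False)
    for t in range(3):
        sub = StandardizedCovarianceSequence([cov.S[t]], [cov.n[t]])
        single = solve(sub, Hyperparameters(lam, 0.0),
                       settings=tight_settings, penalize_diagonal=False)
        assert np.allclose(joint[t], single[0], atol=1e-5)
        # cross-check against scikit-learn's graphical lasso; its
        # coordinate descent plateaus around a 1e-4 entrywise accuracy
        with np.errstate(all="ignore"):
            _, prec = graphical_lasso(cov.S[t], alpha=lam / cov.n[t],
                                      tol=1e-10, max_iter=1000)
        assert np.allclose(joint[t], prec, atol=5e-4)


def test_objective_matches_convex_oracle(tight_settings):
    cov = random_cov(3, 2, n=50, seed=33)
    hp = Hyperparameters(1.0, 1.0)
    theta = solve(cov, hp, settings=tight_settings)
    ours = objective(theta, cov, hp)
    ref = oracle_objective(cov.S, cov.n, hp.lam, hp.rho)
    assert ours == pytest.approx(ref, rel=1e-4, abs=1e-6)


def test_objective_never_below_initialization(small_cov):
    hp = Hyperparameters(6.0, 2.0)
    init = PrecisionSequence([np.eye(5)] * 3)
    theta = solve(small_cov, hp, settings=SolverSettings(init=init))
    assert objective(theta, small_cov, hp) >= objective(init, small_cov, hp)


def test_permutation_equivariance(tight_settings):
    cov = random_cov(5, 2, seed=8)
    perm = np.array([3, 0, 4, 1, 2])
    cov_p = StandardizedCovarianceSequence(
        [s[np.ix_(perm, perm)] for s in cov.S], cov.n)
    hp = Hyperparameters(4.0, 2.0)
    a = solve(cov, hp, settings=tight_settings)
    b = solve(cov_p, hp, settings=tight_settings)
    for t in range(2):
        assert np.allclose(a[t][np.ix_(perm, perm)], b[t], atol=1e-6)


def test_convergence_error_carries_state(small_cov):
    with pytest.raises(ConvergenceError) as err:
        solve(small_cov, Hyperparameters(3.0, 1.0),
              settings=SolverSettings(max_iter=2, adapt_penalty=False))
    assert err.value.last_iterate is not None
    assert err.value.primal_residual > 0


def test_mask_exempts_lambda_only(tight_settings):
    # fully exempting every entry at rho=0 reproduces the ML estimate
    cov = random_cov(4, 2, n=150, seed=40)
    mask = PenaltyMask([np.ones((4, 4), bool)] * 2)
    theta = solve(cov, Hyperparameters(50.0, 0.0), mask=mask,
                  settings=tight_settings, penalize_diagonal=False)
    for t in range(2):
        assert np.allclose(theta[t], np.linalg.inv(cov.S[t]), atol=1e-5)


def test_warm_start_reaches_same_solution(small_cov, tight_settings):
    hp = Hyperparameters(10.0, 4.0)
    cold = solve(small_cov, hp, settings=tight_settings)
    other = solve(small_cov, Hyperparameters(12.0, 4.0),
                  settings=tight_settings)
    warm_settings = SolverSettings(tol_primal=1e-9, tol_dual=1e-9,
                                   max_iter=20000, init=other)
    warm = solve(small_cov, hp, settings=warm_settings)
    assert np.allclose(cold.stacked(), warm.stacked(), atol=1e-6)


# ------------------------------------------------------ partial correlations

def test_partial_correlation_direct_formula():
    th = PrecisionSequence([np.array([[1.0, -0.5], [-0.5, 1.0]])])
    r = partial_correlations(th)[0]
    assert r[0, 1] == pytest.approx(0.5)
    assert r[0, 0] == 1.0


def test_partial_correlation_diagonal_theta():
    th = PrecisionSequence([np.diag([1.0, 2.0, 3.0])])
    r = partial_correlations(th)[0]
    assert np.allclose(r - np.eye(3), 0.0)


def test_partial_correlation_matches_scaled_inverse(rng):
    a = rng.standard_normal((5, 5))
    th = PrecisionSequence([a @ a.T + 5 * np.eye(5)])
    r = partial_correlations(th)[0]
    m = th[0]
    for i in range(5):
        for j in range(5):
            want = 1.0 if i == j else -m[i, j] / np.sqrt(m[i, i] * m[j, j])
            assert r[i, j] == pytest.approx(want)
    assert np.max(np.abs(r)) <= 1.0
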