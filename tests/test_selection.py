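import math

import numpy as np
import pytest

from dynglasso import (DomainError, Hyperparameters, ImproperPriorError,
                       PrecisionSequence, SolverSettings,
                       StandardizedCovarianceSequence, bic, grid_search,
                       lambda_star, prior_constant, rho_star, solve,
                       two_stage_refit)
from dynglasso.solver import partial_correlations

from _oracle import exact_objective
from conftest import random_cov


# ------------------------------------------------------------ critical values

def test_lambda_star_direct_arithmetic():
    S = np.eye(3)
    S[0, 1] = S[1, 0] = 0.5
    cov = StandardizedCovarianceSequence([S], [10])
    assert lambda_star(cov) == pytest.approx(5.0)


def test_lambda_star_identity_covariance():
    cov = StandardizedCovarianceSequence([np.eye(4)] * 2, [10, 10])
    assert lambda_star(cov) == 0.0


def test_rho_star_direct_arithmetic():
    S1 = np.eye(3)
    S2 = np.eye(3)
    S2[0, 2] = S2[2, 0] = 0.3
    cov = StandardizedCovarianceSequence([S1, S2], [100, 100])
    assert rho_star(cov) == pytest.approx(30.0)


def test_rho_star_identical_matrices():
    S = np.eye(3)
    S[0, 1] = S[1, 0] = -0.4
    cov = StandardizedCovarianceSequence([S, S, S], [50, 60, 70])
    assert rho_star(cov) == 0.0


def test_rho_star_needs_two_time_points():
    cov = StandardizedCovarianceSequence([np.eye(3)], [10])
    with pytest.raises(DomainError):
        rho_star(cov)


@pytest.mark.parametrize("seed", range(5))
def test_critical_values_match_exhaustive_enumeration(seed):
    cov = random_cov(6, 3, seed=seed)
    lam_brute = max(
        cov.n[t] * abs(cov.S[t][i, j])
        for t in range(3) for i in range(6) for j in range(6) if i != j)
    assert lambda_star(cov) == pytest.approx(lam_brute, rel=1e-14)
    rho_brute = max(
        max(cov.n[t], cov.n[t - 1]) * abs(cov.S[t][i, j] - cov.S[t - 1][i, j])
        for t in range(1, 3) for i in range(6) for j in range(6) if i != j)
    assert rho_star(cov) == pytest.approx(rho_brute, rel=1e-14)


# ------------------------------------------------------------- prior constant

def test_prior_constant_log_one_terms():
    assert prior_constant(Hyperparameters(4.0, 4.0), T=3, p=4) == 0.0


def test_prior_constant_single_time_ignores_rho():
    a = prior_constant(Hyperparameters(2.0, 1.0), T=1, p=4)
    b = prior_constant(Hyperparameters(2.0, 99.0), T=1, p=4)
    assert a == b == 1 * 10 * math.log(0.5)


def test_prior_constant_monotone_beyond_four():
    grid = np.linspace(4.5, 50, 12)
    vals = [prior_constant(Hyperparameters(v, 5.0), 3, 5) for v in grid]
    assert np.all(np.diff(vals) > 0)
    vals = [prior_constant(Hyperparameters(5.0, v), 3, 5) for v in grid]
    assert np.all(np.diff(vals) > 0)


def test_prior_constant_improper_cases():
    with pytest.raises(ImproperPriorError):
        prior_constant(Hyperparameters(0.0, 1.0), 2, 4)
    with pytest.raises(ImproperPriorError):
        prior_constant(Hyperparameters(1.0, 0.0), 2, 4)
    # rho = 0 is fine when there is no difference term
    prior_constant(Hyperparameters(1.0, 0.0), 1, 4)


# ----------------------------------------------------------------------- BIC

def test_bic_diagonal_estimate_counts_p_parameters():
    cov = StandardizedCovarianceSequence([np.eye(4)] * 2, [30, 40])
    theta = PrecisionSequence([np.diag([1.0, 2.0, 0.5, 1.5])] * 2)
    comps = bic(theta, cov, Hyperparameters(1.0, 1.0))
    assert comps.k == [4, 4]


def test_bic_zero_penalties_reduce_to_likelihood_terms():
    cov = random_cov(3, 2, seed=2)
    theta = solve(cov, Hyperparameters(0.0, 0.0))
    comps = bic(theta, cov, Hyperparameters(0.0, 0.0))
    assert comps.l1_term == 0.0
    assert comps.fused_term == 0.0
    assert comps.prior_const == 0.0
    assert comps.total == pytest.approx(comps.neg_loglik + comps.complexity)


def test_bic_matches_term_by_term_recomputation():
    cov = random_cov(3, 2, n=70, seed=9)
    hp = Hyperparameters(3.0, 2.0)
    theta = solve(cov, hp)
    comps = bic(theta, cov, hp)
    # independent recomputation from the definition
    neg_loglik = 0.0
    complexity = 0.0
    l1 = fused = 0.0
    m = 3 * 4 // 2
    for t in range(2):
        th = theta[t]
        neg_loglik -= 0.5 * cov.n[t] * (
            np.linalg.slogdet(th)[1] - np.trace(cov.S[t] @ th))
        k_t = sum(1 for i in range(3) for j in range(i, 3) if th[i, j] != 0.0)
        complexity += 0.5 * k_t * math.log(cov.n[t] / (2 * math.pi))
        l1 += 0.5 * hp.lam * np.abs(th).sum()
        if t:
            fused += 0.5 * hp.rho * np.abs(th - theta[t - 1]).sum()
    c = 2 * m * math.log(hp.lam / 4) + 1 * m * math.log(hp.rho / 4)
    assert comps.total == pytest.approx(
        neg_loglik + complexity + l1 + fused - c, rel=1e-10)
    assert comps.total == pytest.approx(
        comps.neg_loglik + comps.complexity + comps.l1_term
        + comps.fused_term - comps.prior_const, rel=1e-12)


# ---------------------------------------------------------------- grid search

def test_grid_search_argmin_contract_and_determinism():
    cov = random_cov(4, 2, n=80, seed=14)
    res1 = grid_search(cov, n_lambda=4, n_rho=4)
    res2 = grid_search(cov, n_lambda=4, n_rho=4)
    totals = [g.components.total for g in res1.grid]
    assert min(totals) == res1.grid[
        int(np.argmin(totals))].components.total
    best = min(totals)
    sel = res1.selected
    assert 0 < sel.lam <= res1.lambda_star + 1e-12
    assert 0 < sel.rho <= max(res1.rho_star, 1e-5) + 1e-12
    for g, h in zip(res1.grid, res2.grid):
        assert (g.lam, g.rho) == (h.lam, h.rho)
        assert g.components.total == h.components.total
    assert all(best <= t for t in totals)


def test_grid_search_identity_covariance_selects_empty_graph():
    cov = StandardizedCovarianceSequence([np.eye(4)] * 2, [50, 50])
    res = grid_search(cov, n_lambda=3, n_rho=3)
    theta = res.theta_selected
    for th in theta:
        off = th - np.diag(np.diag(th))
        assert np.max(np.abs(off)) <= 1e-8


def test_grid_search_prefers_smoothing_for_constant_truth():
    # data resampled from one fixed structure: the selected rho should
    # sit in the upper half of its grid most of the time
    hits = 0
    for seed in range(10):
        cov = random_cov(5, 3, n=150, seed=300 + seed,
                         shared_structure=True)
        res = grid_search(cov, n_lambda=4, n_rho=4)
        rhos = sorted({g.rho for g in res.grid})
        upper = rhos[len(rhos) // 2]
        if res.selected.rho >= upper:
            hits += 1
    assert hits >= 7


# ------------------------------------------------------------- two-stage refit

def test_two_stage_noop_when_nothing_selected():
    cov = random_cov(4, 2, seed=17)
    hp = Hyperparameters(lambda_star(cov) * 1.01, 0.0)
    stage2, stage1, mask = two_stage_refit(cov, hp, return_stage1=True)
    assert np.allclose(stage2.stacked(), stage1.stacked(), atol=1e-7)


def test_two_stage_threshold_above_one_equals_plain_solve(tight_settings):
    cov = random_cov(4, 2, seed=18)
    hp = Hyperparameters(5.0, 2.0)
    refit = two_stage_refit(cov, hp, edge_threshold=1.5,
                            settings=tight_settings)
    plain = solve(cov, hp, settings=tight_settings)
    assert np.allclose(refit.stacked(), plain.stacked(), atol=1e-6)


def test_two_stage_support_superset_and_debiasing(tight_settings):
    cov = random_cov(5, 3, n=200, seed=19)
    hp = Hyperparameters(0.3 * lambda_star(cov), 0.3 * rho_star(cov))
    stage2, stage1, mask = two_stage_refit(
        cov, hp, edge_threshold=1e-3, settings=tight_settings,
        return_stage1=True)
    pc1 = partial_correlations(stage1)
    pc2 = partial_correlations(stage2)
    for t in range(3):
        sel = (np.abs(pc1[t]) > 1e-3) & ~np.eye(5, dtype=bool)
        # selected edges survive the refit...
        assert np.all(np.abs(pc2[t][sel]) > 1e-8)
        # ...and are not shrunk below their penalized stage-1 values
        assert np.all(np.abs(stage2[t][sel])
                      >= np.abs(stage1[t][sel]) - 1e-8)
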