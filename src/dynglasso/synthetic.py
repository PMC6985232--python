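"""Ground-truth generator for the in-silico benchmark.

The generator emulates the benchmark conditions of the method study: a
random weighted network over p = 30 nodes whose precision matrix
P₁ = (I − W)ᵀ(I − W) is sparse (75–80% zero off-diagonal entries), a
sequence of T = 6 precision matrices drifting slowly via small sparse
positive-semidefinite perturbations, and n_t = 1000 Gaussian samples per
time point with additive observation noise.  Edge weights are drawn
uniformly from (−1, −δ] ∪ [δ, 1) with δ = 0.2 so that no structural edge
is numerically weak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import PrecisionSequence
from .errors import DomainError, GenerationError

__all__ = [
    "SyntheticConfig", "SyntheticTruth",
    "generate_weighted_network", "precision_from_weights",
    "perturb_sequence", "sample_data", "generate_dataset",
    "write_dataset", "read_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the benchmark's: 30 nodes, six time points, 1000 samples
    per time point, off-diagonal sparsity kept within 75–80%, edge-weight
    floor δ = 0.2, small perturbations (max magnitude 0.05) between
    consecutive precision matrices, and additive Gaussian noise with
    standard deviation 0.1 on the (standardized-scale) observations.
    """

    p: int = 30
    T: int = 6
    n: Union[int, Sequence[int]] = 1000
    sparsity_range: Tuple[float, float] = (0.75, 0.80)
    delta: float = 0.2
    perturb_scale: float = 0.05
    noise_sd: float = 0.1
    seed: int = 0
    #: symmetric entry pairs newly added to the support per time step
    #: (before the sparsity budget is applied); ceil(0.02 p^2) by default
    n_new_pairs: Optional[int] = None

    def __post_init__(self):
        lo, hi = self.sparsity_range
        if not (0.0 < lo < hi < 1.0):
            raise DomainError("sparsity_range must satisfy 0 < low < high < 1")
        if not (0.0 < self.delta < 1.0):
            raise DomainError("delta must lie in (0, 1)")
        if self.perturb_scale < 0:
            raise DomainError("perturb_scale must be nonnegative")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")
        if self.p < 2 or self.T < 1:
            raise DomainError("need p >= 2 and T >= 1")

    @property
    def n_per_time(self) -> np.ndarray:
        n = self.n
        if np.isscalar(n):
            return np.full(self.T, int(n))
        arr = np.asarray(n, dtype=int)
        if arr.size != self.T:
            raise DomainError("n must be a scalar or length-T sequence")
        return arr

    @property
    def new_pairs_per_step(self) -> int:
        if self.n_new_pairs is not None:
            return int(self.n_new_pairs)
        return int(np.ceil(0.02 * self.p * self.p))


@dataclass
class SyntheticTruth:
    """Ground truth plus the sampled data for one synthetic dataset."""

    W: np.ndarray
    precisions: PrecisionSequence
    adjacency: List[np.ndarray]
    data: List[np.ndarray]
    config: SyntheticConfig


def _offdiag_zero_fraction(P: np.ndarray) -> float:
    p = P.shape[0]
    off = ~np.eye(p, dtype=bool)
    return float(np.mean(P[off] == 0.0))


def _draw_weights(rng: np.random.Generator, k: int, delta: float) -> np.ndarray:
    mag = rng.uniform(delta, 1.0, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    return sign * mag


def generate_weighted_network(config: SyntheticConfig,
                              rng: Optional[np.random.Generator] = None,
                              ) -> np.ndarray:
    """Random weighted directed adjacency matrix W.

    Edges are placed uniformly at random (Erdős–Rényi style, no
    self-loops) at a density tuned by a rejection loop so that the induced
    precision matrix (I − W)ᵀ(I − W) lands inside ``sparsity_range``; the
    loop targets the sparser (upper) part of the range to leave headroom
    for the perturbation steps.  Nonzero weights are uniform on
    (−1, −δ] ∪ [δ, 1).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = config.p
    lo, hi = config.sparsity_range
    # accept only in the upper (sparser) part of the range so that later
    # support growth cannot fall through the floor
    accept_lo = lo + 0.6 * (hi - lo)
    n_ordered = p * (p - 1)
    # the zero-fraction moves in steps of 2/n_ordered (symmetric support);
    # for small p the narrowed band may contain no reachable value
    if hi - accept_lo < 2.0 / n_ordered:
        accept_lo = lo
    target_nonzero = 1.0 - 0.5 * (accept_lo + hi)
    # initial guess: direct edges contribute ~2q of the off-diagonal
    # support of P1, common-parent fill-ins add more
    q = target_nonzero / 2.5
    achieved = None
    for _ in range(100):
        k = int(round(q * n_ordered))
        k = min(max(k, 1), n_ordered)
        idx = rng.choice(n_ordered, size=k, replace=False)
        rows, cols = np.divmod(idx, p - 1)
        cols = cols + (cols >= rows)  # skip the diagonal
        W = np.zeros((p, p))
        W[rows, cols] = _draw_weights(rng, k, config.delta)
        IW = np.eye(p) - W
        if abs(np.linalg.slogdet(IW)[0]) < 0.5:
            continue  # singular (I - W); redraw
        P1 = IW.T @ IW
        zf = _offdiag_zero_fraction(P1)
        achieved = zf
        if accept_lo <= zf <= hi:
            return W
        nz = 1.0 - zf
        if nz > 0:
            q *= target_nonzero / nz
            q = float(np.clip(q, 1.0 / n_ordered, 0.9))
    raise GenerationError(
        f"could not reach an off-diagonal zero-fraction in "
        f"[{accept_lo:.3f}, {hi:.3f}] within 100 tries "
        f"(last achieved {achieved})")


def precision_from_weights(W: np.ndarray) -> np.ndarray:
    """P₁ = (I − W)ᵀ(I − W): symmetric, PSD, and PD for nonsingular I − W."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise DomainError("W must be square")
    IW = np.eye(W.shape[0]) - W
    sign, _ = np.linalg.slogdet(IW)
    if sign == 0:
        raise GenerationError("I - W is singular; regenerate W")
    P = IW.T @ IW
    return (P + P.T) / 2.0


def _sparse_psd_perturbation(rng: np.random.Generator,
                             support: np.ndarray,
                             n_new: int,
                             scale: float) -> Tuple[np.ndarray, np.ndarray]:
    """Symmetric PSD matrix supported on ``support`` plus n_new new pairs.

    Off-diagonal entries are drawn on a random half of the existing
    support and on the new pairs; the diagonal is set to the absolute row
    sums (Gershgorin dominance) and everything is rescaled so the largest
    magnitude is ``scale``; a ridge (scale / 10)·I guarantees strict PD.
    Returns the perturbation and the set of new pairs used.
    """
    p = support.shape[0]
    iu = np.triu_indices(p, k=1)
    on_support = support[iu]
    candidates = np.flatnonzero(on_support)
    use = candidates[rng.random(candidates.size) < 0.5]
    free = np.flatnonzero(~on_support)
    new = (rng.choice(free, size=min(n_new, free.size), replace=False)
           if n_new > 0 and free.size else np.array([], dtype=int))
    A = np.zeros((p, p))
    chosen = np.concatenate([use, new])
    if chosen.size:
        vals = rng.uniform(-1.0, 1.0, size=chosen.size)
        A[iu[0][chosen], iu[1][chosen]] = vals
        A = A + A.T
    d = np.abs(A).sum(axis=1)
    np.fill_diagonal(A, d + 1e-3)
    top = np.max(np.abs(A))
    if top > 0 and scale > 0:
        A *= scale / top
    elif scale == 0:
        A[:] = 0.0
    A += (scale / 10.0 if scale > 0 else 0.0) * np.eye(p)
    return A, new


def perturb_sequence(P1: np.ndarray,
                     config: SyntheticConfig,
                     rng: Optional[np.random.Generator] = None,
                     ) -> PrecisionSequence:
    """Drift the precision matrix through T time points.

    P_t = P_{t−1} + D_t with D_t a small sparse symmetric PSD matrix
    supported on the existing support plus a few new entry pairs.  A
    rejection loop (halving the new-pair count on repeated failure) keeps
    the off-diagonal zero-fraction of every P_t inside
    ``config.sparsity_range``; with ``perturb_scale = 0`` only the ridge
    remains and the support is constant.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    P1 = np.asarray(P1, dtype=float)
    p = config.p
    lo, hi = config.sparsity_range
    zf1 = _offdiag_zero_fraction(P1)
    if not (lo <= zf1 <= hi):
        raise GenerationError(
            f"P1 off-diagonal zero-fraction {zf1:.3f} outside "
            f"[{lo}, {hi}]")
    n_off_pairs = p * (p - 1) // 2
    seq = [P1]
    remaining_budget = max(int(np.floor((zf1 - lo) * n_off_pairs)), 0)
    for t in range(1, config.T):
        steps_left = config.T - t
        cap = remaining_budget // steps_left if steps_left else 0
        n_new = min(config.new_pairs_per_step, cap)
        prev = seq[-1]
        support = prev != 0.0
        ok = False
        for attempt in range(100):
            if config.perturb_scale == 0.0:
                D = np.zeros((p, p))
                new = np.array([], dtype=int)
            else:
                D, new = _sparse_psd_perturbation(
                    rng, support, n_new, config.perturb_scale)
            Pt = prev + D
            zf = _offdiag_zero_fraction(Pt)
            if lo <= zf <= hi:
                seq.append(Pt)
                remaining_budget -= new.size
                ok = True
                break
            if attempt % 10 == 9 and n_new > 0:
                n_new //= 2
        if not ok:
            raise GenerationError(
                f"perturbation rejection loop exhausted at step {t} "
                f"(zero-fraction {zf:.3f} outside [{lo}, {hi}])")
    return PrecisionSequence(seq)


def sample_data(precisions: PrecisionSequence,
                config: SyntheticConfig,
                rng: Optional[np.random.Generator] = None,
                ) -> List[np.ndarray]:
    """Draw n_t samples from N(0, P_t⁻¹) per time point, plus sensor noise.

    Observation noise is i.i.d. N(0, noise_sd²) added to every entry.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_per_time = config.n_per_time
    data = []
    for t, P in enumerate(precisions):
        cov = np.linalg.inv(P)
        cov = (cov + cov.T) / 2.0
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((int(n_per_time[t]), P.shape[0]))
        x = z @ L.T
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(x.shape)
        data.append(x)
    return data


def generate_dataset(config: Optional[SyntheticConfig] = None,
                     seed: Optional[int] = None) -> SyntheticTruth:
    """Generate one full synthetic dataset (network, precisions, samples).

    All randomness flows through a single generator stream seeded by
    ``config.seed`` (or the ``seed`` override), drawn in the fixed order
    network → perturbations → samples, so results are reproducible.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    W = generate_weighted_network(config, rng)
    P1 = precision_from_weights(W)
    precisions = perturb_sequence(P1, config, rng)
    data = sample_data(precisions, config, rng)
    adjacency = []
    for P in precisions:
        adj = P != 0.0
        np.fill_diagonal(adj, False)
        adjacency.append(adj)
    return SyntheticTruth(W=W, precisions=precisions, adjacency=adjacency,
                          data=data, config=config)


def write_dataset(truth: SyntheticTruth, out_dir) -> List[Path]:
    """Write one delimited table per time point plus a truth edge list.

    Data files are ``data_t<t>.csv`` with a header of variable names;
    the truth file ``truth_edges.tsv`` holds (t, i, j, weight) rows with
    the precision-matrix entries of every true edge (i < j).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = truth.config.p
    names = [f"v{i}" for i in range(p)]
    written = []
    for t, x in enumerate(truth.data):
        path = out_dir / f"data_t{t}.csv"
        pd.DataFrame(x, columns=names).to_csv(path, index=False)
        written.append(path)
    rows = []
    for t, P in enumerate(truth.precisions):
        iu = np.triu_indices(p, k=1)
        nz = P[iu] != 0.0
        for i, j, w in zip(iu[0][nz], iu[1][nz], P[iu][nz]):
            rows.append((t, int(i), int(j), float(w)))
    truth_path = out_dir / "truth_edges.tsv"
    pd.DataFrame(rows, columns=["t", "i", "j", "weight"]).to_csv(
        truth_path, sep="\t", index=False)
    written.append(truth_path)
    return written


def read_dataset(data_paths: Sequence) -> List[np.ndarray]:
    """Read the per-time-point delimited tables back as matrices."""
    return [pd.read_csv(p).to_numpy(dtype=float) for p in data_paths]
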