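"""Model / Results interface over the functional layer.

`DynamicGraphicalLasso` is constructed from data (or directly from a
standardized covariance sequence) and fitted at fixed penalties, by BIC
grid search, or with the two-stage de-biasing refit.  The returned
`DynGLassoResults` carries the estimated precision sequence, partial
correlations, solver diagnostics, BIC components and a printable
summary, in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (Hyperparameters, PenaltyMask, PrecisionSequence,
                         SolverSettings, StandardizedCovarianceSequence)
from .covariance import standardize
from .errors import DomainError
from .selection import (ModelSelectionResult, bic, grid_search, lambda_star,
                        rho_star, two_stage_refit)
from .solver import (NONZERO_TOL, SolverInfo, objective,
                     partial_correlations, solve)

__all__ = ["DynamicGraphicalLasso", "DynGLassoResults"]


class DynamicGraphicalLasso:
    """Joint sparse precision-sequence estimator for time-course data.

    Parameters
    ----------
    cov : StandardizedCovarianceSequence
        The sufficient statistics: per-time correlation matrices and
        sample sizes.
    penalize_diagonal : bool
        Whether the diagonal enters the λ term of the objective.
    """

    def __init__(self, cov: StandardizedCovarianceSequence,
                 penalize_diagonal: bool = True):
        self.cov = cov
        self.penalize_diagonal = penalize_diagonal

    # ------------------------------------------------------------ builders
    @classmethod
    def from_data(cls, data_per_time: Sequence[np.ndarray],
                  labels=None, names=None,
                  penalize_diagonal: bool = True) -> "DynamicGraphicalLasso":
        """Standardize raw per-time data matrices and build the model."""
        cov = standardize(data_per_time, labels=labels, names=names)
        return cls(cov, penalize_diagonal=penalize_diagonal)

    @classmethod
    def from_dataframes(cls, frames: Sequence[pd.DataFrame],
                        labels=None,
                        penalize_diagonal: bool = True
                        ) -> "DynamicGraphicalLasso":
        """Build from per-time-point DataFrames sharing their columns."""
        names = list(frames[0].columns)
        for df in frames[1:]:
            if list(df.columns) != names:
                raise DomainError("data frames disagree on column names")
        mats = [df.to_numpy(dtype=float) for df in frames]
        return cls.from_data(mats, labels=labels, names=names,
                             penalize_diagonal=penalize_diagonal)

    # ---------------------------------------------------------- properties
    @property
    def T(self) -> int:
        return self.cov.T

    @property
    def p(self) -> int:
        return self.cov.p

    @property
    def lambda_star(self) -> float:
        """Penalty above which (at ρ = 0) all graphs are disconnected."""
        return lambda_star(self.cov)

    @property
    def rho_star(self) -> float:
        """Penalty above which the estimate is the same at all times."""
        return rho_star(self.cov)

    # --------------------------------------------------------------- fits
    def fit(self, lam: float, rho: float = 0.0,
            mask: Optional[PenaltyMask] = None,
            settings: Optional[SolverSettings] = None) -> "DynGLassoResults":
        """Solve at fixed (λ, ρ) and wrap the estimate in a results object."""
        hp = Hyperparameters(lam, rho)
        theta, info = solve(self.cov, hp, mask=mask, settings=settings,
                            penalize_diagonal=self.penalize_diagonal,
                            return_info=True)
        return DynGLassoResults(self, theta, hp, info, mask=mask)

    def fit_bic(self, n_lambda: int = 8, n_rho: int = 8,
                settings: Optional[SolverSettings] = None
                ) -> "DynGLassoResults":
        """Greedy BIC grid search; results carry the full grid report."""
        sel = grid_search(self.cov, n_lambda=n_lambda, n_rho=n_rho,
                          settings=settings,
                          penalize_diagonal=self.penalize_diagonal)
        res = DynGLassoResults(self, sel.theta_selected, sel.selected,
                               None, selection=sel)
        return res

    def fit_two_stage(self, lam: Optional[float] = None,
                      rho: Optional[float] = None,
                      edge_threshold: float = 1e-3,
                      n_lambda: int = 8, n_rho: int = 8,
                      settings: Optional[SolverSettings] = None
                      ) -> "DynGLassoResults":
        """Two-stage refit; (λ, ρ) from arguments or BIC when omitted."""
        selection = None
        if lam is None or rho is None:
            selection = grid_search(self.cov, n_lambda=n_lambda, n_rho=n_rho,
                                    settings=settings,
                                    penalize_diagonal=self.penalize_diagonal)
            hp = selection.selected
        else:
            hp = Hyperparameters(lam, rho)
        stage2, stage1, mask = two_stage_refit(
            self.cov, hp, edge_threshold=edge_threshold, settings=settings,
            penalize_diagonal=self.penalize_diagonal, return_stage1=True)
        res = DynGLassoResults(self, stage2, hp, None, mask=mask,
                               selection=selection)
        res.stage1 = DynGLassoResults(self, stage1, hp, None)
        return res


class DynGLassoResults:
    """Fitted precision sequence with diagnostics and reporting helpers."""

    def __init__(self, model: DynamicGraphicalLasso,
                 theta: PrecisionSequence,
                 hyperparameters: Hyperparameters,
                 info: Optional[SolverInfo] = None,
                 mask: Optional[PenaltyMask] = None,
                 selection: Optional[ModelSelectionResult] = None):
        self.model = model
        self.theta = theta
        self.hyperparameters = hyperparameters
        self.info = info
        self.mask = mask
        self.selection = selection
        self.stage1: Optional[DynGLassoResults] = None
        self._pc: Optional[List[np.ndarray]] = None

    # ------------------------------------------------------------ derived
    @property
    def partial_correlations(self) -> List[np.ndarray]:
        if self._pc is None:
            self._pc = partial_correlations(self.theta)
        return self._pc

    @property
    def objective(self) -> float:
        """Φ at the estimate (penalties per the model's diagonal setting)."""
        return objective(self.theta, self.model.cov, self.hyperparameters,
                         mask=self.mask,
                         penalize_diagonal=self.model.penalize_diagonal)

    def bic(self):
        """BIC components of this fit."""
        return bic(self.theta, self.model.cov, self.hyperparameters)

    @property
    def structural_variation(self) -> int:
        from .evaluation import structural_variation

        return structural_variation(self.theta)

    def edges(self, tol: float = NONZERO_TOL) -> pd.DataFrame:
        """Long-format edge table (time, i, j, names, partial correlation)."""
        cov = self.model.cov
        names = cov.names or [f"v{i}" for i in range(cov.p)]
        labels = cov.labels if cov.labels is not None else list(range(cov.T))
        iu = np.triu_indices(cov.p, k=1)
        rows = []
        for t in range(cov.T):
            r = self.partial_correlations[t]
            nz = np.abs(r[iu]) > tol
            for i, j in zip(iu[0][nz], iu[1][nz]):
                rows.append({
                    "time": labels[t], "i": int(i), "j": int(j),
                    "source": names[i], "target": names[j],
                    "partial_correlation": float(r[i, j]),
                })
        return pd.DataFrame(
            rows, columns=["time", "i", "j", "source", "target",
                           "partial_correlation"])

    # ---------------------------------------------------------- reporting
    def summary(self) -> str:
        cov = self.model.cov
        hp = self.hyperparameters
        lines = []
        lines.append("Dynamic Graphical Lasso Results")
        lines.append("=" * 46)
        lines.append(f"{'variables (p)':<28}{cov.p:>18}")
        lines.append(f"{'time points (T)':<28}{cov.T:>18}")
        lines.append(f"{'samples per time':<28}"
                     f"{', '.join(str(int(v)) for v in cov.n):>18}")
        lines.append(f"{'lambda (sparsity)':<28}{hp.lam:>18.6g}")
        lines.append(f"{'rho (smoothing)':<28}{hp.rho:>18.6g}")
        lines.append(f"{'lambda*':<28}{self.model.lambda_star:>18.6g}")
        if cov.T >= 2:
            lines.append(f"{'rho*':<28}{self.model.rho_star:>18.6g}")
        if self.info is not None:
            lines.append(f"{'ADMM iterations':<28}{self.info.n_iter:>18}")
            lines.append(f"{'primal residual':<28}"
                         f"{self.info.primal_residual:>18.3e}")
            lines.append(f"{'dual residual':<28}"
                         f"{self.info.dual_residual:>18.3e}")
        lines.append(f"{'objective':<28}{self.objective:>18.6g}")
        comps = self.bic()
        lines.append(f"{'BIC total':<28}{comps.total:>18.6g}")
        lines.append("-" * 46)
        iu = None
        for t in range(cov.T):
            r = self.partial_correlations[t]
            if iu is None:
                iu = np.triu_indices(cov.p, k=1)
            n_edges = int(np.sum(np.abs(r[iu]) > NONZERO_TOL))
            label = cov.labels[t] if cov.labels is not None else t
            lines.append(f"  t = {label!s:<10} edges: {n_edges}")
        if cov.T >= 2:
            lines.append(f"{'structural variation':<28}"
                         f"{self.structural_variation:>18}")
        return "\n".join(lines)

    def plot_partial_correlations(self, axes=None, cmap="RdBu_r"):
        """One heatmap of partial correlations per time point."""
        import matplotlib.pyplot as plt

        cov = self.model.cov
        if axes is None:
            _, axes = plt.subplots(1, cov.T,
                                   figsize=(3.2 * cov.T, 3.0), squeeze=False)
            axes = axes[0]
        for t, ax in zip(range(cov.T), np.atleast_1d(axes)):
            r = self.partial_correlations[t].copy()
            np.fill_diagonal(r, 0.0)
            im = ax.imshow(r, vmin=-1, vmax=1, cmap=cmap)
            label = cov.labels[t] if cov.labels is not None else t
            ax.set_title(f"t = {label}")
        plt.colorbar(im, ax=np.atleast_1d(axes).tolist(), shrink=0.8)
        return axes
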