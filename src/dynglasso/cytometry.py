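"""Reading time-course single-cell tables and exporting inferred networks.

The expected input is one delimited text table per time point (rows =
cells, columns = markers, shared header of marker names), e.g. gated and
debarcoded mass-cytometry exports for a 0/5/10/15/30/60-minute
stimulation time course.  FCS parsing, normalization and debarcoding are
upstream concerns.  An optional arcsinh(x / cofactor) transform (the
usual mass-cytometry variance stabilization, cofactor 5) can be applied
before covariance computation.

Outputs follow the time-resolved network reading of the fits: per-time
edge lists of partial correlations, a classification into *stable* edges
(present at every time point) versus *transient* edges (present at some
but not all), GraphML export of the union network, and a long-format
table of the strongest marker pairs across experimental conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .containers import Hyperparameters, SolverSettings
from .covariance import standardize
from .errors import DomainError, DynGLassoError, ShapeError
from .selection import grid_search, two_stage_refit
from .solver import NONZERO_TOL, partial_correlations

__all__ = [
    "TimeCourseTable", "NetworkExport",
    "load_timecourse", "networks_from_timecourse", "top_pairs_heatmap",
    "write_edge_lists", "read_edge_lists", "to_graphml",
]


@dataclass
class TimeCourseTable:
    """Per-time-point cells × markers matrices with shared marker names."""

    matrices: List[np.ndarray]
    markers: List[str]
    labels: List

    def __post_init__(self):
        p = len(self.markers)
        for t, x in enumerate(self.matrices):
            if x.ndim != 2 or x.shape[1] != p:
                raise ShapeError(
                    f"matrix {t} has shape {x.shape}, expected (*, {p})")
            if x.shape[0] < 2:
                raise ShapeError(f"time point {t} has fewer than 2 cells")

    @property
    def T(self) -> int:
        return len(self.matrices)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DynGLassoError(
                f"non-numeric cell in {path} at row {row + 2} "
                f"(1-based, incl. header), column {col!r}: "
                f"{df[col].iloc[row]!r}")
        df[col] = converted
    if df.isna().any().any():
        raise DynGLassoError(f"missing values in {path}")
    return df


def load_timecourse(paths: Sequence[Union[str, Path]],
                    transform: str = "none",
                    cofactor: float = 5.0,
                    labels: Optional[Sequence] = None) -> TimeCourseTable:
    """Parse one delimited table per time point into a time-course table.

    ``transform='arcsinh'`` applies entrywise arcsinh(x / cofactor).
    All files must share the same header of marker names, in order.
    """
    if transform not in ("none", "arcsinh"):
        raise DomainError("transform must be 'none' or 'arcsinh'")
    if cofactor <= 0:
        raise DomainError("cofactor must be positive")
    paths = [Path(p) for p in paths]
    frames = [_read_table(p) for p in paths]
    markers = list(frames[0].columns)
    for p, df in zip(paths[1:], frames[1:]):
        if list(df.columns) != markers:
            raise DynGLassoError(
                f"header of {p} does not match {paths[0]}: "
                f"{list(df.columns)} vs {markers}")
    mats = [df.to_numpy(dtype=float) for df in frames]
    if transform == "arcsinh":
        mats = [np.arcsinh(x / cofactor) for x in mats]
    if labels is None:
        labels = list(range(len(mats)))
    return TimeCourseTable(matrices=mats, markers=markers,
                           labels=list(labels))


@dataclass
class NetworkExport:
    """Per-time edge lists plus the stable/transient classification.

    ``edges`` is a long-format frame (time, i, j, source, target,
    partial_correlation); ``stable`` holds the (i, j) pairs present at
    all time points and ``transient`` those present at some but not all.
    ``pc`` keeps the full partial-correlation matrices for ranking and
    heatmaps.
    """

    edges: pd.DataFrame
    stable: set
    transient: set
    markers: List[str]
    labels: List
    pc: List[np.ndarray]
    hyperparameters: Optional[Hyperparameters] = None

    @property
    def T(self) -> int:
        return len(self.pc)


def networks_from_timecourse(table: TimeCourseTable,
                             selection="bic",
                             settings: Optional[SolverSettings] = None,
                             edge_threshold: float = 1e-3,
                             n_lambda: int = 8,
                             n_rho: int = 8,
                             penalize_diagonal: bool = True,
                             ) -> NetworkExport:
    """Standardize, select hyperparameters, refit, and extract networks.

    ``selection`` is either the string ``"bic"`` (greedy BIC grid search)
    or a :class:`Hyperparameters` / ``(lam, rho)`` pair for a fixed fit.
    The final estimate is the two-stage refit (de-biased edge strengths);
    edges are entries with |partial correlation| above the module-wide
    nonzero test, classified stable (all T time points) or transient.
    """
    settings = settings or SolverSettings()
    cov = standardize(table.matrices, labels=table.labels,
                      names=table.markers)
    if selection == "bic":
        sel = grid_search(cov, n_lambda=n_lambda, n_rho=n_rho,
                          settings=settings,
                          penalize_diagonal=penalize_diagonal)
        hp = sel.selected
    elif isinstance(selection, Hyperparameters):
        hp = selection
    else:
        lam, rho = selection
        hp = Hyperparameters(float(lam), float(rho))
    theta = two_stage_refit(cov, hp, edge_threshold=edge_threshold,
                            settings=settings,
                            penalize_diagonal=penalize_diagonal)
    pcs = partial_correlations(theta)
    rows = []
    presence = {}
    iu = np.triu_indices(cov.p, k=1)
    for t in range(cov.T):
        r = pcs[t]
        nz = np.abs(r[iu]) > NONZERO_TOL
        for i, j in zip(iu[0][nz], iu[1][nz]):
            pair = (int(i), int(j))
            presence.setdefault(pair, set()).add(t)
            rows.append({
                "time": table.labels[t], "i": int(i), "j": int(j),
                "source": table.markers[i], "target": table.markers[j],
                "partial_correlation": float(r[i, j]),
            })
    stable = {pr for pr, ts in presence.items() if len(ts) == cov.T}
    transient = {pr for pr, ts in presence.items() if 0 < len(ts) < cov.T}
    edges = pd.DataFrame(
        rows, columns=["time", "i", "j", "source", "target",
                       "partial_correlation"])
    return NetworkExport(edges=edges, stable=stable, transient=transient,
                         markers=table.markers, labels=table.labels,
                         pc=pcs, hyperparameters=hp)


def write_edge_lists(export: NetworkExport, path) -> Path:
    """Write the edge table as TSV with a stable/transient flag."""
    path = Path(path)
    df = export.edges.copy()
    df["stable_flag"] = [
        "stable" if (i, j) in export.stable else "transient"
        for i, j in zip(df["i"], df["j"])
    ]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_edge_lists(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def to_graphml(export: NetworkExport, path) -> Path:
    """Union network across time with per-time partial correlations."""
    g = nx.Graph()
    for name in export.markers:
        g.add_node(name)
    for (i, j) in sorted(export.stable | export.transient):
        attrs = {"stable": (i, j) in export.stable}
        for t, lab in enumerate(export.labels):
            attrs[f"pc_t{lab}"] = float(export.pc[t][i, j])
        g.add_edge(export.markers[i], export.markers[j], **attrs)
    path = Path(path)
    nx.write_graphml(g, path)
    return path


def top_pairs_heatmap(exports: Sequence[NetworkExport],
                      k: int = 20,
                      conditions: Optional[Sequence[str]] = None,
                      ) -> pd.DataFrame:
    """Union of the top-k strongest pairs per condition, long format.

    Pairs are ranked within each condition by the maximum |partial
    correlation| over time; the union of the per-condition top-k sets is
    reported as (condition, time, pair, partial_correlation) rows for
    every condition and time point.
    """
    if k < 1:
        raise DomainError("k must be at least 1")
    if not exports:
        raise DomainError("need at least one export")
    markers = exports[0].markers
    for e in exports[1:]:
        if e.markers != markers:
            raise ShapeError("exports disagree on marker names")
    if conditions is None:
        conditions = [f"condition_{c}" for c in range(len(exports))]
    p = len(markers)
    iu = np.triu_indices(p, k=1)
    n_pairs = iu[0].size
    if k > n_pairs:
        warnings.warn(
            f"k={k} exceeds the {n_pairs} available pairs; using all pairs")
        k = n_pairs
    union = set()
    for e in exports:
        strength = np.max(
            [np.abs(r[iu]) for r in e.pc], axis=0)
        order = np.argsort(-strength, kind="stable")[:k]
        union |= {(int(iu[0][q]), int(iu[1][q])) for q in order}
    rows = []
    for cond, e in zip(conditions, exports):
        for t, lab in enumerate(e.labels):
            for (i, j) in sorted(union):
                rows.append({
                    "condition": cond, "time": lab,
                    "pair": f"{markers[i]}--{markers[j]}",
                    "partial_correlation": float(e.pc[t][i, j]),
                })
    return pd.DataFrame(rows)
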