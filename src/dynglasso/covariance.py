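"""Standardization of per-time-point data matrices.

Sample covariance matrices are standardized to zero mean and unit variance
(i.e. reduced to correlation matrices) before estimation, so that the
penalization rates act on a common scale for all variables.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import StandardizedCovarianceSequence
from .errors import DegenerateInputError, ShapeError

__all__ = ["standardize"]


def standardize(data_per_time: Sequence[np.ndarray],
                labels: Optional[Sequence] = None,
                names: Optional[Sequence[str]] = None,
                ) -> StandardizedCovarianceSequence:
    """Build the standardized covariance sequence from raw data matrices.

    Each matrix holds ``n_t`` samples (rows) of ``p`` variables (columns).
    Columns are centered and scaled to unit variance, and the correlation
    matrix ``S_t = X'ᵀ X' / n_t`` of the standardized data is recorded
    together with the sample size.

    Raises
    ------
    DegenerateInputError
        If a column has zero variance (its correlations are undefined).
    ShapeError
        If the matrices disagree on the number of columns or a time point
        has fewer than two samples.
    """
    if len(data_per_time) < 1:
        raise ShapeError("need at least one data matrix")
    mats = [np.asarray(x, dtype=float) for x in data_per_time]
    p = None
    S, n = [], []
    for t, x in enumerate(mats):
        if x.ndim != 2:
            raise ShapeError(f"data[{t}] must be 2-dimensional, got {x.ndim}")
        n_t, p_t = x.shape
        if n_t < 2:
            raise ShapeError(f"data[{t}] needs at least 2 rows, got {n_t}")
        if p_t < 2:
            raise ShapeError(f"data[{t}] needs at least 2 columns, got {p_t}")
        if p is None:
            p = p_t
        elif p_t != p:
            raise ShapeError(
                f"data[{t}] has {p_t} columns but data[0] has {p}")
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population scaling; cancels in the ratio
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            col = bad[0]
            name = names[col] if names is not None else str(col)
            raise DegenerateInputError(
                f"column {name!r} (index {col}) has zero variance at time "
                f"point {t}; correlations are undefined")
        xs = (x - mu) / sd
        s = xs.T @ xs / n_t
        s = (s + s.T) / 2.0
        np.fill_diagonal(s, 1.0)
        S.append(np.clip(s, -1.0, 1.0))
        n.append(n_t)
    return StandardizedCovarianceSequence(S=S, n=n, labels=labels, names=names)
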