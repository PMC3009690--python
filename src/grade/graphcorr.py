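"""Cross-correlation and graph-delayed correlation estimators.

For a centered data matrix ``X`` (m experiments x l genes) the unbiased
cross-correlation estimate is ``C_X = X X^T / (l - 1)``.  Replacing ``X`` by
its graph-shifted copy gives the *graph-delayed correlation*

    C_X^G(tau) = X^G(tau) X^T / (l - 1) = X W^tau X^T / (l - 1),

whose off-diagonal entries capture network-lagged co-expression between
experiments.  Since regulatory networks are rarely symmetric, the
symmetrized form ``(C + C^T) / 2`` is used downstream: its eigendecomposition
is well defined and stabilizes estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_prior import WeightMatrix, g_shift

__all__ = [
    "DelayedCorrelation",
    "cross_correlation",
    "graph_delayed_correlation",
    "symmetrize",
    "assert_centered",
]

#: Row means must be below this multiple of the row standard deviation.
CENTERING_RTOL = 1e-8


@dataclass
class DelayedCorrelation:
    """An m x m (graph-)delayed correlation estimate at a given shift."""

    matrix: np.ndarray
    tau: int
    symmetrized: bool = False


def assert_centered(X: np.ndarray, auto_center: bool = False) -> np.ndarray:
    """Check that every row of ``X`` has (numerically) zero mean.

    Constant rows pass (their deviation is exactly zero after centering
    would be a no-op); otherwise the row mean must be below
    ``CENTERING_RTOL`` times the row standard deviation.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1)
    scale = np.where(sds > 0, sds, 1.0)
    bad = np.abs(means) > CENTERING_RTOL * scale
    if np.any(bad):
        if auto_center:
            return X - means[:, None]
        raise ValueError(
            f"rows {np.nonzero(bad)[0].tolist()} are not centered "
            "(pass auto_center=True or center first)"
        )
    return X


def cross_correlation(X: np.ndarray, auto_center: bool = False) -> np.ndarray:
    """Unbiased cross-correlation estimate ``X X^T / (l - 1)`` of centered rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least 2 columns (samples)")
    X = assert_centered(X, auto_center=auto_center)
    l = X.shape[1]
    return (X @ X.T) / (l - 1)


def graph_delayed_correlation(
    X: np.ndarray,
    W: WeightMatrix,
    tau: int,
    auto_center: bool = False,
) -> DelayedCorrelation:
    """Estimate ``C_X^G(tau) = X W^tau X^T / (l - 1)`` (unsymmetrized)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least 2 columns (samples)")
    X = assert_centered(X, auto_center=auto_center)
    l = X.shape[1]
    shifted = g_shift(X, W, tau)
    C = (shifted @ X.T) / (l - 1)
    return DelayedCorrelation(matrix=C, tau=tau, symmetrized=False)


def symmetrize(C: DelayedCorrelation | np.ndarray) -> DelayedCorrelation:
    """Symmetrized delayed correlation ``(C + C^T) / 2``.  Idempotent."""
    if isinstance(C, DelayedCorrelation):
        M, tau = C.matrix, C.tau
    else:
        M, tau = np.asarray(C, dtype=float), 0
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    return DelayedCorrelation(matrix=(M + M.T) / 2.0, tau=tau, symmetrized=True)
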