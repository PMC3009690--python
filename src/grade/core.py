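"""The graph-decorrelation (GraDe) factorization.

Model: the observed expression matrix ``X`` (m experiments x l genes) is a
noisy linear mixture ``X = A S + eps`` of n unobserved sources (rows of S,
gene-indexed expression programs) with mixing matrix ``A`` (per-experiment
activities).  The sources are assumed uncorrelated under the graph-delayed
correlation for a prior network G: ``C̄_S^G(tau)`` is diagonal.  After
whitening (which makes the sources' lag-0 correlation the identity and A
orthogonal), the factorization reduces to a single eigendecomposition of the
symmetric matrix ``C̄_Z^G(tau)``; with pairwise distinct eigenvalues A and S
are identified up to permutation and sign.

The procedure is second-order only and fully deterministic: center rows,
whiten (optionally reducing dimension and estimating the noise floor from
the discarded eigenvalues), eigendecompose the symmetrized graph-delayed
correlation of the whitened data, then map back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .graph_prior import GeneIndex, WeightMatrix
from .graphcorr import cross_correlation, graph_delayed_correlation, symmetrize

__all__ = [
    "WhiteningResult",
    "GradeResult",
    "center_rows",
    "whiten",
    "grade",
    "order_and_sign",
    "average_replicates",
]

#: Eigenvalues of C̄(0) below this multiple of the largest are null space.
RANK_RTOL = 1e-10
#: Relative eigenvalue gap below which identifiability is flagged.
TIE_RTOL = 1e-6


@dataclass
class WhiteningResult:
    """Whitening transform derived from the lag-0 correlation of the data.

    ``Z = whitening @ X`` has identity cross-correlation;
    ``dewhitening @ whitening`` is the identity on the retained subspace.
    """

    Z: np.ndarray
    whitening: np.ndarray
    dewhitening: np.ndarray
    eigenvalues: np.ndarray
    sigma2: float


@dataclass
class GradeResult:
    """Mixing matrix, sources and diagnostics of one GraDe run.

    Sources have unit variance under the ``1/(l-1)`` estimator and are
    ordered by decreasing absolute eigenvalue of the symmetrized
    graph-delayed correlation; each source's sign is fixed so that the
    largest-magnitude entry of its mixing column is positive.
    """

    A: np.ndarray
    S: np.ndarray
    eigenvalues: np.ndarray
    tau: int
    whitening: WhiteningResult
    row_means: np.ndarray
    gene_index: GeneIndex | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return self.S.shape[0]

    def reconstruction(self, add_means: bool = False) -> np.ndarray:
        """``A @ S`` (the centered model fit), optionally re-adding row means."""
        R = self.A @ self.S
        if add_means:
            R = R + self.row_means[:, None]
        return R


def center_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each row's mean; returns (centered matrix, row means)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite entries")
    means = X.mean(axis=1)
    return X - means[:, None], means


def whiten(
    X: np.ndarray,
    n_components: int | None = None,
    sigma2: float | None = None,
) -> WhiteningResult:
    """Whiten centered rows via eigendecomposition of the lag-0 correlation.

    Parameters
    ----------
    X
        Centered m x l data.
    n_components
        Number of components to retain; ``None`` keeps every component above
        the rank tolerance (no dimension reduction beyond the null space).
    sigma2
        Noise variance to subtract from the retained eigenvalues.  ``None``
        estimates it as the mean of the discarded eigenvalues when
        ``n_components`` reduces the dimension, and 0 otherwise.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    C0 = cross_correlation(X)
    evals, evecs = sla.eigh(C0)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = RANK_RTOL * max(evals[0], 0.0)
    rank = int(np.sum(evals > tol))
    if n_components is None:
        r = rank
    else:
        r = int(n_components)
        if r > m:
            raise ValueError(f"n_components={r} exceeds number of rows m={m}")
    if sigma2 is None:
        # noise floor only when dimension reduction was explicitly requested;
        # automatic null-space trimming implies sigma^2 = 0
        s2 = (float(np.mean(evals[r:]))
              if (n_components is not None and r < m) else 0.0)
    else:
        s2 = float(sigma2)

    retained = evals[:r] - s2
    bad = np.nonzero(retained <= tol)[0]
    if bad.size:
        k = int(bad[0])
        raise np.linalg.LinAlgError(
            f"component {k} has eigenvalue {evals[k]:.3e} at or below the "
            f"noise floor / rank tolerance; reduce n_components"
        )
    scale = 1.0 / np.sqrt(retained)
    whitening = scale[:, None] * evecs[:, :r].T
    dewhitening = evecs[:, :r] * np.sqrt(retained)[None, :]
    Z = whitening @ X
    return WhiteningResult(
        Z=Z,
        whitening=whitening,
        dewhitening=dewhitening,
        eigenvalues=evals[:r],
        sigma2=s2,
    )


def grade(
    X: np.ndarray,
    W: WeightMatrix,
    tau: int = 1,
    n_sources: int | None = None,
    sigma2: float | None = None,
    gene_index: GeneIndex | None = None,
) -> GradeResult:
    """Factor ``X`` into network-decorrelated sources and their activities.

    Pipeline: center rows -> whiten (to ``n_sources`` components) -> form
    the symmetrized graph-delayed correlation of the whitened data at shift
    ``tau`` -> eigendecompose -> rotate back.  ``tau`` must be nonzero: the
    lag-0 correlation of whitened data is the identity and carries no
    separation information.

    Returns a :class:`GradeResult` ordered and sign-fixed by
    :func:`order_and_sign`.
    """
    if int(tau) == 0:
        raise ValueError("tau must be nonzero: the lag-0 matrix carries no "
                         "separation information after whitening")
    X = np.asarray(X, dtype=float)
    m, l = X.shape
    notes: list[str] = []
    if l <= m:
        msg = f"expected many more genes than experiments (got m={m}, l={l})"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    if W.dimension != l:
        raise ValueError(
            f"weight matrix dimension {W.dimension} != number of genes {l}"
        )

    Xc, means = center_rows(X)
    white = whiten(Xc, n_components=n_sources, sigma2=sigma2)
    Ctau = symmetrize(graph_delayed_correlation(white.Z, W, tau, auto_center=True))
    lam, V = sla.eigh(Ctau.matrix)

    # identifiability requires pairwise distinct eigenvalues
    gaps = np.diff(np.sort(lam))
    scale = max(np.max(np.abs(lam)), np.finfo(float).tiny)
    if np.any(gaps < TIE_RTOL * scale):
        msg = ("near-degenerate eigenvalues of the graph-delayed correlation: "
               "sources within tied blocks are identified only up to rotation")
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    S = V.T @ white.Z
    A = white.dewhitening @ V
    result = GradeResult(
        A=A,
        S=S,
        eigenvalues=lam,
        tau=int(tau),
        whitening=white,
        row_means=means,
        gene_index=gene_index,
        warnings=notes,
    )
    return order_and_sign(result)


def order_and_sign(result: GradeResult) -> GradeResult:
    """Resolve the permutation/sign indeterminacy canonically.

    Sources are sorted by decreasing ``|eigenvalue|``; each source is flipped
    so the largest-magnitude entry of its mixing column is positive.  ``A S``
    is unchanged.  Idempotent.
    """
    order = np.argsort(-np.abs(result.eigenvalues), kind="stable")
    A = result.A[:, order].copy()
    S = result.S[order, :].copy()
    lam = result.eigenvalues[order].copy()
    for k in range(A.shape[1]):
        col = A[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            A[:, k] = -col
            S[k, :] = -S[k, :]
    return GradeResult(
        A=A,
        S=S,
        eigenvalues=lam,
        tau=result.tau,
        whitening=result.whitening,
        row_means=result.row_means,
        gene_index=result.gene_index,
        warnings=list(result.warnings),
    )


def average_replicates(
    X: np.ndarray,
    conditions: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Average replicate rows sharing a condition label.

    ``conditions[i]`` labels row ``i``; rows with equal labels are averaged
    into one observation.  Condition order follows first appearance.
    """
    X = np.asarray(X, dtype=float)
    if len(conditions) != X.shape[0]:
        raise ValueError("one condition label per row required")
    seen: list[str] = []
    for c in conditions:
        if c not in seen:
            seen.append(c)
    rows = [X[[i for i, c in enumerate(conditions) if c == cond]].mean(axis=0)
            for cond in seen]
    return np.vstack(rows), seen
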