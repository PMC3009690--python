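"""Submode extraction, gene-set enrichment, PEI, and baseline methods.

A source (row of S, unit variance) is partitioned into two *submodes*: the
genes with contribution >= +threshold and those <= -threshold (threshold in
standard-deviation units, default 2).  Submodes are tested for
over-representation of annotation gene sets (GMT format) with a one-sided
hypergeometric test, Benjamini-Hochberg corrected.  The pathway enrichment
index (PEI) summarizes a whole decomposition: the fraction of testable
pathways significantly enriched in at least one submode or cluster.

PCA and k-means baselines follow the standard comparison protocols:
eigendecomposition of the data covariance with +/-2 SD submodes, and
k-means on the top-variance genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .graphcorr import cross_correlation
from .core import center_rows

__all__ = [
    "Submode",
    "PeiResult",
    "PcaResult",
    "KmeansResult",
    "extract_submodes",
    "hypergeometric_enrichment",
    "bh_adjust",
    "pathway_enrichment_index",
    "pca_baseline",
    "kmeans_baseline",
    "read_gmt",
]


@dataclass
class Submode:
    """One signed half of a source: its strongly contributing genes."""

    source_id: int
    sign: str  # 'positive' | 'negative'
    genes: set[str]
    threshold: float


def extract_submodes(
    S: np.ndarray,
    genes: Sequence[str],
    threshold: float = 2.0,
) -> list[Submode]:
    """Threshold each unit-variance source into positive/negative submodes.

    Positive submode: genes with source value >= +threshold (inclusive);
    negative: <= -threshold.  Warns if rows deviate from unit variance,
    since the threshold is meant in standard-deviation units.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != len(genes):
        raise ValueError("one gene identifier per source column required")
    sds = S.std(axis=1, ddof=1)
    if np.any(np.abs(sds - 1.0) > 0.05):
        warnings.warn(
            "source rows deviate from unit variance; the threshold no longer "
            "measures standard deviations",
            stacklevel=2,
        )
    genes = np.asarray(genes)
    out: list[Submode] = []
    for k, row in enumerate(S):
        out.append(Submode(k, "positive", set(genes[row >= threshold]), threshold))
        out.append(Submode(k, "negative", set(genes[row <= -threshold]), threshold))
    return out


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    annotation: Mapping[str, Iterable[str]],
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Over-representation of each annotation set in *query*.

    For a set with ``K`` genes in the universe and an overlap of ``k`` with
    the ``N``-gene query, the one-sided p-value is
    ``P(overlap >= k)`` under Hypergeometric(|universe|, K, N).  Sets with
    fewer than ``min_set_size`` genes in the universe are not tested.
    Returns a table sorted by BH-adjusted p with columns
    ``set, overlap, set_size, query_size, p, p_adj``.
    """
    query, universe = set(query), set(universe)
    if not universe or not query:
        raise ValueError("universe and query must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, members in annotation.items():
        in_uni = set(members) & universe
        K = len(in_uni)
        if K < min_set_size:
            continue
        k = len(in_uni & query)
        p = float(stats.hypergeom.sf(k - 1, len(universe), K, len(query)))
        rows.append((name, k, K, len(query), min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "p"]
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p_adj", kind="stable").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table


@dataclass
class PeiResult:
    """Pathway enrichment index of a set of submodes/clusters."""

    significant_per_submode: list[set[str]]
    significant_union: set[str]
    total_tested: int
    pei: float
    per_submode_tables: list[pd.DataFrame] = field(default_factory=list)


def pathway_enrichment_index(
    submodes: Sequence[set[str]],
    universe: set[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    min_set_size: int = 2,
    joint_bh: bool = False,
) -> PeiResult:
    """Fraction of testable pathways enriched in at least one submode.

    Each submode's gene set is tested against every annotation set; BH
    correction is applied within each submode's table (``joint_bh=True``
    corrects across all submodes jointly instead).  A pathway counts as
    significant if its adjusted p < alpha in any submode.  The denominator
    is the number of annotation sets with >= ``min_set_size`` genes in the
    universe.
    """
    testable = {
        name
        for name, members in annotation.items()
        if len(set(members) & set(universe)) >= min_set_size
    }
    if not testable:
        raise ValueError("no annotation set intersects the universe; PEI undefined")
    tables = []
    for genes in submodes:
        q = set(genes) & set(universe)
        if not q:
            tables.append(pd.DataFrame(
                columns=["set", "overlap", "set_size", "query_size", "p", "p_adj"]
            ))
            continue
        tables.append(
            hypergeometric_enrichment(q, universe, annotation, min_set_size)
        )
    if joint_bh:
        all_p = np.concatenate([t["p"].to_numpy() for t in tables if len(t)])
        adj = bh_adjust(all_p)
        pos = 0
        for t in tables:
            if len(t):
                t["p_adj"] = adj[pos:pos + len(t)]
                pos += len(t)
    sig_sets = [
        set(t.loc[t["p_adj"] < alpha, "set"]) if len(t) else set()
        for t in tables
    ]
    union = set().union(*sig_sets) if sig_sets else set()
    return PeiResult(
        significant_per_submode=sig_sets,
        significant_union=union,
        total_tested=len(testable),
        pei=len(union) / len(testable),
        per_submode_tables=tables,
    )


@dataclass
class PcaResult:
    """PCA of the experiment covariance, shaped like a factorization result."""

    A: np.ndarray                # experiments x components (mixing)
    S: np.ndarray                # components x genes, unit variance
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    row_means: np.ndarray


def pca_baseline(X: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Eigenvalue decomposition of the data covariance as a baseline.

    Components are scaled to unit variance so the +/-2 SD submode rule
    applies unchanged; ``A @ S`` reconstructs the centered data on the
    retained subspace.
    """
    Xc, means = center_rows(np.asarray(X, dtype=float))
    C = cross_correlation(Xc)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(np.sum(np.clip(evals, 0.0, None)))
    tol = 1e-10 * max(evals[0], 0.0)
    rank = int(np.sum(evals > tol))
    r = rank if n_components is None else min(int(n_components), rank)
    scale = np.sqrt(evals[:r])
    S = (evecs[:, :r].T @ Xc) / scale[:, None]
    A = evecs[:, :r] * scale[None, :]
    return PcaResult(
        A=A,
        S=S,
        eigenvalues=evals[:r],
        explained_variance_ratio=np.clip(evals, 0.0, None)[:r] / total,
        row_means=means,
    )


@dataclass
class KmeansResult:
    genes: list[str]             # genes retained by the variance filter
    labels: np.ndarray
    centroids: np.ndarray
    clusters: list[set[str]]


def kmeans_baseline(
    X: pd.DataFrame,
    k: int = 8,
    top_frac: float = 0.15,
    seed: int = 0,
    n_init: int = 10,
) -> KmeansResult:
    """k-means over the most variable genes (genes x samples orientation).

    Genes are ranked by expression variance across samples and the top
    ``top_frac`` fraction retained before clustering with a fixed seed and
    multiple restarts.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    var = X.var(axis=1, ddof=1)
    n_keep = max(int(round(top_frac * len(X))), 1)
    kept = var.sort_values(ascending=False, kind="stable").index[:n_keep]
    if k > len(kept):
        raise ValueError(f"k={k} exceeds the {len(kept)} genes kept by the filter")
    sub = X.loc[kept]
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(sub.to_numpy(dtype=float))
    clusters = [set(np.asarray(kept)[labels == c]) for c in range(k)]
    return KmeansResult(
        genes=list(kept),
        labels=labels,
        centroids=km.cluster_centers_,
        clusters=clusters,
    )


def read_gmt(stream: TextIO | Iterable[str]) -> dict[str, list[str]]:
    """Parse GMT gene-set records: name <TAB> description <TAB> genes..."""
    sets: dict[str, list[str]] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"GMT line {line_no}: expected name, description and >= 1 gene"
            )
        name = parts[0]
        if name in sets:
            raise ValueError(f"GMT line {line_no}: duplicate set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets
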