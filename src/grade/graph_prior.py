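"""Prior-knowledge regulatory networks and the graph-shift operator.

A directed, weighted graph over genes encodes prior knowledge such as
transcription-factor/target relations.  Its weight matrix ``W`` (entry
``W[i, j]`` = weight of edge ``i -> j``) acts as a propagator: multiplying an
activity pattern by ``W`` pushes activity one step along the network, the
graph analogue of a unit time delay.  Shifting along the line graph
``1 -> 2 -> ... -> l`` with unit weights recovers the classic lag operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RegulatoryGraph",
    "GeneIndex",
    "WeightMatrix",
    "EdgeListParseError",
    "EdgeConflictError",
    "load_edge_list",
    "to_weight_matrix",
    "g_shift",
    "INTERACTION_WEIGHTS",
]

#: Curated-database interaction keywords mapped to signed unit weights.
#: Activating relations propagate activity with weight +1, repressing
#: relations with weight -1 (the minimal signed encoding).
INTERACTION_WEIGHTS: dict[str, float] = {
    "transactivation": 1.0,
    "increase of abundance": 1.0,
    "expression": 1.0,
    "activation": 1.0,
    "dna binding": 1.0,
    "increase of dna binding": 1.0,
    "transrepression": -1.0,
    "decrease of abundance": -1.0,
    "decrease of dna binding": -1.0,
    "inhibition": -1.0,
}


class EdgeListParseError(ValueError):
    """A malformed record in an edge-list stream (carries the line number)."""


class EdgeConflictError(ValueError):
    """Duplicate (source, target) records with conflicting weights."""


@dataclass
class RegulatoryGraph:
    """A directed, weighted gene network given as an edge list.

    Parameters
    ----------
    edges
        ``(source, target, weight)`` triples.  Self-loops are permitted and
        weights may be negative.  Duplicate ``(source, target)`` pairs are
        forbidden.
    extra_nodes
        Isolated genes to include in :attr:`node_set` beyond edge endpoints.
    """

    edges: list[tuple[str, str, float]]
    extra_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float] = {}
        for s, t, w in self.edges:
            key = (s, t)
            if key in seen and seen[key] != w:
                raise EdgeConflictError(
                    f"conflicting weights for edge {s}->{t}: {seen[key]} vs {w}"
                )
            seen[key] = w
        # drop exact duplicates, keep first-seen order
        self.edges = [(s, t, w) for (s, t), w in seen.items()]

    @property
    def node_set(self) -> set[str]:
        nodes = set(self.extra_nodes)
        for s, t, _ in self.edges:
            nodes.add(s)
            nodes.add(t)
        return nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators(self) -> set[str]:
        return {s for s, _, _ in self.edges}

    def targets(self) -> set[str]:
        return {t for _, t, _ in self.edges}


class GeneIndex:
    """Bidirectional map between gene identifiers and matrix positions.

    Aligns the columns of an expression matrix with the rows/columns of a
    weight matrix.  Positions are contiguous ``0 .. l-1`` and stable.
    """

    def __init__(self, genes: Sequence[str]):
        self._genes = list(genes)
        self._pos = {g: i for i, g in enumerate(self._genes)}
        if len(self._pos) != len(self._genes):
            raise ValueError("duplicate gene identifiers in index")

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def __iter__(self):
        return iter(self._genes)

    def position(self, gene: str) -> int:
        return self._pos[gene]

    def gene(self, position: int) -> str:
        return self._genes[position]

    @property
    def genes(self) -> list[str]:
        return list(self._genes)


@dataclass
class WeightMatrix:
    """Sparse l x l propagator; ``matrix[i, j]`` is the weight of edge i -> j."""

    matrix: sp.csr_matrix
    index: GeneIndex | None = None

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"weight matrix must be square, got {m.shape}")
        self.matrix = m

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def transpose(self) -> "WeightMatrix":
        return WeightMatrix(self.matrix.T.tocsr(), self.index)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _parse_weight(token: str, line_no: int) -> float:
    try:
        return float(token)
    except ValueError:
        key = token.strip().lower().replace("_", " ")
        if key in INTERACTION_WEIGHTS:
            return INTERACTION_WEIGHTS[key]
        raise EdgeListParseError(
            f"line {line_no}: cannot interpret weight field {token!r} "
            "(not a number or a known interaction keyword)"
        ) from None


def load_edge_list(
    stream: TextIO | Iterable[str],
    dialect: str = "tsv",
    header: bool = False,
    uppercase: bool = False,
) -> RegulatoryGraph:
    """Read a directed weighted network from a text stream.

    Parameters
    ----------
    stream
        Iterable of lines.  ``#`` starts a comment line; blank lines ignored.
    dialect
        ``"tsv"``: three tab-separated columns *source, target, weight*,
        where the weight is numeric or an interaction keyword.
        ``"sif"``: *source, relation, target* with the relation mapped via
        the keyword table.
    header
        Skip the first non-comment line.
    uppercase
        Normalize identifiers to upper case (matching is otherwise
        case-sensitive exact).
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: list[tuple[str, str, float]] = []
    skipped_header = not header
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not skipped_header:
            skipped_header = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise EdgeListParseError(
                f"line {line_no}: expected 3 tab-separated fields, got {len(parts)}"
            )
        if dialect == "tsv":
            s, t, wtok = parts
        else:  # sif: source, relation, target
            s, wtok, t = parts
        s, t = s.strip(), t.strip()
        if not s or not t:
            raise EdgeListParseError(f"line {line_no}: empty gene identifier")
        if uppercase:
            s, t = s.upper(), t.upper()
        edges.append((s, t, _parse_weight(wtok, line_no)))
    return RegulatoryGraph(edges)


def to_weight_matrix(
    graph: RegulatoryGraph,
    index: GeneIndex,
    drop_missing: bool = False,
) -> WeightMatrix:
    """Build the sparse weight matrix of *graph* aligned to *index*.

    Genes present in the index but absent from the network get all-zero
    rows and columns (they contribute to lag-0 statistics only).  Graph
    nodes missing from the index raise unless ``drop_missing``.
    """
    rows, cols, data = [], [], []
    for s, t, w in graph.edges:
        if s not in index or t not in index:
            if drop_missing:
                continue
            missing = s if s not in index else t
            raise KeyError(
                f"gene {missing!r} from network not found in gene index "
                "(pass drop_missing=True to ignore)"
            )
        rows.append(index.position(s))
        cols.append(index.position(t))
        data.append(w)
    l = len(index)
    m = sp.csr_matrix((data, (rows, cols)), shape=(l, l))
    return WeightMatrix(m, index)


def g_shift(X: np.ndarray, W: WeightMatrix | sp.spmatrix, tau: int) -> np.ndarray:
    """Propagate the columns of ``X`` *tau* steps along the network.

    For ``tau >= 0`` returns ``X @ W^tau``; for ``tau < 0`` propagation runs
    against edge direction, ``X @ (W.T)^|tau|``.  ``tau = 0`` returns a copy
    of ``X``.  The matrix power is never materialized: ``X`` is multiplied
    ``|tau|`` times by the sparse propagator.
    """
    M = W.matrix if isinstance(W, WeightMatrix) else sp.csr_matrix(W)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
        squeeze = True
    else:
        squeeze = False
    if X.shape[1] != M.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but weight matrix is {M.shape[0]}x{M.shape[0]}"
        )
    P = M if tau >= 0 else M.T.tocsr()
    out = X.copy()
    for _ in range(abs(int(tau))):
        out = out @ P
        out = np.asarray(out)
    return out[0] if squeeze else out
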