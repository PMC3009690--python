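import io

import numpy as np
import pytest
import scipy.sparse as sp

from grade import GeneIndex, RegulatoryGraph, WeightMatrix, to_weight_matrix


def line_graph_weights(l: int) -> WeightMatrix:
    """Unit-weight line graph 1 -> 2 -> ... -> l (classic lag operator)."""
    rows = np.arange(l - 1)
    cols = np.arange(1, l)
    M = sp.csr_matrix((np.ones(l - 1), (rows, cols)), shape=(l, l))
    return WeightMatrix(M)


def random_sparse_weights(l: int, density: float = 0.02, seed: int = 0) -> WeightMatrix:
    """Random signed sparse propagator for synthetic-mixture tests."""
    rs = np.random.RandomState(seed)
    M = sp.random(l, l, density=density, random_state=rs,
                  data_rvs=lambda k: np.sign(rs.standard_normal(k)))
    return WeightMatrix(M.tocsr())


@pytest.fixture
def chain_graph() -> RegulatoryGraph:
    return RegulatoryGraph([("g1", "g2", 1.0), ("g2", "g3", 1.0)])


@pytest.fixture
def chain_index() -> GeneIndex:
    return GeneIndex(["g1", "g2", "g3"])


@pytest.fixture
def chain_weights(chain_graph, chain_index) -> WeightMatrix:
    return to_weight_matrix(chain_graph, chain_index)


def edge_stream(text: str):
    return io.StringIO(text)


def random_bipartite_graph(n_reg=10, n_tgt=20, n_edges=100, seed=0) -> RegulatoryGraph:
    rng = np.random.default_rng(seed)
    pairs = [(f"r{i}", f"t{j}") for i in range(n_reg) for j in range(n_tgt)]
    picks = rng.choice(len(pairs), size=n_edges, replace=False)
    weights = rng.choice([-1.0, 1.0], size=n_edges)
    return RegulatoryGraph(
        [(pairs[p][0], pairs[p][1], float(w)) for p, w in zip(picks, weights)]
    )
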