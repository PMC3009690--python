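"""ODE toy systems and a synthetic-mixture generator with ground truth.

Two small regulatory motifs illustrate graph-decorrelation on data whose
generating network is known exactly:

* **bifan** — two regulators each target the same two genes with mixed
  activation/inhibition; one input is active until t = 10, when it is
  switched off and the second input is switched on.  Two downstream
  reporter genes bring the number of observed species to six.
* **funnel** — a regulatory cascade whose branches converge on a single
  gene, observed at steady state under three different input conditions.

Gene dynamics follow a degradation + Hill-regulation ODE,
``dx_i/dt = -gamma_i x_i + sum_{j in P(i)} f_ji(x_j) + u_i(t)``,
with sigmoidal Hill interactions.  Exact parameters for the published
figures are not available; the fixtures use generic defaults
(gamma = 1, K = 1, h = 2) chosen for qualitative agreement.

:func:`synthetic_mixture` realizes the mixing model exactly: it constructs
sources whose symmetrized graph-delayed cross-correlations vanish
off-diagonal for a given network, mixes them with a random orthogonal-column
matrix and optionally adds white noise, returning the ground truth for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .core import center_rows, whiten
from .graph_prior import GeneIndex, RegulatoryGraph, WeightMatrix, to_weight_matrix
from .graphcorr import graph_delayed_correlation, symmetrize

__all__ = [
    "OdeNetworkModel",
    "Trajectory",
    "hill_interaction",
    "simulate_ode",
    "bifan_fixture",
    "bifan_expression",
    "funnel_fixture",
    "funnel_expression",
    "synthetic_mixture",
]


def hill_interaction(
    x: float | np.ndarray,
    sign: str,
    beta: float = 1.0,
    K: float = 1.0,
    h: float = 2.0,
) -> float | np.ndarray:
    """Sigmoidal Hill regulation term.

    Activation (``sign='+'``): ``beta * x^h / (K^h + x^h)`` — zero at x=0,
    half-saturated at x=K.  Inhibition (``sign='-'``):
    ``beta * K^h / (K^h + x^h)`` — maximal production when the inhibitor is
    absent, decaying to zero as it accumulates.
    """
    if K <= 0 or h < 1 or beta < 0:
        raise ValueError("require K > 0, h >= 1, beta >= 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill regulation is defined for nonnegative inputs")
    xh = x**h
    Kh = K**h
    if sign == "+":
        out = beta * xh / (Kh + xh)
    elif sign == "-":
        out = beta * Kh / (Kh + xh)
    else:
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class HillEdge:
    source: str
    target: str
    sign: str  # '+' activation, '-' inhibition
    beta: float = 1.0
    K: float = 1.0
    h: float = 2.0


@dataclass
class OdeNetworkModel:
    """Degradation + Hill-regulation ODE system on a gene network."""

    nodes: list[str]
    edges: list[HillEdge]
    gamma: dict[str, float]
    inputs: dict[str, Callable[[float], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.nodes:
            if self.gamma.get(n, 0.0) <= 0:
                raise ValueError(f"degradation rate gamma must be positive for {n}")

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.nodes)}
        # clip: tiny negative excursions from the solver are not biology
        xc = np.maximum(x, 0.0)
        dx = np.array([-self.gamma[n] * x[i] for n, i in pos.items()])
        for e in self.edges:
            dx[pos[e.target]] += hill_interaction(
                xc[pos[e.source]], e.sign, e.beta, e.K, e.h
            )
        for n, u in self.inputs.items():
            dx[pos[n]] += u(t)
        return dx

    def regulatory_graph(self) -> RegulatoryGraph:
        """Signed +/-1 edge list of the motif, for use as a GraDe prior."""
        sign = {"+": 1.0, "-": -1.0}
        return RegulatoryGraph(
            [(e.source, e.target, sign[e.sign]) for e in self.edges],
            extra_nodes=set(self.nodes),
        )


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # |times| x |nodes|
    nodes: list[str]


def simulate_ode(
    model: OdeNetworkModel,
    t_grid: np.ndarray,
    x0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float | None = None,
) -> Trajectory:
    """Integrate the model on a strictly increasing time grid.

    Uses an implicit stiff-safe solver; ``max_step`` should stay below the
    spacing of any step-input switches so they are not skipped (the fixtures
    set it accordingly).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be 1-d and strictly increasing")
    if x0 is None:
        x0 = np.zeros(len(model.nodes))
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    kwargs = {} if max_step is None else {"max_step": max_step}
    sol = solve_ivp(
        model.rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, nodes=list(model.nodes))


def _step(on_until: float | None = None, on_from: float | None = None,
          level: float = 1.0) -> Callable[[float], float]:
    def u(t: float) -> float:
        if on_until is not None:
            return level if t < on_until else 0.0
        return level if t >= on_from else 0.0
    return u


def bifan_fixture() -> tuple[OdeNetworkModel, np.ndarray]:
    """Bifan motif with a switched input schedule and two reporter genes.

    Regulators x1 (driven until t = 10) and x2 (driven from t = 10) both
    target x3 and x4 with crossed signs: x1 activates x3 and inhibits x4,
    x2 activates x4 and inhibits x3.  x3 tracks x1 and peaks at the switch;
    x4 shows an early activation because its inhibitor x1 starts at zero.
    Reporters x5 and x6 relay x3 and x4, giving six observed species.  The
    grid has 11 evenly spaced points covering the switch at t = 10.
    """
    nodes = ["x1", "x2", "x3", "x4", "x5", "x6"]
    edges = [
        HillEdge("x1", "x3", "+"),
        HillEdge("x1", "x4", "-"),
        HillEdge("x2", "x3", "-"),
        HillEdge("x2", "x4", "+"),
        HillEdge("x3", "x5", "+"),
        HillEdge("x4", "x6", "+"),
    ]
    model = OdeNetworkModel(
        nodes=nodes,
        edges=edges,
        gamma={n: 1.0 for n in nodes},
        inputs={"x1": _step(on_until=10.0), "x2": _step(on_from=10.0)},
    )
    t_grid = np.linspace(0.0, 20.0, 11)
    return model, t_grid


def bifan_expression() -> tuple[np.ndarray, GeneIndex, WeightMatrix]:
    """Simulated bifan time courses as a (time points x genes) matrix.

    Returns the expression matrix, the gene index, and the signed +/-1
    weight matrix of the motif topology (the prior handed to GraDe, which
    has no access to the generating ODE system).
    """
    model, t_grid = bifan_fixture()
    # x2 inhibition at level 0 still contributes; the solver sees the
    # step switch because max_step < grid spacing
    traj = simulate_ode(model, t_grid, max_step=0.5)
    index = GeneIndex(model.nodes)
    W = to_weight_matrix(model.regulatory_graph(), index)
    return traj.states, index, W


def funnel_fixture() -> tuple[OdeNetworkModel, list[dict[str, float]]]:
    """Funnel motif: a cascade and two direct inputs converging on one gene.

    g1 -> g2 -> g3 feed g6, together with g4 and g5.  Three input
    conditions drive (g1), (g4), and (g4, g5) respectively; each condition
    is read out at steady state, giving three expression vectors.
    """
    nodes = ["g1", "g2", "g3", "g4", "g5", "g6"]
    edges = [
        HillEdge("g1", "g2", "+"),
        HillEdge("g2", "g3", "+"),
        HillEdge("g3", "g6", "+"),
        HillEdge("g4", "g6", "+"),
        HillEdge("g5", "g6", "+"),
    ]
    model = OdeNetworkModel(
        nodes=nodes, edges=edges, gamma={n: 1.0 for n in nodes}
    )
    conditions = [
        {"g1": 2.0},
        {"g4": 2.0},
        {"g4": 2.0, "g5": 2.0},
    ]
    return model, conditions


def funnel_expression() -> tuple[np.ndarray, GeneIndex, WeightMatrix]:
    """Steady-state funnel expression for the three input conditions (3 x 6)."""
    model, conditions = funnel_fixture()
    rows = []
    for cond in conditions:
        m = OdeNetworkModel(
            nodes=model.nodes,
            edges=model.edges,
            gamma=model.gamma,
            inputs={n: (lambda t, c=c: c) for n, c in cond.items()},
        )
        traj = simulate_ode(m, np.linspace(0.0, 50.0, 26))
        rows.append(traj.states[-1])
    index = GeneIndex(model.nodes)
    W = to_weight_matrix(model.regulatory_graph(), index)
    return np.vstack(rows), index, W


def synthetic_mixture(
    m: int,
    n: int,
    l: int,
    W: WeightMatrix,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a network-consistent mixture ``X = A S + eps`` with ground truth.

    The sources are built so that their symmetrized graph-delayed
    cross-correlation at shift ``tau`` is exactly diagonal: random centered
    data are whitened, the realized symmetrized graph-delayed correlation is
    eigendecomposed, and its eigenbasis rotates the whitened rows.  The
    construction leaves every source row with exactly unit variance under
    the ``1/(l-1)`` estimator.  ``A`` has random orthonormal columns.

    Returns ``(X, A_true, S_true)``; the same seed reproduces all three.
    """
    if n > m:
        raise ValueError("cannot mix more sources than observations (n <= m)")
    if W.dimension != l:
        raise ValueError("weight matrix dimension must equal l")
    rng = np.random.default_rng(seed)
    R, _ = center_rows(rng.standard_normal((n, l)))
    white = whiten(R)
    if white.Z.shape[0] < n:
        raise ValueError("random draw was rank-deficient; use larger l")
    C = symmetrize(graph_delayed_correlation(white.Z, W, tau, auto_center=True))
    scale = float(np.max(np.abs(C.matrix)))
    if scale < 1e-12:
        raise ValueError(
            "degenerate weight matrix: graph-delayed correlation vanishes, "
            "no distinct eigenvalues to separate on"
        )
    lam, U = np.linalg.eigh(C.matrix)
    gaps = np.diff(np.sort(lam))
    if np.any(gaps < 1e-10 * scale):
        raise ValueError("realized delayed-correlation eigenvalues are tied; "
                         "try another seed or a more informative network")
    order = np.argsort(-np.abs(lam))
    S = (U[:, order].T @ white.Z)

    Q, Rq = np.linalg.qr(rng.standard_normal((m, n)))
    A = Q * np.sign(np.diag(Rq))[None, :]
    X = A @ S
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal((m, l))
    return X, A, S
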