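"""Edge curvature and the discrete Ricci flow on the network weights.

The curvature of an edge (i, j) is

    kappa_beta(i, j) = 1 - W_beta(m_i, m_j) / d_ij,

where W_beta is the beta-Wasserstein cost between the endpoint neighborhood
distributions (solved on the local bipartite problem) and d_ij the weighted
shortest-path distance between i and j on the current graph — which can be
shorter than the edge's own weight once the flow has deformed the metric.
Positively curved edges sit inside well-connected groups; negatively curved
ones are bridges between groups.

One flow step replaces every weight by d_ij * (1 - kappa) — algebraically
exactly the transport cost W_beta of that edge — and then normalizes all
weights by their total sum.  Iterating shortens intra-community edges and
stretches inter-community ones, separating the communities metrically.

Curvature of all edges in one pass goes through the batched DMK engine;
shortest-path distances are computed once per iteration with scipy's
Dijkstra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .dmk import DMKConfig, solve_dmk, solve_dmk_many, sinkhorn_transport_cost
from .graph_core import ensure_weighted_graph, normalize_weights, sorted_nodes
from .ot_local import BipartiteOTProblem, neighborhood_mass

__all__ = [
    "CurvatureMap",
    "FlowSnapshot",
    "FlowTrace",
    "edge_curvature",
    "curvature_all_edges",
    "ricci_flow_step",
    "run_flow",
]

Node = Hashable

#: updated weights never drop below this before normalization
EPS_WEIGHT = 1e-12


@dataclass
class CurvatureMap:
    """Per-edge curvature values, keyed by sorted node pairs."""

    kappa: dict

    def get(self, i: Node, j: Node) -> float:
        key = tuple(sorted_nodes((i, j)))
        return self.kappa[key]

    def items(self):
        return self.kappa.items()

    def to_frame(self, G: nx.Graph | None = None, iteration: int | None = None) -> pd.DataFrame:
        rows = []
        for (u, v), k in sorted(self.kappa.items(), key=lambda kv: repr(kv[0])):
            row = {"u": u, "v": v, "kappa": k}
            if G is not None:
                row["weight"] = G[u][v]["weight"]
            if iteration is not None:
                row["iteration"] = iteration
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class FlowSnapshot:
    """State of one flow iteration.

    ``weights`` are the normalized weights at this iteration; ``curvatures``
    and ``wasserstein`` are the per-edge values computed *on* these weights
    (None on the final snapshot, whose weights are the flow's output);
    ``surgery`` is filled in by the community-detection driver.
    """

    iteration: int
    weights: dict
    curvatures: CurvatureMap | None = None
    wasserstein: dict | None = None
    distances: dict | None = None
    n_unconverged: int = 0
    surgery: object | None = None  # communities.SurgeryResult

    @property
    def modularity_best(self) -> float | None:
        return None if self.surgery is None else self.surgery.modularity

    @property
    def partition_best(self) -> dict | None:
        return None if self.surgery is None else self.surgery.partition


@dataclass
class FlowTrace:
    """Ordered snapshots of a Ricci-flow run; entry 0 is the initial state."""

    iterations: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    def __getitem__(self, t: int) -> FlowSnapshot:
        return self.iterations[t]

    def graphs(self, template: nx.Graph):
        """Yield the graph of each snapshot (template topology, snapshot weights)."""
        for snap in self.iterations:
            H = template.copy()
            for (u, v), w in snap.weights.items():
                H[u][v]["weight"] = w
            yield H


def _distance_matrix(G: nx.Graph, nodes: list) -> np.ndarray:
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, data in G.edges(data=True):
        rows.append(idx[u])
        cols.append(idx[v])
        vals.append(data["weight"])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return dijkstra(A, directed=False)


def _edge_problems(
    G: nx.Graph, nodes: list, D: np.ndarray, alpha: float
) -> tuple[list, list]:
    """Bipartite problems for every edge, in sorted edge order."""
    idx = {n: k for k, n in enumerate(nodes)}
    neigh = {n: sorted_nodes(set(G.neighbors(n)) | {n}) for n in nodes}
    masses = {
        n: neighborhood_mass(G, n, alpha) for n in nodes if G.degree(n) > 0
    }
    edges = sorted((tuple(sorted_nodes(e)) for e in G.edges), key=repr)
    problems = []
    for i, j in edges:
        left, right = neigh[i], neigh[j]
        li = np.array([idx[n] for n in left])
        ri = np.array([idx[n] for n in right])
        cost = D[np.ix_(li, ri)]
        problems.append(
            BipartiteOTProblem(
                left_nodes=left,
                right_nodes=right,
                cost=cost,
                source=masses[i].as_array(left),
                sink=masses[j].as_array(right),
                edge=(i, j),
            )
        )
    return edges, problems


def edge_curvature(
    G: nx.Graph,
    i: Node,
    j: Node,
    beta: float = 1.0,
    alpha: float = 0.0,
    config: DMKConfig | None = None,
) -> float:
    """Curvature kappa_beta of a single edge of ``G``."""
    config = (config or DMKConfig()).with_beta(beta)
    if not G.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge")
    from .ot_local import build_local_ot_problem

    problem = build_local_ot_problem(G, i, j, alpha)
    d_ij = nx.dijkstra_path_length(G, i, j, weight="weight")
    if d_ij <= 0:
        raise ValueError("shortest-path distance between endpoints must be positive")
    result = solve_dmk(problem, config)
    return 1.0 - result.cost / d_ij


def _curvature_pass(
    G: nx.Graph,
    beta: float,
    alpha: float,
    config: DMKConfig,
    method: str = "dmk",
    sinkhorn_reg: float = 1e-3,
    mu_state: dict | None = None,
):
    """Compute (d_ij, W_beta, kappa) for every edge in one batched pass.

    ``mu_state`` maps edges to conductivity arrays from a previous pass on
    the same topology (warm start); the returned dict holds the new states.
    """
    nodes = sorted_nodes(G.nodes)
    D = _distance_matrix(G, nodes)
    edges, problems = _edge_problems(G, nodes, D, alpha)
    mu_out: dict = {}
    if method == "dmk":
        init = None
        if mu_state is not None:
            init = [mu_state.get(e) for e in edges]
        results = solve_dmk_many(problems, config.with_beta(beta), mu_init=init)
        costs = [r.cost for r in results]
        n_unconverged = sum(1 for r in results if not r.converged)
        mu_out = {e: r.mu for e, r in zip(edges, results)}
    elif method == "sinkhorn":
        costs = [sinkhorn_transport_cost(p, reg=sinkhorn_reg) for p in problems]
        n_unconverged = 0
    else:
        raise ValueError(f"unknown curvature method {method!r}")
    idx = {n: k for k, n in enumerate(nodes)}
    dist, wass, kappa = {}, {}, {}
    for (i, j), w_cost in zip(edges, costs):
        d_ij = D[idx[i], idx[j]]
        dist[(i, j)] = d_ij
        wass[(i, j)] = w_cost
        kappa[(i, j)] = 1.0 - w_cost / d_ij
    return dist, wass, CurvatureMap(kappa), n_unconverged, mu_out


def curvature_all_edges(
    G: nx.Graph,
    beta: float = 1.0,
    alpha: float = 0.0,
    config: DMKConfig | None = None,
    method: str = "dmk",
) -> CurvatureMap:
    """Curvature of every edge of ``G`` (per connected component)."""
    ensure_weighted_graph(G)
    config = config or DMKConfig()
    _, _, cmap, _, _ = _curvature_pass(G, beta, alpha, config, method=method)
    return cmap


def ricci_flow_step(
    G: nx.Graph,
    beta: float = 1.0,
    alpha: float = 0.0,
    config: DMKConfig | None = None,
    method: str = "dmk",
) -> tuple[nx.Graph, CurvatureMap]:
    """One flow update: w_ij <- d_ij (1 - kappa_ij), then normalize."""
    config = config or DMKConfig()
    _, wass, cmap, _, _ = _curvature_pass(G, beta, alpha, config, method=method)
    H = G.copy()
    for (i, j), w_cost in wass.items():
        H[i][j]["weight"] = max(w_cost, EPS_WEIGHT)
    return normalize_weights(H), cmap


def run_flow(
    G: nx.Graph,
    beta: float = 1.0,
    alpha: float = 0.0,
    max_iter: int = 15,
    config: DMKConfig | None = None,
    method: str = "dmk",
) -> FlowTrace:
    """Iterate the Ricci flow ``max_iter`` times and record every state.

    The initial weights are the pairwise shortest-path distances of the
    input metric (w^(0) = d^(0)), normalized; each subsequent snapshot holds
    the normalized weights together with the curvatures and transport costs
    computed on them.  The trace has ``max_iter + 1`` snapshots; surgery and
    partition extraction are layered on top by the communities module.
    """
    ensure_weighted_graph(G)
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    if G.number_of_edges() == 0:
        raise ValueError("cannot flow a graph with no edges")
    config = (config or DMKConfig()).with_beta(beta)

    nodes = sorted_nodes(G.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    D0 = _distance_matrix(G, nodes)
    H = G.copy()
    for u, v in H.edges:
        H[u][v]["weight"] = max(D0[idx[u], idx[v]], EPS_WEIGHT)
    H = normalize_weights(H)

    trace = FlowTrace()
    mu_state: dict | None = None
    for t in range(max_iter):
        # conductivities are warm-started from the previous iteration's
        # steady state: the metric deforms slowly, so this is a continuation
        dist, wass, cmap, n_unconv, mu_state = _curvature_pass(
            H, beta, alpha, config, method=method, mu_state=mu_state
        )
        trace.iterations.append(
            FlowSnapshot(
                iteration=t,
                weights={e: H[e[0]][e[1]]["weight"] for e in cmap.kappa},
                curvatures=cmap,
                wasserstein=wass,
                distances=dist,
                n_unconverged=n_unconv,
            )
        )
        for (i, j), w_cost in wass.items():
            H[i][j]["weight"] = max(w_cost, EPS_WEIGHT)
        H = normalize_weights(H)
    trace.iterations.append(
        FlowSnapshot(
            iteration=max_iter,
            weights={
                tuple(sorted_nodes(e)): H[e[0]][e[1]]["weight"] for e in H.edges
            },
        )
    )
    return trace
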