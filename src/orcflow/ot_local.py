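"""Neighborhood mass distributions and per-edge bipartite transport problems.

For an edge (i, j) the similarity of the two endpoints' neighborhoods is
measured by an optimal-transport problem posed on an auxiliary complete
bipartite graph: the left side holds copies of N(i) ∪ {i}, the right side
copies of N(j) ∪ {j}, and the cost of a left–right pair is the weighted
shortest-path distance between the two nodes in the ambient graph (zero for
the copies of one and the same node).  The source marginal is the lazy
one-step distribution m_i^alpha — mass ``alpha`` on i itself and
``(1-alpha)/deg(i)`` on each neighbor — and the sink marginal is m_j^alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import sorted_nodes

__all__ = ["MassDistribution", "BipartiteOTProblem", "neighborhood_mass", "build_local_ot_problem"]

Node = Hashable

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class MassDistribution:
    """Probability mass on a node's closed neighborhood."""

    center: Node
    masses: Mapping[Node, float]
    alpha: float = 0.0

    def __post_init__(self):
        total = sum(self.masses.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total}, expected 1")
        if any(m < 0 for m in self.masses.values()):
            raise ValueError("negative mass")

    def as_array(self, order: list) -> np.ndarray:
        return np.array([self.masses.get(n, 0.0) for n in order], dtype=float)


@dataclass(frozen=True)
class BipartiteOTProblem:
    """Complete bipartite transport problem for one edge of the graph.

    ``cost[k, l]`` is the shortest-path distance between ``left_nodes[k]``
    and ``right_nodes[l]`` measured on the ambient graph (exactly 0 when the
    two entries are copies of the same node).  ``source`` and ``sink`` are
    the marginals in the same orderings; each sums to 1.
    """

    left_nodes: list = field(repr=False)
    right_nodes: list = field(repr=False)
    cost: np.ndarray = field(repr=False)
    source: np.ndarray = field(repr=False)
    sink: np.ndarray = field(repr=False)
    edge: tuple = ()

    def __post_init__(self):
        nL, nR = len(self.left_nodes), len(self.right_nodes)
        if self.cost.shape != (nL, nR):
            raise ValueError("cost matrix shape does not match node lists")
        if self.source.shape != (nL,) or self.sink.shape != (nR,):
            raise ValueError("marginal shape mismatch")
        if abs(self.source.sum() - 1.0) > 1e-9 or abs(self.sink.sum() - 1.0) > 1e-9:
            raise ValueError("marginals must each sum to 1")
        if np.any(self.cost < 0) or not np.all(np.isfinite(self.cost)):
            raise ValueError("costs must be finite and nonnegative")

    @property
    def shape(self) -> tuple:
        return self.cost.shape

    def transpose(self) -> "BipartiteOTProblem":
        """Swap the two sides (source becomes sink); costs are transposed."""
        return BipartiteOTProblem(
            left_nodes=list(self.right_nodes),
            right_nodes=list(self.left_nodes),
            cost=self.cost.T.copy(),
            source=self.sink.copy(),
            sink=self.source.copy(),
            edge=tuple(reversed(self.edge)),
        )

    def to_frame(self) -> pd.DataFrame:
        """Debug dump: one row per bipartite pair."""
        rows = []
        for k, u in enumerate(self.left_nodes):
            for l, v in enumerate(self.right_nodes):
                rows.append(
                    {
                        "left": u,
                        "right": v,
                        "cost": self.cost[k, l],
                        "source_mass": self.source[k],
                        "sink_mass": self.sink[l],
                    }
                )
        return pd.DataFrame(rows)


def neighborhood_mass(G: nx.Graph, i: Node, alpha: float = 0.0) -> MassDistribution:
    """Distribution m_i^alpha: mass alpha at i, (1-alpha)/deg(i) per neighbor."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    neighbors = list(G.neighbors(i))
    if not neighbors:
        raise ValueError(f"node {i!r} is isolated; it has no neighborhood distribution")
    share = (1.0 - alpha) / len(neighbors)
    masses = {n: share for n in neighbors}
    masses[i] = masses.get(i, 0.0) + alpha
    return MassDistribution(center=i, masses=masses, alpha=alpha)


def build_local_ot_problem(
    G: nx.Graph,
    i: Node,
    j: Node,
    alpha: float = 0.0,
    distances: Mapping[Node, Mapping[Node, float]] | None = None,
) -> BipartiteOTProblem:
    """Construct the bipartite problem for edge (i, j).

    ``distances`` may hold precomputed per-source shortest-path maps (as
    produced once per flow iteration); otherwise Dijkstra runs on demand.
    """
    if not G.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge of the graph")
    left = sorted_nodes(set(G.neighbors(i)) | {i})
    right = sorted_nodes(set(G.neighbors(j)) | {j})
    m_i = neighborhood_mass(G, i, alpha)
    m_j = neighborhood_mass(G, j, alpha)

    if distances is None:
        distances = {
            u: nx.single_source_dijkstra_path_length(G, u, weight="weight") for u in left
        }
    cost = np.empty((len(left), len(right)))
    for k, u in enumerate(left):
        du = distances[u]
        for l, v in enumerate(right):
            d = du.get(v, math.inf) if hasattr(du, "get") else du[v]
            if not math.isfinite(d):
                raise ValueError(
                    f"nodes {u!r} and {v!r} are disconnected; cannot cost the pair"
                )
            cost[k, l] = d
    return BipartiteOTProblem(
        left_nodes=left,
        right_nodes=right,
        cost=cost,
        source=m_i.as_array(left),
        sink=m_j.as_array(right),
        edge=(i, j),
    )
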