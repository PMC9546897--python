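"""Network surgery, partition extraction, iteration selection and ARI.

After the Ricci flow has stretched inter-community edges and shrunk
intra-community ones, communities are obtained by *surgery*: cut every edge
longer than a threshold and read the connected components of the remainder.
The threshold is chosen by scanning the midpoints between consecutive
distinct edge weights and keeping the cut whose partition maximizes the
Newman modularity — evaluated on the *reference* graph (by default the
uncut input), because the communities are claims about the input network,
not about the deformed metric.

The number of communities is never an input: it emerges from the cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .dmk import DMKConfig
from .graph_core import ensure_weighted_graph, modularity, sorted_nodes
from .ricci_flow import FlowTrace, run_flow

__all__ = [
    "SurgeryResult",
    "surgery",
    "best_surgery",
    "detect_communities",
    "adjusted_rand_index",
    "infomap_partition",
]

Node = Hashable
Partition = Mapping[Node, Hashable]


@dataclass
class SurgeryResult:
    """Outcome of cutting all edges heavier than ``threshold``."""

    partition: dict
    threshold: float
    modularity: float
    n_cut_edges: int

    @property
    def n_communities(self) -> int:
        return len(set(self.partition.values()))


def _components_partition(H: nx.Graph) -> dict:
    partition: dict = {}
    comps = sorted((sorted_nodes(c) for c in nx.connected_components(H)), key=repr)
    for label, comp in enumerate(comps):
        for node in comp:
            partition[node] = label
    return partition


def surgery(
    G: nx.Graph, threshold: float, reference: nx.Graph | None = None
) -> SurgeryResult:
    """Cut every edge with weight > ``threshold``; components are communities.

    Modularity of the resulting partition is evaluated on ``reference``
    (default: ``G`` itself, uncut).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    reference = G if reference is None else reference
    H = G.copy()
    cut = [(u, v) for u, v, d in H.edges(data=True) if d["weight"] > threshold]
    H.remove_edges_from(cut)
    partition = _components_partition(H)
    return SurgeryResult(
        partition=partition,
        threshold=float(threshold),
        modularity=modularity(reference, partition),
        n_cut_edges=len(cut),
    )


def best_surgery(G: nx.Graph, reference: nx.Graph | None = None) -> SurgeryResult:
    """Scan all candidate thresholds and return the modularity-maximizing cut.

    Candidates are the midpoints between consecutive distinct edge weights
    plus the maximum weight itself (cut nothing).  Ties in modularity are
    broken toward fewer communities, then toward the larger threshold.

    The scan runs incrementally: edges enter in ascending weight order and a
    union-find structure maintains the component partition together with the
    reference-graph modularity (intra-weight sum and squared degree sums),
    so the whole sweep costs O(E log N) instead of one modularity evaluation
    per candidate.
    """
    if G.number_of_edges() == 0:
        raise ValueError("surgery needs at least one edge")
    reference = G if reference is None else reference

    nodes = sorted_nodes(G.nodes)
    # union-find with per-root bookkeeping
    parent = {n: n for n in nodes}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    two_m = 2.0 * sum(d["weight"] for _, _, d in reference.edges(data=True))
    if two_m <= 0:
        raise ValueError("reference graph has zero total weight")
    deg = {n: 0.0 for n in nodes}
    for u, v, d in reference.edges(data=True):
        deg[u] += d["weight"]
        deg[v] += d["weight"]
    # per-root: degree sum, cross-weights to other roots (reference weights)
    deg_sum = dict(deg)
    cross: dict = {n: {} for n in nodes}
    for u, v, d in reference.edges(data=True):
        cross[u][v] = cross[u].get(v, 0.0) + d["weight"]
        cross[v][u] = cross[v].get(u, 0.0) + d["weight"]

    intra = 0.0  # total reference weight inside current components
    sumsq = float(np.sum(np.fromiter((deg[n] ** 2 for n in nodes), dtype=float)))
    n_comms = len(nodes)

    def q_now():
        return 2.0 * intra / two_m - sumsq / (two_m * two_m)

    edges = sorted(
        G.edges(data=True), key=lambda e: (e[2]["weight"], repr((e[0], e[1])))
    )
    weights = [d["weight"] for _, _, d in edges]
    best_thr, best_q, best_n = None, -np.inf, None
    i = 0
    while i < len(edges):
        w = weights[i]
        while i < len(edges) and weights[i] == w:
            u, v, _ = edges[i]
            ru, rv = find(u), find(v)
            if ru != rv:
                if len(cross[ru]) < len(cross[rv]):  # small-to-large merge
                    ru, rv = rv, ru
                intra += cross[ru].get(rv, 0.0)
                sumsq += (deg_sum[ru] + deg_sum[rv]) ** 2 - deg_sum[ru] ** 2 - deg_sum[rv] ** 2
                for other, cw in cross[rv].items():
                    if other == ru:
                        continue
                    cross[ru][other] = cross[ru].get(other, 0.0) + cw
                    cross[other][ru] = cross[ru][other]
                    cross[other].pop(rv, None)
                cross[ru].pop(rv, None)
                cross[rv] = {}
                deg_sum[ru] += deg_sum.pop(rv)
                parent[rv] = ru
                n_comms -= 1
            i += 1
        thr = w if i == len(edges) else 0.5 * (w + weights[i])
        q = q_now()
        # ascending sweep: later candidates have fewer communities and a
        # larger threshold, so >= implements the documented tie-breaking
        if q >= best_q:
            best_thr, best_q, best_n = thr, q, n_comms
    return surgery(G, best_thr, reference=reference)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    if set(p1) != set(p2):
        raise ValueError("partitions are defined on different node sets")
    nodes = sorted_nodes(p1)
    a = [p1[n] for n in nodes]
    b = [p2[n] for n in nodes]
    # map opaque labels to integers for sklearn
    la = {l: k for k, l in enumerate(dict.fromkeys(a))}
    lb = {l: k for k, l in enumerate(dict.fromkeys(b))}
    return float(adjusted_rand_score([la[x] for x in a], [lb[x] for x in b]))


def detect_communities(
    G: nx.Graph,
    beta: float = 1.0,
    alpha: float = 0.0,
    max_iter: int = 15,
    selection: str = "modularity",
    truth: Partition | None = None,
    config: DMKConfig | None = None,
    method: str = "dmk",
) -> tuple[dict, FlowTrace]:
    """Full pipeline: flow, per-snapshot surgery, and snapshot selection.

    ``selection="modularity"`` (deployment mode) returns the snapshot whose
    surgery partition has the highest modularity on the input graph;
    ``selection="ari"`` (benchmarking mode) needs ``truth`` and returns the
    snapshot maximizing the adjusted Rand index against it.  Isolated nodes
    become singleton communities.
    """
    ensure_weighted_graph(G)
    if selection not in ("modularity", "ari"):
        raise ValueError(f"selection must be 'modularity' or 'ari', got {selection!r}")
    if selection == "ari" and truth is None:
        raise ValueError("selection='ari' requires a ground-truth partition")

    isolated = [n for n in G.nodes if G.degree(n) == 0]
    core = G.subgraph([n for n in G.nodes if G.degree(n) > 0]).copy()
    if core.number_of_edges() == 0:
        partition = {n: k for k, n in enumerate(sorted_nodes(G.nodes))}
        return partition, FlowTrace()

    trace = run_flow(core, beta=beta, alpha=alpha, max_iter=max_iter, config=config, method=method)
    for snap, H in zip(trace.iterations, trace.graphs(core)):
        snap.surgery = best_surgery(H, reference=core)

    def full_partition(snap) -> dict:
        part = dict(snap.surgery.partition)
        next_label = len(set(part.values()))
        for k, n in enumerate(sorted_nodes(isolated)):
            part[n] = next_label + k
        return part

    if selection == "modularity":
        score = lambda snap: snap.surgery.modularity  # noqa: E731
    else:
        score = lambda snap: adjusted_rand_index(full_partition(snap), truth)  # noqa: E731

    best_snap = None
    best_score = -np.inf
    for snap in trace.iterations:
        s = score(snap)
        if s > best_score:  # earliest iteration wins ties
            best_snap, best_score = snap, s
    return full_partition(best_snap), trace


def infomap_partition(G: nx.Graph, trials: int = 10, seed: int = 0) -> dict:
    """Infomap baseline via python-igraph's built-in implementation."""
    import igraph as ig
    import random

    nodes = sorted_nodes(G.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in G.edges]
    weights = [G[u][v]["weight"] for u, v in G.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    random.seed(seed)  # igraph's infomap draws from Python's RNG
    clustering = g.community_infomap(edge_weights=weights, trials=trials)
    return {nodes[k]: comm for k, comm in enumerate(clustering.membership)}
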