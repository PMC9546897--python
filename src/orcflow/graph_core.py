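"""Graph data model, file I/O, distances, modularity and summary statistics.

The package operates on plain :class:`networkx.Graph` objects subject to a
small contract enforced by :func:`ensure_weighted_graph`: undirected, simple
(no self-loops, no parallel edges), every edge carrying a strictly positive
``weight`` attribute.  All public functions accept graphs in that form and
node identifiers of any hashable type; graphs read from disk use string
labels.

Supported file formats are GML in the Newman ``netdata`` dialect (node
``id``/``label``, edge ``source``/``target`` and optional ``value``) and
plain edge lists ``u v [w]`` separated by whitespace or commas.  Partitions
travel as two-column TSV ``node<TAB>label`` or as a JSON object.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = [
    "GraphFormatError",
    "GraphStats",
    "ensure_weighted_graph",
    "read_graph",
    "write_graph",
    "read_partition",
    "write_partition",
    "shortest_path_distance",
    "modularity",
    "normalize_weights",
    "graph_stats",
    "sorted_nodes",
]

Node = Hashable
Partition = Mapping[Node, Hashable]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of a connected graph.

    ``avg_degree`` is ``2|E|/|V|``; ``avg_betweenness`` is the mean
    normalized (weight-agnostic) shortest-path betweenness centrality and
    ``avg_clustering`` the mean unweighted local clustering coefficient.
    These are the conventions under which the classic co-appearance and
    sports-schedule datasets reproduce their published summary values.
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_betweenness: float
    avg_clustering: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_betweenness": self.avg_betweenness,
            "avg_clustering": self.avg_clustering,
        }


def sorted_nodes(nodes: Iterable[Node]) -> list:
    """Deterministically order node identifiers, even of mixed types."""
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=lambda n: (type(n).__name__, repr(n)))


def ensure_weighted_graph(G: nx.Graph) -> nx.Graph:
    """Validate the package's graph contract, returning ``G`` unchanged.

    Raises ``ValueError`` on directed input, self-loops, missing or
    non-positive edge weights, or an empty node set.
    """
    if G.is_directed() or G.is_multigraph():
        raise ValueError("expected a simple undirected graph")
    if G.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    for u, v, data in G.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop at node {u!r} is not allowed")
        w = data.get("weight", 1.0)
        if not (w > 0):
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")
        data["weight"] = float(w)
    return G


def _parse_edgelist(path: Path) -> nx.Graph:
    G = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'u v [w]', got {raw.rstrip()!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                continue  # self-loops dropped
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                ) from None
            if w <= 0:
                raise GraphFormatError(f"{path}:{lineno}: weight must be > 0")
            if not G.has_edge(u, v):  # duplicates collapsed keeping the first weight
                G.add_edge(u, v, weight=w)
    return G


def _parse_gml(path: Path) -> nx.Graph:
    try:
        raw = nx.read_gml(path, label="id")
    except Exception as exc:  # noqa: BLE001 - re-raised with file context
        raise GraphFormatError(f"{path}: GML parse failure: {exc}") from exc
    G = nx.Graph()
    # Prefer human-readable labels when present, falling back to numeric ids.
    labels = {}
    for n, data in raw.nodes(data=True):
        labels[n] = str(data.get("label", n))
    if len(set(labels.values())) != raw.number_of_nodes():
        labels = {n: str(n) for n in raw.nodes}
    G.add_nodes_from(labels.values())
    edge_iter = (
        raw.edges(data=True, keys=False) if raw.is_multigraph() else raw.edges(data=True)
    )
    for u, v, data in edge_iter:
        if u == v:
            continue
        w = float(data.get("weight", data.get("value", 1.0)))
        if not G.has_edge(labels[u], labels[v]):
            G.add_edge(labels[u], labels[v], weight=w if w > 0 else 1.0)
    return G


def read_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a graph from ``path`` as ``gml`` or ``edgelist``.

    The format is inferred from the file suffix when ``fmt`` is None.
    Missing weights default to 1, self-loops are dropped, duplicate edges
    are collapsed keeping the first weight, node labels become strings.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gml" if path.suffix.lower() == ".gml" else "edgelist"
    if fmt not in ("gml", "edgelist"):
        raise ValueError(f"unknown graph format {fmt!r}")
    G = _parse_gml(path) if fmt == "gml" else _parse_edgelist(path)
    if G.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: no nodes parsed (empty graph)")
    return ensure_weighted_graph(G)


def write_graph(G: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write ``G`` to disk; round-trips nodes, edges and weights exactly."""
    path = Path(path)
    if fmt is None:
        fmt = "gml" if path.suffix.lower() == ".gml" else "edgelist"
    if fmt == "gml":
        H = nx.relabel_nodes(G, {n: str(n) for n in G.nodes}, copy=True)
        nx.write_gml(H, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in sorted((tuple(sorted_nodes(e)) for e in G.edges)):
                fh.write(f"{u} {v} {G[u][v]['weight']!r}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_partition(path: str | Path) -> dict:
    """Read a node→label partition from TSV (``node<TAB>label``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise GraphFormatError(f"{path}: JSON partition must be an object")
        return {str(k): v for k, v in data.items()}
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node<TAB>label', got {line!r}"
                )
            out[parts[0]] = parts[1]
    return out


def write_partition(partition: Partition, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({str(k): str(v) for k, v in partition.items()}, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            for node in sorted_nodes(partition):
                fh.write(f"{node}\t{partition[node]}\n")


def shortest_path_distance(G: nx.Graph, i: Node, j: Node) -> float:
    """Weighted shortest-path distance; ``math.inf`` for disconnected pairs."""
    try:
        return float(nx.dijkstra_path_length(G, i, j, weight="weight"))
    except nx.NetworkXNoPath:
        return math.inf


def modularity(G: nx.Graph, partition: Partition) -> float:
    """Weighted Newman modularity Q = sum_c (e_cc - a_c^2) of ``partition``."""
    missing = [n for n in G.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition misses {len(missing)} node(s), e.g. {missing[0]!r}")
    groups: dict = {}
    for node in G.nodes:
        groups.setdefault(partition[node], set()).add(node)
    communities = [groups[k] for k in sorted_nodes(groups)]
    return float(nx.community.modularity(G, communities, weight="weight"))


def normalize_weights(G: nx.Graph) -> nx.Graph:
    """Return a copy of ``G`` with weights divided by their total sum."""
    if G.number_of_edges() == 0:
        raise ValueError("cannot normalize a graph with no edges")
    total = sum(data["weight"] for _, _, data in G.edges(data=True))
    if total <= 0:
        raise ValueError("total edge weight is zero")
    H = G.copy()
    for _, _, data in H.edges(data=True):
        data["weight"] = data["weight"] / total
    return H


def graph_stats(G: nx.Graph) -> GraphStats:
    """Node/edge counts, average degree, betweenness and clustering."""
    ensure_weighted_graph(G)
    n, m = G.number_of_nodes(), G.number_of_edges()
    btw = nx.betweenness_centrality(G, normalized=True)  # weight-agnostic
    return GraphStats(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        avg_betweenness=sum(btw.values()) / n,
        avg_clustering=float(nx.average_clustering(G)),
    )
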