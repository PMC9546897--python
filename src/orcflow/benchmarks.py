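"""Synthetic generators, semi-synthetic perturbations and the sweep harness.

Two planted-partition generators supply ground truth for benchmarking:

* **SBM** — N nodes in K equal blocks; an intra-block pair is an edge with
  probability ``p_intra = d K / N`` (d the expected degree) and an
  inter-block pair with probability ``r p_intra``, so small ``r`` means
  cleanly separated communities.
* **LFR** — power-law degrees (exponent tau1) and community sizes
  (exponent tau2), expected degree d, and a fraction ``mu`` of each node's
  edges crossing community borders.

Two perturbations turn a real (or synthetic) network with known
communities into noisy test instances: uniformly random adjacency-entry
*flips* (R = r |V|^2 toggles), and removal of R = r |E| *intra-community*
edges chosen uniformly among edges whose endpoints both keep degree >= 2
(so no leaves are created or touched).

``run_benchmark`` sweeps a generator parameter over seeds and betas,
scoring each run with the adjusted Rand index; ``pairwise_win_rate``
implements the trial-by-trial method comparison.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .communities import adjusted_rand_index, detect_communities
from .dmk import DMKConfig
from .graph_core import ensure_weighted_graph, sorted_nodes
from .ot_local import BipartiteOTProblem, build_local_ot_problem

__all__ = [
    "SBMParams",
    "LFRParams",
    "PerturbationParams",
    "generate_sbm",
    "generate_lfr",
    "flip_entries",
    "remove_intra_edges",
    "run_benchmark",
    "pairwise_win_rate",
    "random_local_problems",
]

Node = Hashable
Partition = Mapping[Node, Hashable]


@dataclass(frozen=True)
class SBMParams:
    """Stochastic block model parameters (equal blocks, unit weights)."""

    N: int
    K: int
    d: float
    r: float
    seed: int = 0

    @property
    def p_intra(self) -> float:
        return self.d * self.K / self.N

    def __post_init__(self):
        if self.N < self.K or self.K < 1:
            raise ValueError("need N >= K >= 1")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if not 0.0 < self.p_intra <= 1.0:
            raise ValueError(
                f"p_intra = d*K/N = {self.p_intra:.3f} must lie in (0, 1]"
            )


@dataclass(frozen=True)
class LFRParams:
    """LFR benchmark parameters.

    ``k_max_communities`` is the maximum number of communities; it is
    mapped to a minimum community size of ``N // k_max_communities``.
    """

    N: int
    tau1: float = 2.0
    tau2: float = 1.0
    d: float = 20.0
    k_max_communities: int = 50
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.tau1 <= 1:
            raise ValueError("tau1 must exceed 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")


@dataclass(frozen=True)
class PerturbationParams:
    """Perturbation intensity r, mode and seed."""

    r: float
    mode: str = "flip"  # or "remove_intra"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if self.mode not in ("flip", "remove_intra"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


def generate_sbm(params: SBMParams) -> tuple[nx.Graph, dict]:
    """Sample an SBM graph and its planted partition (deterministic in seed)."""
    rng = np.random.default_rng(params.seed)
    sizes = [params.N // params.K] * params.K
    for i in range(params.N - sum(sizes)):
        sizes[i] += 1
    labels = np.repeat(np.arange(params.K), sizes)
    G = nx.Graph()
    G.add_nodes_from(range(params.N))
    p_intra = params.p_intra
    p_inter = params.r * p_intra
    # vectorized Bernoulli draws over the upper triangle
    iu, ju = np.triu_indices(params.N, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, p_intra, p_inter)
    mask = rng.random(iu.size) < p
    G.add_edges_from(
        (int(a), int(b), {"weight": 1.0}) for a, b in zip(iu[mask], ju[mask])
    )
    truth = {int(n): int(labels[n]) for n in range(params.N)}
    return G, truth


def generate_lfr(params: LFRParams, max_tries: int = 5) -> tuple[nx.Graph, dict]:
    """Sample an LFR benchmark graph with planted communities.

    The construction needs community-size exponents strictly above 1 (its
    zipf sampler overflows as tau2 -> 1), so ``tau2`` is clamped to 1.1 from
    below; community sizes are bounded in ``[N // k_max_communities, N // 10]``.
    Retries with derived seeds when the sampler fails to satisfy the
    degree/size constraints, then raises.
    """
    tau2 = max(params.tau2, 1.1)
    min_comm = max(2, params.N // params.k_max_communities)
    max_comm = max(min_comm + 1, params.N // 10)
    # a node's intra-community degree ~ (1-mu) k must fit inside its
    # community, which caps the degree distribution
    max_degree = min(params.N - 1, int((max_comm - 1) / max(1.0 - params.mu, 1e-9)))
    last_exc: Exception | None = None
    for attempt in range(max_tries):
        seed = params.seed + 7919 * attempt
        try:
            G0 = nx.LFR_benchmark_graph(
                params.N,
                params.tau1,
                tau2,
                params.mu,
                average_degree=params.d,
                max_degree=max_degree,
                min_community=min_comm,
                max_community=max_comm,
                seed=seed,
            )
        except nx.ExceededMaxIterations as exc:
            last_exc = exc
            continue
        communities = {frozenset(G0.nodes[n]["community"]) for n in G0.nodes}
        truth = {}
        for label, comm in enumerate(sorted(map(sorted, communities))):
            for n in comm:
                truth[n] = label
        G = nx.Graph()
        G.add_nodes_from(G0.nodes)
        for u, v in G0.edges:
            if u != v:
                G.add_edge(u, v, weight=1.0)
        return G, truth
    raise RuntimeError(
        f"LFR generation failed after {max_tries} attempts: {last_exc}"
    )


def flip_entries(
    G: nx.Graph, r: float, seed: int = 0, mode: str = "count"
) -> nx.Graph:
    """Toggle adjacency entries uniformly at random.

    ``mode="count"`` (default) flips exactly ``R = round(r |V|^2)`` distinct
    unordered off-diagonal pairs; ``mode="bernoulli"`` flips each pair
    independently with probability ``r``.  Created edges get unit weight.
    """
    ensure_weighted_graph(G)
    rng = np.random.default_rng(seed)
    nodes = sorted_nodes(G.nodes)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    H = G.copy()
    if mode == "bernoulli":
        chosen = np.flatnonzero(rng.random(iu.size) < r)
    elif mode == "count":
        R = round(r * n * n)
        if R > iu.size:
            raise ValueError(
                f"R = round(r*|V|^2) = {R} exceeds the {iu.size} node pairs"
            )
        chosen = rng.choice(iu.size, size=R, replace=False)
    else:
        raise ValueError(f"unknown flip mode {mode!r}")
    for k in chosen:
        u, v = nodes[iu[k]], nodes[ju[k]]
        if H.has_edge(u, v):
            H.remove_edge(u, v)
        else:
            H.add_edge(u, v, weight=1.0)
    return H


def remove_intra_edges(
    G: nx.Graph, truth: Partition, r: float, seed: int = 0
) -> nx.Graph:
    """Remove ``R = round(r |E|)`` intra-community edges uniformly at random.

    Only edges whose two endpoints currently have degree >= 2 are eligible
    (no leaf-incident edge is ever sampled), and eligibility is re-evaluated
    after each removal so the graph never gains an isolated node.
    """
    ensure_weighted_graph(G)
    rng = np.random.default_rng(seed)
    R = round(r * G.number_of_edges())
    H = G.copy()
    for k in range(R):
        eligible = sorted(
            (u, v)
            for u, v in ((min(a, b, key=repr), max(a, b, key=repr)) for a, b in H.edges)
            if truth[u] == truth[v] and H.degree(u) >= 2 and H.degree(v) >= 2
        )
        if not eligible:
            raise RuntimeError(
                f"eligible intra-community edges exhausted after {k} of {R} removals"
            )
        u, v = eligible[int(rng.integers(len(eligible)))]
        H.remove_edge(u, v)
    return H


def run_benchmark(
    generator: Callable[[float, int], tuple[nx.Graph, dict]],
    param_values: Sequence[float],
    betas: Sequence[float],
    n_seeds: int = 10,
    max_iter: int = 15,
    selection: str = "ari",
    config: DMKConfig | None = None,
    method: str = "dmk",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Sweep ``generator(param, seed)`` over parameters, seeds and betas.

    Returns one row per (param, beta, seed) with the ARI of the detected
    partition against the planted one, the number of communities found and
    the flow iteration that was selected.
    """
    import warnings

    rows = []
    for value in param_values:
        for s in range(n_seeds):
            seed = base_seed + s
            G, truth = generator(value, seed)
            for beta in betas:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    part, trace = detect_communities(
                        G,
                        beta=beta,
                        max_iter=max_iter,
                        selection=selection,
                        truth=truth if selection == "ari" else None,
                        config=config,
                        method=method,
                    )
                ari = adjusted_rand_index(part, truth)
                best_iter = 0
                if len(trace):
                    scores = [
                        adjusted_rand_index(
                            {**s_.surgery.partition}, {k: truth[k] for k in s_.surgery.partition}
                        )
                        if selection == "ari"
                        else s_.surgery.modularity
                        for s_ in trace.iterations
                    ]
                    best_iter = int(np.argmax(scores))
                rows.append(
                    {
                        "generator_param": value,
                        "beta": beta,
                        "seed": seed,
                        "ari": ari,
                        "n_communities": len(set(part.values())),
                        "iterations_used": best_iter,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of ARI per (generator_param, beta) cell."""
    return (
        df.groupby(["generator_param", "beta"])["ari"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "ari_mean", "std": "ari_std", "count": "n"})
    )


def pairwise_win_rate(
    results_a: Sequence[float], results_b: Sequence[float], ties: str = "a"
) -> float:
    """Fraction of paired instances where method A outperforms method B.

    ``ties`` controls how equal scores count: ``"a"`` (default) credits A,
    ``"half"`` credits each method half a win, ``"exclude"`` drops the pair.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score lists must have equal length")
    if a.size == 0:
        raise ValueError("empty score lists")
    wins = np.sum(a > b)
    eq = np.sum(a == b)
    if ties == "a":
        return float((wins + eq) / a.size)
    if ties == "half":
        return float((wins + 0.5 * eq) / a.size)
    if ties == "exclude":
        denom = a.size - eq
        return float(wins / denom) if denom else 0.5
    raise ValueError(f"unknown tie policy {ties!r}")


def sbm_generator(N: int, K: int, d: float) -> Callable[[float, int], tuple[nx.Graph, dict]]:
    """Generator closure for :func:`run_benchmark` sweeping the SBM ratio r."""

    def gen(r: float, seed: int) -> tuple[nx.Graph, dict]:
        return generate_sbm(SBMParams(N=N, K=K, d=d, r=r, seed=seed))

    return gen


def lfr_generator(
    N: int, tau1: float = 2.0, tau2: float = 1.0, d: float = 20.0, k_max: int = 50
) -> Callable[[float, int], tuple[nx.Graph, dict]]:
    """Generator closure for :func:`run_benchmark` sweeping the LFR mixing mu."""

    def gen(mu: float, seed: int) -> tuple[nx.Graph, dict]:
        return generate_lfr(
            LFRParams(N=N, tau1=tau1, tau2=tau2, d=d, k_max_communities=k_max, mu=mu, seed=seed)
        )

    return gen


def random_local_problems(
    n_problems: int, seed: int, max_side: int = 8
) -> list[BipartiteOTProblem]:
    """Random transport-oracle instances with *metric* costs.

    Each instance is the local bipartite problem of a random edge of a
    random connected weighted graph, so costs are shortest-path distances
    (a metric).  Metric costs are required for the beta=1 steady state to
    coincide with the LP transport optimum: with arbitrary cost matrices
    the flux may route through alternating paths that undercut any
    transport plan.
    """
    rng = np.random.default_rng(seed)
    problems: list[BipartiteOTProblem] = []
    while len(problems) < n_problems:
        n = int(rng.integers(5, max_side + 1))
        G = nx.gnp_random_graph(n, 0.55, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0 or not nx.is_connected(G):
            continue
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        edges = sorted(G.edges)
        u, v = edges[int(rng.integers(len(edges)))]
        problems.append(build_local_ot_problem(G, u, v, alpha=0.0))
    return problems
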