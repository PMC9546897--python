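# orcflow

Community detection on weighted undirected networks by **Ollivier–Ricci
curvature flow**, with the transport problems behind the curvature solved by
a **dynamical Monge–Kantorovich (DMK)** system whose traffic rate
`β ∈ (0, 2]` tunes between congested (`β < 1`) and branched (`β > 1`)
transport. The package is aimed at network scientists who want a
geometry-based community detector that learns the number of communities from
the data, plus the synthetic benchmarks (SBM, LFR) and robustness protocols
to evaluate it.

## The method

For an edge `(i, j)` of a weighted graph `G`, put the lazy one-step
distribution on each endpoint's neighborhood,

    m_i^α(k) = α              if k = i,
               (1-α)/|N(i)|   if k ∈ N(i),

(`α = 0` throughout the benchmarks) and measure the cost of transporting
`m_i` into `m_j` over a complete bipartite auxiliary graph whose pair costs
are shortest-path distances in `G` (zero between the two copies of one
node). The transport problem is solved by the DMK system

    B diag(μ/w) Bᵀ u = f,      μ̇ₑ = (μₑ |(Bᵀu)ₑ| / wₑ)^β − μₑ,   μₑ(0) > 0,

whose steady-state flux `q*` yields the **β-Wasserstein cost**
`W_β = Σₑ q*ₑ wₑ` (at `β = 1` this is the exact 1-Wasserstein distance).
The edge curvature is

    κ_β(i, j) = 1 − W_β(m_i, m_j) / d_ij ,

positive inside well-connected groups, negative on bridges. The **Ricci
flow** replaces every weight by `d_ij (1 − κ_β) = W_β` and renormalizes,
shrinking intra-community edges and stretching bridges; after each of the
(default 15) iterations, **surgery** cuts all edges above a threshold chosen
by maximizing Newman modularity over all candidate cuts, and the connected
components are the communities. No prior number of communities is needed.

## Worked example

```python
import networkx as nx
from orcflow import curvature_all_edges, detect_communities

# two 4-cliques joined by a bridge
G = nx.Graph()
for base in (0, 4):
    for a in range(4):
        for b in range(a + 1, 4):
            G.add_edge(base + a, base + b, weight=1.0)
G.add_edge(3, 4, weight=1.0)

kappa = curvature_all_edges(G, beta=1.0)
print(round(kappa.get(0, 1), 3), round(kappa.get(3, 4), 3))

partition, trace = detect_communities(G, beta=1.0, max_iter=15)
best = max(s.surgery.modularity for s in trace.iterations)
print(sorted(set(partition.values())), round(best, 4))
```

prints

```
0.667 -1.0
[0, 1] 0.4231
```

The clique edge has strongly positive curvature 0.667 (most mass moves for
free between the overlapping neighborhoods) while the bridge has κ = −1
(all mass must cross between the cliques); the flow plus surgery recovers
the two cliques with modularity 0.4231 = 12/13 − 1/2, the exact hand value
for this 13-edge graph.

The same pipeline from the shell:

```
orcflow detect graph.txt --beta 1.0 --max-iter 15 -o partition.tsv
orcflow curvature graph.txt --beta 0.5 -o curvature.csv
orcflow stats graph.gml
orcflow benchmark-sbm --n 150 --k 3 --d 15 --r 0.01 --r 0.5 --beta 2 --n-seeds 5 -o sweep.csv
```

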