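# Methods

## Model

A community, for this package, is a set of nodes whose members see similar
neighborhoods: if `(i, j)` is an intra-community edge, the one-step
distributions `m_i^α` and `m_j^α` overlap heavily and little transport work
is needed to turn one into the other. The per-edge transport problem lives
on a complete bipartite auxiliary graph — left side `N(i) ∪ {i}`, right
side `N(j) ∪ {j}`, pair costs equal to weighted shortest-path distances in
the ambient graph, zero between the two copies of a shared node — with
forcing `f = m_i − m_j`. The curvature `κ_β = 1 − W_β/d_ij` compares the
transport cost to the endpoints' own distance; the discrete Ricci flow
`w ← d(1−κ_β) = W_β` (followed by normalization of the weights by their
total sum) contracts intra-community edges and stretches bridges until
surgery can separate the groups.

Assumptions worth stating explicitly:

* **Metric costs.** The bipartite pair costs are shortest-path distances,
  hence a metric. This matters: the DMK solver computes a minimum-cost
  *flow* on the bipartite graph, and only for metric costs does that
  coincide with the minimum-cost transport *plan* (with arbitrary cost
  matrices, alternating paths through cheap pairs can undercut every plan).
  All oracle tests therefore draw random instances as genuine local
  problems of random weighted graphs rather than as arbitrary matrices.
* **Assortative structure.** Neighborhood overlap signals communities only
  when connection patterns are denser inside groups than between them.
  Mixed assortative/disassortative structure confuses the contraction and
  is out of scope.
* `α` (mass kept on the center node) defaults to 0, matching the benchmark
  protocol; `α > 0` is supported but not benchmarked.

## DMK solver numerics

The conductivity dynamics are integrated by explicit Euler.

| parameter | default | meaning |
|---|---|---|
| `beta` | 1.0 | traffic rate in (0, 2]; <1 congested, >1 branched |
| `dt` | 0.2 | Euler step (dimensionless relaxation time) |
| `tol` | 1e-5 | stagnation tolerance (see below) |
| `max_steps` | 2000 | iteration cap; exceeded ⇒ `converged=False` warning |
| `mu0` | 1.0 | uniform initial conductivity |
| `eps_cost` | 1e-6 | zero-cost regularizer, *relative* to the problem's largest cost |

`dt = 0.2` is stable for every `β ∈ (0, 2]` on all tested problem classes
and measurably more accurate against the LP oracle than smaller steps at a
fixed step budget (stragglers get further before the cap).

**Zero-cost pairs.** The copies of one node on the two bipartite sides are
connected at cost 0; inside the solver this weight becomes
`eps_cost × max(cost)` so the conductance `μ/w` stays finite. Reported
costs always use the true zeros. The epsilon is relative because the Ricci
flow shrinks intra-community distances without bound — an absolute epsilon
would eventually exceed the real costs.

**Background conductance.** The potential solve adds a uniform
`1e-13 × max(μ/w)` to every conductance, *only* inside the linear system.
Without it, branched dynamics (`β > 1`) switches edges off until the
bipartite problem disconnects and the pinned Laplacian turns exactly
singular, and the conductivity dynamic range (up to ~1e23 with hard floors)
lets factorization noise drive relaxation oscillations. With it the
effective condition number is bounded near 1e12 and the flux perturbation
is ~1e-12 relative. Conductivities are floored at 1e-12.

**Convergence.** Primary criterion: the relative conductivity change per
unit time, `max_e |Δμ_e| / (dt · max_e μ_e)`, and the relative per-step cost
change both below `tol` for 10 consecutive steps. The denominator is the
*global* maximum conductivity: dying edges decay exponentially forever and
a per-edge denominator would never stagnate. Fallback: if the cost moved
by less than `tol` (relative) over a whole 50-step window, the integration
also stops — transport problems with degenerate optima (symmetric cliques,
collapsed metric regions) keep drifting conductivity along the optimal face
indefinitely while the cost, the only quantity the curvature consumes, is
converged to machine precision. Consequence: at termination the cost is
stationary, but `μ = q^β` stationarity is only guaranteed edge-wise in the
congested regimes; at `β > 1` flux may still be migrating between
equal-cost routes.

**Batching.** The flow driver solves all per-edge problems of an iteration
side by side, grouped into buckets padded to side lengths that are
multiples of 4. Padding entries carry zero conductivity and zero forcing
and are pinned out of the linear system; they change floating-point
summation order only, so batched and one-at-a-time solves agree to ~1e-12
relative rather than bitwise. Within a bucket, finished problems are
compacted out of the arrays.

**Warm start.** Across flow iterations the metric deforms slowly, so each
iteration's solves start from the previous iteration's steady-state
conductivities (a continuation); iteration 0 starts from the uniform
`mu0`. Cold start is the default for standalone solves. This roughly
halves the benchmark runtime and leaves all tested community outcomes
unchanged; note that for `β > 1`, where steady states need not be unique,
the continuation selects among them deterministically.

## Flow and surgery conventions

* `d^(t)` is recomputed as the all-pairs shortest-path distance on the
  current normalized weights at every iteration; an edge's own weight is
  not used as a shortcut (after a few iterations a two-hop path is often
  shorter than the direct edge).
* Initial weights are `w^(0) = d^(0)` (then normalized); the trace records
  `max_iter + 1` snapshots, each holding the normalized weights together
  with the curvatures, transport costs and distances computed *on* them.
* Updated weights are floored at 1e-12 before normalization, so an edge
  whose endpoints' neighborhoods coincide (`W_β ≈ 0`, `κ = 1`) cannot
  produce a zero-length edge and corrupt later shortest paths.
* Surgery cuts every edge heavier than a threshold; candidate thresholds
  are the midpoints between consecutive distinct weights plus the maximum
  weight. The scan is incremental: edges enter in ascending weight order,
  a union-find structure merges components, and the modularity of the
  current partition is maintained from the intra-component weight sum and
  the squared degree sums of the *reference* graph (O(E log N) per sweep).
  Modularity is evaluated against the original input graph, not the flowed
  weights — communities are claims about the input network. Ties in
  modularity break toward fewer communities, then larger thresholds.
* Snapshot selection: `modularity` (deployment; no ground truth needed) or
  `ari` (benchmark protocol: the iteration maximizing agreement with the
  planted partition). Isolated nodes become singleton communities.

## Synthetic generators

**SBM.** N nodes in K equal blocks (remainder spread one-per-block);
intra-block edge probability `p_intra = dK/N`, inter-block `r·p_intra`,
unit weights, vectorized Bernoulli draws from a seeded generator. The
benchmark conditions used by the tests and the acceptance script are
`N = 150, K = 3, d = 15, β = 2`, five seeds, ARI-maximizing iteration,
with `r = 0.01` (well separated) and `r = 0.5` (near-indistinguishable);
N is scaled down from the common N = 500 setting, which leaves the two
regimes' qualitative outcomes (ARI ≈ 1 vs ARI ≈ 0) intact.

**LFR.** Wraps the networkx LFR construction. Power-law exponents
`τ1 = 2` (degrees) and `τ2 = 1` (community sizes) with expected degree 20
and at most 50 communities are the reference parameterization; two
mappings are needed because networkx parameterizes differently: `τ2` is
clamped to 1.1 (the zipf sampler diverges as `τ2 → 1`), and the community
count bound becomes size bounds `[N/K_max, N/10]` with the maximum degree
capped at `(max_community − 1)/(1 − μ)` so every node's intra-community
degree fits inside a community. At `N = 500, μ = 0.35` this plants 19–22
communities. Reproduction is statistical, not instance-level.

**Perturbations.** *Entry flipping* toggles exactly `R = round(r·|V|²)`
distinct unordered node pairs chosen uniformly (an independent
Bernoulli(r) mode is also provided). *Intra-community edge removal* deletes
`R = round(r·|E|)` within-community edges uniformly among edges whose two
endpoints currently have degree ≥ 2, re-evaluating eligibility after every
removal so no leaf-incident edge is ever sampled and no node is isolated.

**What the generators do not emulate:** weighted real-world edges, degree
assortativity, overlapping membership, and metadata-derived "ground truth"
whose communities need not be structural. Passing the synthetic benchmarks
shows the pipeline separates planted assortative structure at the stated
densities; it does not guarantee agreement with metadata partitions of
real networks.

## Baselines

The Sinkhorn-curvature baseline runs the identical flow/surgery pipeline
but computes each edge's transport cost by entropically regularized
Sinkhorn iterations (log-domain, regularization 1e-3, plan rounded onto
the transport polytope so the reported cost is always feasible). The
Infomap baseline uses python-igraph's built-in implementation with 10
trials. The win-rate protocol scores two methods trial-by-trial on
perturbed instances; ties count for the first method by default
(configurable: `half`, `exclude`).

## Known limitations

* Like other curvature-flow detectors, the method over-fragments sparse or
  hub-and-spoke communities (many singleton/small communities in the hard
  regime); no automatic reattachment is performed.
* `β = 2` sits at the edge of the admissible range; branched steady states
  need not be unique, and only cost-level (not flux-level) convergence is
  guaranteed there.
* The LP equivalence at `β = 1` presumes metric costs (always true for the
  pipeline's own problems; not true for arbitrary user-supplied cost
  matrices).
* Runtime is dominated by the per-edge transport solves:
  O(|E| · steps · s³) per flow iteration for neighborhood size s, so dense
  graphs with large hubs are expensive.
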