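# Methods

This note records the model, the conventions chosen where a definition
admitted more than one reading, the synthetic study conditions, and the
numerical details a user needs to interpret results.

## Influence model

Graphs are undirected, unweighted and simple. Every node `i` carries an
adoption threshold `T_i`, either **absolute** (an integer count of
activated neighbors, `T_i ≥ 1`) or **fractional** (a fraction of the
neighborhood, `0 < T_i ≤ 1`). Thresholds are **homogeneous** (one value
for all nodes) or **heterogeneous** (drawn i.i.d. uniformly from an
interval: uniform integers for absolute mode, uniform reals for
fractional mode; one draw per network realization, reproducible under
the seed).

Dynamics are discrete-time and synchronous: at each step every inactive
node whose number of active neighbors reaches its effective threshold
activates, and active nodes stay active. Because activation is
monotone, the final active set is the unique minimal fixed point
containing the seeds; synchronous and asynchronous schedules yield the
same fixed point, which the test suite verifies against a brute-force
asynchronous scanner on exhaustive small-graph ensembles.

**Fractional → count conversion.** A fractional threshold `T_i` on a
node of degree `d` demands `ceil(T_i · d)` active neighbors — the
smallest count satisfying the stated fraction — floored at 1. Isolated
nodes in fractional mode degenerate to 1 (logged; they can still only
activate as seeds).

## Bridge width

For an ordered pair `(i, j)` with closed neighborhoods `N[i]`, `N[j]`
and induced neighborhood edge sets `E(N[·])`:

* overlap `O_ij = N[i] ∩ N[j]`; disjoint set `D_ij = N[j] \ N[i]`;
* reinforcement set `R_ij = {v ∈ D_ij : |E(N[i]) ∩ E(N[v])| ≥ 1}`;
* bridge `BW_ij = O_ij ∪ R_ij`, width `W_ij = |BW_ij|`; since
  `R_ij ⊆ D_ij` is disjoint from `N[i] ⊇ O_ij`,
  `W_ij = |O_ij| + |R_ij|`;
* sufficiency `[W_ij] = 1` iff `W_ij ≥ T_j` (effective threshold in
  fractional mode).

Two readings of the reinforcement condition are possible: the formal
edge-set condition above (an edge inside `N[i]` whose endpoints are
both adjacent to `v`), or the looser "adjacent to some member of
`N[i]`". The formal condition is the default because it is the only
unambiguous statement; the looser variant stays available behind
`bridge_report(..., prose_reinforcement=True)` for sensitivity
analysis.

Under **heterogeneous** thresholds the reinforcement set keeps only
nodes the source neighborhood could actually activate:
`x ∈ R_ij` additionally requires `|N[i] ∩ N[x]| ≥ T_x`. The filter is
applied only when the assignment is heterogeneous, matching the scope
under which it is defined.

**Local sufficiency.** `B_i` is the set of nodes `v ≠ i` with
`W_vi ≥ 1` (width *toward* `i`), while the numerator of
`LB_i = (1/|B_i|) Σ_{x∈B_i} [W_ix]` scores bridges *outward* from `i`.
The two directions follow the respective defining formulas literally;
width is not assumed symmetric. `LB_i = 0` when `B_i = ∅` (isolated or
degenerate positions; logged), which keeps the graph average total.
`LB` is the mean of `LB_i` over all nodes.

**Exact candidate pruning.** Any `v` with `W_vi ≥ 1` lies within
shortest-path distance 3 of `i`: overlap members force distance ≤ 2,
and a reinforcement member `x ∈ N[i]` sharing an edge inside `N[v]`
forces distance ≤ 3. Partner searches therefore scan only the radius-3
ball — a pruning, not an approximation; tests compare against an
unpruned all-pairs oracle. For homogeneous absolute thresholds, widths
do not depend on `T`, so `graph_lb_absolute_curve` computes the width
sweep once and reads `LB` off it for every `T` (tested exactly equal to
the per-`T` computation).

## Complex path length and complex centrality

`CP_ij` is the subgraph induced on the nodes activated by seeding the
entire closed neighborhood `N[i]` at `t = 0` and running the threshold
dynamics to fixation. The activated set does not depend on the target,
so one cascade per source serves all targets. If `j` never activates,
`PL_c_ij = 0`. Otherwise `PL_c_ij` is the **vertex count** of a
shortest `i → j` path inside `CP_ij` (every activated node is reachable
from `i` there, since activation chains back to `N[i]` and all seeds
are adjacent to `i`). The vertex-count convention makes the `T = 1`
limit equal hop count + 1; reachable non-neighbor targets always score
≥ 3. BFS ties are broken lexicographically for a reproducible geodesic;
only the length is consumed downstream.

`PL_c_i` sums `PL_c_ij` over targets `j ∉ N[i]` and divides by
`n − |N[i]|`; when `N[i]` covers the whole graph the node has no
targets and scores 0. `PL_c` is the mean of `PL_c_i` over nodes.
Complex centrality is `CC_i = PL_c_i`; argmax ties are broken by
smallest node label (logged), with random tie-breaking available in the
tournament harness via its seed.

When the true threshold is unknown (e.g., empirical data),
`ensemble_complex_centrality` averages `CC_i` over homogeneous absolute
`T = 2..6` by default.

## Baseline centralities

Degree, shortest-path betweenness, eigenvector (principal eigenvector
per connected component; two-node components get the closed-form
uniform vector, singletons 0), coreness, closeness (inverse mean
distance to reachable nodes), reach (nodes within radius 2 by default),
and collective-influence "percolation" centrality
`(deg_i − 1) · Σ_{j: d(i,j)=d} (deg_j − 1)` with `d = 3` by default.
The greedy baseline ranks every node by its own mean simulated adoption
(individual performance, not submodular set optimization); under the
threshold model each focal's trial seeds are built with the clustered
`T − 1` rule below, under Independent Cascade / Linear Threshold the
focal alone is seeded.

## Seeding protocol

A focal node's seed set is itself plus `budget − 1` uniformly sampled
neighbors; when the budget exceeds the neighborhood, nodes adjacent to
the already-selected set are sampled iteratively (clustered seeding)
until the budget is met, or the smaller set is returned with a warning.
The minimal triggering budget for a focal under the threshold model is
its effective threshold (focal + `T_i − 1` neighbors); the same rule
extends to fractional thresholds through the ceiling conversion. A run
counts as a **global cascade** when final adoption reaches 0.5 of the
population (inclusive); the cutoff is a configuration knob, and no
reported statistic depends on its exact value.

## Synthetic ensembles

* **Rewired ring lattices.** A ring of `n` nodes, each tied to its
  `k/2` nearest neighbors per side, then each lattice edge visited once
  in random order and, with probability `p`, double-edge-swapped with a
  uniformly chosen partner edge; swaps creating self-loops or
  multi-edges are rejected. Degrees are exactly preserved at every `p`
  (every node keeps degree `k`), clustering decays with `p`, and
  connectivity is *not* enforced — high-`p` realizations may fragment,
  and consumers that need connectivity check it explicitly.
* **Clustering-tunable scale-free graphs.** Growth with `m` edges per
  arriving node and triad formation with probability `triad_p`
  (preferential attachment plus triangle closure), giving a power-law
  tail with exponent ≈ 3 and tunable clustering. The experiments use
  `m = 4`, `triad_p = 0.5`.

These generators reproduce the topological features the measures
respond to — degree heterogeneity, clustering, bridge structure — but
not homophily, community structure, degree assortativity or edge
weights of real social networks. Passing tests demonstrate the measures
behave as claimed on these ensembles, not that any empirical network
matches them.

## Experiment designs and problem sizes

* **Cascades vs. LB (lattices):** `n = 200`, `k = 8`,
  `p ∈ {0, 1}`, homogeneous absolute `T ∈ {2, 3, 4}`, 10 realizations
  per cell, every node tried as focal once per realization. One graph
  per (p, realization) is shared across threshold values.
* **PL_c vs. adoption (scale-free):** `n = 300`, `m = 4`,
  `triad_p = 0.5`; homogeneous fractional `T ∈ {0.1..0.5}` with 10
  independent realizations per condition (50 points pooled), and
  heterogeneous `T_i ~ U[0.1, 0.5]` with 50 realizations. Adoption is
  the mean over *all* neighborhood seedings, which is deterministic
  given the graph and thresholds, so no per-point Monte-Carlo noise
  enters. Spearman correlations are reported with two-tailed p and a
  seeded bootstrap percentile 95% CI (the CI method is a package
  choice).
* **Seeding tournament:** per network and per homogeneous absolute `T`,
  each strategy's top node is seeded with the clustered `T`-budget rule
  over repeated trials; adoption and focal complex centrality are
  min–max normalized within each (network, T) cell (constant cells
  collapse to 0, logged), averaged over `T`, and compared with
  two-tailed Wilcoxon signed-rank tests.

These sizes are the package's desk-scale defaults; the published-scale
ensembles (n = 1000, 50 realizations, T up to 6) are reached by raising
`n`, `realizations` and `t_specs` in `ExperimentConfig`.

**Reproducibility.** Every stochastic sub-task derives its generator
from the master seed via `numpy.random.SeedSequence(master,
spawn_key=loop_indices)`, so results are independent of execution
order; identical configs produce identical tables.

## Known limitations

* Bridge and path computations are exact set algebra, quadratic-ish in
  local neighborhood sizes; they are intended for graphs up to a few
  thousand nodes, not millions.
* Directed, weighted and bipartite networks are out of scope, as is
  estimating thresholds from empirical adoption timing.
* `LB_i` and `PL_c_i` adopt totalizing conventions (0 for empty partner
  sets / covered graphs); comparisons across graphs with many such
  degenerate nodes should keep that in mind.
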