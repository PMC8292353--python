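"""Complex path length: network distance for threshold contagions.

The complex path from node i to node j is the route a threshold
contagion takes when i's entire closed neighborhood N[i] is activated
at time 0. If the dynamics never reach j, the pair is socially
disconnected and the complex path length is 0. Otherwise the activated
nodes induce a subgraph CP_ij, the geodesic from i to j inside that
subgraph is the shortest complex path, and its length PL_c_ij is the
number of vertices in that geodesic. Note that for a simple contagion
(T = 1) this reduces to the ordinary shortest path (hop count + 1
vertices), so complex path length generalizes, rather than replaces,
simple path length.

Averaging PL_c_ij over all targets outside N[i] gives the node-level
PL_c_i (which doubles as the node's complex centrality), and averaging
that over the graph gives the graph-level PL_c.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .contagion import ThresholdAssignment, run_threshold_model
from .graphs import closed_neighborhood

__all__ = [
    "ComplexPathResult",
    "NodeComplexPathProfile",
    "complex_path",
    "node_complex_path_profile",
    "node_complex_path_length",
    "graph_complex_path_length",
]


def _sort_key(node):
    return (str(type(node)), str(node))


@dataclass(frozen=True)
class ComplexPathResult:
    """Shortest complex path from N[i] to a single target j."""

    source: object
    target: object
    activated: frozenset   # CP_ij vertex set (empty if j unreached)
    geodesic: tuple        # vertex sequence φ from i to j, () if unreached
    length: int            # PL_c_ij = |φ|, 0 if unreached


@dataclass(frozen=True)
class NodeComplexPathProfile:
    """One neighborhood-seeded cascade serving every target of node i."""

    node: object
    activated: frozenset          # final active set when seeding N[i]
    lengths: Mapping              # target j (outside N[i]) -> PL_c_ij
    plc: float                    # PL_c_i, Eq.-style average over targets
    adoption_fraction: float      # |activated| / n


def _cascade_distances(graph: nx.Graph, i, thresholds: ThresholdAssignment):
    """Run the neighborhood-seeded cascade and BFS inside the active set.

    Returns (active set, dict of hop distances from i within the
    induced subgraph on the active set). Every activated node is
    reachable from i inside that subgraph: activation spreads along
    edges from N[i], whose members are all adjacent to i.
    """
    seeds = closed_neighborhood(graph, i)
    trace = run_threshold_model(graph, thresholds, seeds)
    active = trace.active_set
    dist = {i: 0}
    queue = deque([i])
    while queue:
        u = queue.popleft()
        for w in graph[u]:
            if w in active and w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return active, dist


def complex_path(
    graph: nx.Graph, i, j, thresholds: ThresholdAssignment
) -> ComplexPathResult:
    """Shortest complex path from N[i] to j, with its geodesic.

    Seeds the closed neighborhood N[i], runs synchronous threshold
    dynamics to fixation, and — if j activated — extracts a shortest
    i-to-j path by breadth-first search inside the subgraph induced on
    the activated set. Neighbor ties are broken lexicographically so
    the reported geodesic is reproducible; only its length is used
    downstream.
    """
    if i == j:
        raise ValueError("complex path is defined for distinct nodes only")
    active, dist = _cascade_distances(graph, i, thresholds)
    if j not in active or j not in dist:
        return ComplexPathResult(i, j, frozenset(), (), 0)
    # Walk back from j along strictly decreasing BFS distance.
    path = [j]
    current = j
    while current != i:
        current = min(
            (w for w in graph[current] if w in dist and dist[w] == dist[current] - 1),
            key=_sort_key,
        )
        path.append(current)
    path.reverse()
    return ComplexPathResult(i, j, active, tuple(path), len(path))


def node_complex_path_profile(
    graph: nx.Graph, i, thresholds: ThresholdAssignment
) -> NodeComplexPathProfile:
    """Per-target complex path lengths of node i from a single cascade.

    The activated set does not depend on the target, so one
    neighborhood-seeded run serves all targets. Targets are the nodes
    outside N[i]; unreached targets contribute 0. PL_c_i is the sum of
    target lengths divided by ``n - |N[i]|`` (0 when N[i] covers the
    whole graph).
    """
    n = graph.number_of_nodes()
    neighborhood = closed_neighborhood(graph, i)
    active, dist = _cascade_distances(graph, i, thresholds)
    lengths = {}
    for j in graph.nodes():
        if j in neighborhood:
            continue
        d = dist.get(j)
        lengths[j] = (d + 1) if (j in active and d is not None) else 0
    denom = n - len(neighborhood)
    plc = sum(lengths.values()) / denom if denom > 0 else 0.0
    return NodeComplexPathProfile(
        node=i,
        activated=active,
        lengths=lengths,
        plc=plc,
        adoption_fraction=len(active) / n,
    )


def node_complex_path_length(
    graph: nx.Graph, i, thresholds: ThresholdAssignment
) -> float:
    """PL_c_i: mean complex path length from N[i] to targets outside N[i]."""
    return node_complex_path_profile(graph, i, thresholds).plc


def graph_complex_path_length(graph: nx.Graph, thresholds: ThresholdAssignment) -> float:
    """PL_c: mean of PL_c_i over all nodes of the graph."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph must be nonempty")
    return sum(node_complex_path_length(graph, i, thresholds) for i in graph.nodes()) / n
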