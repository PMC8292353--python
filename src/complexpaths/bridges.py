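"""Bridge width between neighborhoods and locally sufficient bridges.

A complex contagion hops between the closed neighborhoods N[i] and
N[j] only if the "bridge" linking them is wide enough. The bridge from
i toward j is the union of

* the overlap ``O_ij = N[i] ∩ N[j]``, and
* the reinforcement set ``R_ij``: nodes of ``D_ij = N[j] \\ N[i]`` that
  share at least one edge of the induced neighborhood edge set,
  ``|E(N[i]) ∩ E(N[v])| >= 1``.

Its width ``W_ij = |O_ij| + |R_ij|`` (the two sets are disjoint) is
compared against the target's threshold: the bridge is *sufficient*
when ``W_ij >= T_j``. Under heterogeneous thresholds the reinforcement
set is additionally restricted to nodes the source neighborhood can
actually activate (``|N[i] ∩ N[x]| >= T_x``).

Averaging sufficiency over each node's bridge partners, and then over
the graph, yields the fraction of locally sufficient bridges (LB) — a
connectedness measure for complex contagions that plays the role the
giant-component fraction plays for simple ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .contagion import ThresholdAssignment, effective_threshold
from .graphs import closed_neighborhood, neighborhood_edge_set

logger = logging.getLogger(__name__)

__all__ = [
    "BridgeReport",
    "bridge_report",
    "bridge_partners",
    "local_sufficiency",
    "graph_LB",
    "graph_lb_absolute_curve",
]


class NeighborhoodCache:
    """Memoized closed neighborhoods and induced neighborhood edge sets.

    Bridge computations touch N[v] and E(N[v]) of the same nodes many
    times; one cache per graph keeps the all-pairs sweeps linear in the
    work actually needed.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._closed: dict = {}
        self._edges: dict = {}

    def closed(self, v) -> frozenset:
        got = self._closed.get(v)
        if got is None:
            got = self._closed[v] = closed_neighborhood(self.graph, v)
        return got

    def edge_set(self, v) -> frozenset:
        got = self._edges.get(v)
        if got is None:
            got = self._edges[v] = neighborhood_edge_set(self.graph, v)
        return got


@dataclass(frozen=True)
class BridgeReport:
    """Bridge structure for the ordered pair (i, j)."""

    source: object
    target: object
    overlap: frozenset       # O_ij
    disjoint: frozenset      # D_ij
    reinforcement: frozenset  # R_ij
    bridge: frozenset        # BW_ij = O_ij ∪ R_ij
    width: int               # W_ij
    sufficient: bool         # [W_ij] against T_j


def bridge_report(
    graph: nx.Graph,
    i,
    j,
    thresholds: ThresholdAssignment,
    cache: NeighborhoodCache | None = None,
    prose_reinforcement: bool = False,
) -> BridgeReport:
    """Compute the bridge from N[i] toward node j.

    Parameters
    ----------
    prose_reinforcement : bool
        Alternative reinforcement rule for sensitivity checks: a node
        of ``D_ij`` qualifies merely by being adjacent to some member
        of N[i], instead of the default (stricter) requirement of
        sharing an edge of the induced neighborhood edge sets.
    """
    if i == j:
        raise ValueError("bridge is defined for distinct nodes only")
    if cache is None:
        cache = NeighborhoodCache(graph)
    n_i = cache.closed(i)
    n_j = cache.closed(j)
    overlap = n_i & n_j
    disjoint = n_j - n_i
    if prose_reinforcement:
        reinforcement = {v for v in disjoint if any(u in n_i for u in graph[v])}
    else:
        e_i = cache.edge_set(i)
        reinforcement = {v for v in disjoint if e_i & cache.edge_set(v)}
    if thresholds.heterogeneous:
        reinforcement = {
            x
            for x in reinforcement
            if len(n_i & cache.closed(x)) >= effective_threshold(x, graph, thresholds)
        }
    bridge = overlap | frozenset(reinforcement)
    width = len(bridge)
    sufficient = width >= effective_threshold(j, graph, thresholds)
    return BridgeReport(
        source=i,
        target=j,
        overlap=frozenset(overlap),
        disjoint=frozenset(disjoint),
        reinforcement=frozenset(reinforcement),
        bridge=frozenset(bridge),
        width=width,
        sufficient=sufficient,
    )


def _candidates_within_three(graph: nx.Graph, i) -> set:
    """Nodes at shortest-path distance 1..3 from i.

    Any node v with a nonempty bridge toward i (W_vi >= 1) lies within
    distance 3: overlap members force distance <= 2, and a
    reinforcement member x in N[i] sharing an edge inside N[v] forces
    distance <= 3. Restricting the partner search to this ball is
    exact, not an approximation.
    """
    dist = nx.single_source_shortest_path_length(graph, i, cutoff=3)
    return {v for v in dist if v != i}


def bridge_partners(
    graph: nx.Graph,
    i,
    thresholds: ThresholdAssignment,
    cache: NeighborhoodCache | None = None,
) -> frozenset:
    """B_i: nodes v != i whose bridge toward i has positive width W_vi."""
    if cache is None:
        cache = NeighborhoodCache(graph)
    return frozenset(
        v
        for v in _candidates_within_three(graph, i)
        if bridge_report(graph, v, i, thresholds, cache=cache).width >= 1
    )


def local_sufficiency(
    graph: nx.Graph,
    i,
    thresholds: ThresholdAssignment,
    cache: NeighborhoodCache | None = None,
) -> float:
    """LB_i: fraction of i's bridge partners reached by a sufficient bridge.

    Partnership is judged by the width toward i (``W_vi >= 1``) while
    the sufficiency in the numerator is taken outward (``[W_ix]``),
    following the two defining formulas literally. Nodes with no
    bridge partners score 0 (logged).
    """
    if cache is None:
        cache = NeighborhoodCache(graph)
    partners = bridge_partners(graph, i, thresholds, cache=cache)
    if not partners:
        logger.debug("node %r has no bridge partners; LB_i = 0", i)
        return 0.0
    sufficient = sum(
        bridge_report(graph, i, x, thresholds, cache=cache).sufficient
        for x in partners
    )
    return sufficient / len(partners)


def graph_LB(graph: nx.Graph, thresholds: ThresholdAssignment) -> float:
    """LB: mean local sufficiency over all nodes of the graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    cache = NeighborhoodCache(graph)
    return sum(
        local_sufficiency(graph, i, thresholds, cache=cache) for i in graph.nodes()
    ) / graph.number_of_nodes()


def graph_lb_absolute_curve(graph: nx.Graph, t_values: Iterable[int]) -> dict:
    """LB at several homogeneous absolute thresholds, sharing one sweep.

    Bridge widths do not depend on a homogeneous absolute threshold
    (only the sufficiency cutoff does), so the all-pairs width
    computation is done once and each T is read off the widths. Output
    maps T -> LB; exact match with per-T :func:`graph_LB`.
    """
    t_values = sorted(set(int(t) for t in t_values))
    if any(t < 1 for t in t_values):
        raise ValueError("absolute thresholds must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    cache = NeighborhoodCache(graph)
    # Widths are threshold-free here; reuse any homogeneous assignment.
    dummy = ThresholdAssignment("absolute", {v: 1 for v in graph.nodes()})
    totals = {t: 0.0 for t in t_values}
    for i in graph.nodes():
        outward_widths = []
        for v in _candidates_within_three(graph, i):
            if bridge_report(graph, v, i, dummy, cache=cache).width >= 1:
                outward_widths.append(
                    bridge_report(graph, i, v, dummy, cache=cache).width
                )
        if not outward_widths:
            continue
        for t in t_values:
            totals[t] += sum(w >= t for w in outward_widths) / len(outward_widths)
    n = graph.number_of_nodes()
    return {t: totals[t] / n for t in t_values}
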