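"""Graph ensembles and edge-list I/O.

Two generators cover the synthetic study conditions: degree-preserving
rewired ring lattices (a k-regular interpolation between ordered and
random graphs) and clustering-tunable scale-free graphs grown by
preferential attachment with triad formation (Holme–Kim construction).
Empirical networks enter through a plain two-column edge-list reader.

All graphs are undirected, unweighted and simple (no self-loops, no
multi-edges); :class:`networkx.Graph` is the in-memory container
throughout the package.
"""

from __future__ import annotations

import logging
import random
from pathlib import Path
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "generate_rewired_lattice",
    "generate_scale_free",
    "read_edge_list",
    "write_edge_list",
    "closed_neighborhood",
    "neighborhood_edge_set",
]


def closed_neighborhood(graph: nx.Graph, node) -> frozenset:
    """Closed neighborhood N[i]: node ``i`` together with its neighbors."""
    return frozenset(graph[node]) | {node}


def neighborhood_edge_set(graph: nx.Graph, node) -> frozenset:
    """E(N[i]): edge set of the subgraph induced on the closed neighborhood.

    Edges are represented as 2-element frozensets so that orientation
    never matters. All ties to ``i`` itself are included.
    """
    members = closed_neighborhood(graph, node)
    return frozenset(
        frozenset((a, b)) for a in members for b in graph[a] if b in members
    )


def generate_rewired_lattice(n: int, k: int, p: float, rng_seed=None) -> nx.Graph:
    """k-regular ring lattice with degree-preserving random rewiring.

    Starts from a ring of ``n`` vertices each connected to its ``k``
    nearest neighbors (``k/2`` on each side). Each lattice edge is then
    visited once in random order and, with probability ``p``, a
    double-edge swap with another uniformly chosen edge is attempted:
    edges (u,v) and (x,y) are replaced by (u,x) and (v,y). Swaps that
    would create a self-loop or a multi-edge are rejected, so every node
    keeps degree exactly ``k`` at every ``p`` and the graph stays simple.

    Parameters
    ----------
    n : int
        Number of nodes.
    k : int
        Even degree, ``2 <= k < n``.
    p : float
        Per-edge rewiring probability in [0, 1]; ``p=0`` returns the
        pristine lattice, ``p=1`` attempts a swap at every edge.
    rng_seed : int, optional
        Seed for the rewiring randomness; fixed seed gives a
        bit-identical graph.

    Notes
    -----
    Connectivity is not enforced: at high ``p`` a realization may split
    into several components.
    """
    if k % 2 != 0:
        raise ValueError(f"k must be even, got {k}")
    if not 2 <= k < n:
        raise ValueError(f"require 2 <= k < n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must lie in [0, 1], got {p}")

    rng = random.Random(rng_seed)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            graph.add_edge(i, (i + d) % n)

    if p == 0.0:
        return graph

    # Mutable registry of current edges so partner edges are drawn
    # uniformly in O(1) without rebuilding a list per swap.
    edge_list = [frozenset(e) for e in graph.edges()]
    index = {e: pos for pos, e in enumerate(edge_list)}

    def _replace(old: frozenset, new: frozenset) -> None:
        pos = index.pop(old)
        edge_list[pos] = new
        index[new] = pos

    visit_order = list(edge_list)
    rng.shuffle(visit_order)
    for edge in visit_order:
        if edge not in index:  # already consumed by an earlier swap
            continue
        if rng.random() >= p:
            continue
        partner = edge_list[rng.randrange(len(edge_list))]
        if partner == edge:
            continue
        u, v = sorted(edge)
        x, y = sorted(partner)
        if rng.random() < 0.5:  # unbiased pairing of endpoints
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if graph.has_edge(u, x) or graph.has_edge(v, y):
            continue
        graph.remove_edge(u, v)
        graph.remove_edge(x, y)
        graph.add_edge(u, x)
        graph.add_edge(v, y)
        _replace(edge, frozenset((u, x)))
        _replace(frozenset((x, y)), frozenset((v, y)))
    return graph


def generate_scale_free(n: int, m: int, triad_p: float, rng_seed=None) -> nx.Graph:
    """Clustering-tunable scale-free graph (growth + triad formation).

    Each arriving node attaches ``m`` edges; after each preferential
    attachment step a triad-formation step (closing a triangle with a
    neighbor of the node just linked) is taken with probability
    ``triad_p``. Pure preferential attachment (``triad_p=0``) yields a
    power-law degree distribution with exponent near 3; raising
    ``triad_p`` raises clustering without changing the tail.
    """
    if not 1 <= m < n:
        raise ValueError(f"require 1 <= m < n, got m={m}, n={n}")
    if not 0.0 <= triad_p <= 1.0:
        raise ValueError(f"triad probability must lie in [0, 1], got {triad_p}")
    return nx.powerlaw_cluster_graph(n, m, triad_p, seed=rng_seed)


def _parse_line(line: str, lineno: int) -> tuple[str, str] | None:
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    fields = stripped.replace(",", " ").split()
    if len(fields) != 2:
        raise ValueError(
            f"malformed edge-list line {lineno}: expected two fields, got {stripped!r}"
        )
    return fields[0], fields[1]


def read_edge_list(path) -> nx.Graph:
    """Read an undirected graph from a two-column edge list.

    Columns may be whitespace- or comma-delimited; blank lines and lines
    starting with ``#`` are ignored. Node labels are kept as strings.
    Duplicate edges are collapsed and self-loops are dropped with a
    logged warning.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            parsed = _parse_line(line, lineno)
            if parsed is None:
                continue
            u, v = parsed
            if u == v:
                logger.warning(
                    "%s:%d: dropping self-loop on node %r", path, lineno, u
                )
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a graph as a two-column whitespace-delimited edge list.

    Only edges are written; isolated nodes do not survive a round trip.
    """
    path = Path(path)
    with open(path, "w") as handle:
        for u, v in graph.edges():
            handle.write(f"{u} {v}\n")
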