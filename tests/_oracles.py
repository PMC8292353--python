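"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities straight from their defining set
algebra or by exhaustive scanning, without the caching, candidate
pruning or incremental bookkeeping the package itself uses.
"""

import itertools
import math
import random

import networkx as nx


def eff_threshold(graph, node, thresholds):
    t = thresholds[node]
    if thresholds.mode == "absolute":
        return int(t)
    deg = graph.degree(node)
    return max(1, math.ceil(t * deg)) if deg else 1


def closed_nbhd(graph, v):
    return {v} | set(graph[v])


def nbhd_edges(graph, v):
    members = sorted(closed_nbhd(graph, v), key=str)
    return {
        frozenset(pair)
        for pair in itertools.combinations(members, 2)
        if graph.has_edge(*pair)
    }


def bridge_oracle(graph, i, j, thresholds):
    """(O, D, R, W, sufficient) for the ordered pair (i, j)."""
    n_i, n_j = closed_nbhd(graph, i), closed_nbhd(graph, j)
    overlap = n_i & n_j
    disjoint = n_j - n_i
    e_i = nbhd_edges(graph, i)
    reinforcement = {v for v in disjoint if e_i & nbhd_edges(graph, v)}
    if thresholds.heterogeneous:
        reinforcement = {
            x
            for x in reinforcement
            if len(n_i & closed_nbhd(graph, x)) >= eff_threshold(graph, x, thresholds)
        }
    width = len(overlap | reinforcement)
    return overlap, disjoint, reinforcement, width, width >= eff_threshold(
        graph, j, thresholds
    )


def graph_lb_oracle(graph, thresholds):
    """Graph LB by all-ordered-pairs enumeration (no candidate pruning)."""
    total = 0.0
    nodes = list(graph.nodes())
    for i in nodes:
        partners = [
            v for v in nodes if v != i and bridge_oracle(graph, v, i, thresholds)[3] >= 1
        ]
        if not partners:
            continue
        sufficient = sum(bridge_oracle(graph, i, x, thresholds)[4] for x in partners)
        total += sufficient / len(partners)
    return total / len(nodes)


def async_fixed_point(graph, thresholds, seeds, rng: random.Random):
    """Final active set by repeated asynchronous scans in random order."""
    active = set(seeds)
    changed = True
    while changed:
        changed = False
        order = list(graph.nodes())
        rng.shuffle(order)
        for v in order:
            if v in active:
                continue
            exposure = sum(u in active for u in graph[v])
            if exposure >= eff_threshold(graph, v, thresholds):
                active.add(v)
                changed = True
    return active


def random_connected_graph(n, p, seed):
    """Erdős–Rényi graph resampled until connected."""
    rng = random.Random(seed)
    for _ in range(1000):
        graph = nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
        if n <= 1 or nx.is_connected(graph):
            return graph
    raise RuntimeError("could not draw a connected graph")


def connected_atlas_graphs(max_n=6):
    """All connected graphs with 2..max_n nodes from the graph atlas."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for graph in graph_atlas_g():
        n = graph.number_of_nodes()
        if 2 <= n <= max_n and nx.is_connected(graph):
            out.append(graph)
    return out


def hub_vs_clique_chain():
    """Fixture: a high-degree hub with an edgeless neighborhood versus a
    chain of overlapping triangles (a squared path) that carries a
    width-2 bridge at every step. The hub wins on degree but cannot
    spread a T=2 contagion; the chain can.
    """
    graph = nx.Graph()
    leaves = [f"l{i}" for i in range(10)]
    graph.add_edges_from(("h", leaf) for leaf in leaves)
    chain = [f"v{i:02d}" for i in range(20)]
    for a, b in zip(chain, chain[1:]):
        graph.add_edge(a, b)
    for a, b in zip(chain, chain[2:]):
        graph.add_edge(a, b)
    graph.add_edge("h", chain[0])  # single narrow tie keeps it connected
    return graph
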