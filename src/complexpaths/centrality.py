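"""Complex centrality and the baseline centrality measures.

Complex centrality CC_i is the node-level average complex path length
PL_c_i: the best seed for a complex contagion is the node whose
neighborhood reaches the most targets through the longest chains of
sufficient bridges. The baselines — degree, betweenness, eigenvector,
k-core, collective-influence ("percolation") centrality, closeness and
reach — all measure position in terms of simple paths and serve as the
comparison set in the seeding experiments.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .complex_paths import node_complex_path_length
from .contagion import (
    ThresholdAssignment,
    assign_thresholds,
    build_seed_set,
    cascade_outcome,
    effective_threshold,
    run_independent_cascade,
    run_linear_threshold,
    run_threshold_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE_MEASURES",
    "complex_centrality",
    "baseline_centralities",
    "ensemble_complex_centrality",
    "greedy_seed_selection",
    "top_node",
    "minmax_normalize",
]

BASELINE_MEASURES = (
    "degree",
    "betweenness",
    "eigenvector",
    "k_core",
    "percolation",
    "closeness",
    "reach",
)


def _sort_key(node):
    return (str(type(node)), str(node))


def _node_index(graph: nx.Graph) -> list:
    return sorted(graph.nodes(), key=_sort_key)


def complex_centrality(graph: nx.Graph, thresholds: ThresholdAssignment) -> pd.Series:
    """CC_i = PL_c_i for every node, as a Series named ``complex``."""
    nodes = _node_index(graph)
    values = [node_complex_path_length(graph, i, thresholds) for i in nodes]
    return pd.Series(values, index=nodes, name="complex", dtype=float)


def top_node(scores: pd.Series):
    """Argmax with deterministic tie-breaking by smallest node label."""
    best = scores.max()
    tied = sorted((i for i, s in scores.items() if s == best), key=_sort_key)
    if len(tied) > 1:
        logger.info(
            "argmax tie on %s among %d nodes; picking %r",
            scores.name,
            len(tied),
            tied[0],
        )
    return tied[0]


def _eigenvector_scores(graph: nx.Graph) -> dict:
    """Principal-eigenvector scores, computed per connected component."""
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        logger.info(
            "eigenvector centrality on %d components computed component-wise",
            len(components),
        )
    scores: dict = {}
    for comp in components:
        if len(comp) == 1:
            scores[next(iter(comp))] = 0.0
            continue
        if len(comp) == 2:  # principal vector of a single edge is uniform
            scores.update({v: 1 / np.sqrt(2) for v in comp})
            continue
        sub = graph.subgraph(comp)
        try:
            scores.update(nx.eigenvector_centrality_numpy(sub))
        except Exception as exc:  # pragma: no cover - pathological inputs
            raise RuntimeError(f"eigenvector centrality failed to converge: {exc}")
    return scores


def _percolation_scores(graph: nx.Graph, d: int) -> dict:
    """Collective-influence score: (deg_i - 1) * sum of (deg_j - 1) at distance d."""
    if d < 1:
        raise ValueError(f"percolation distance d must be >= 1, got {d}")
    scores = {}
    for i in graph.nodes():
        dist = nx.single_source_shortest_path_length(graph, i, cutoff=d)
        ring = [j for j, dj in dist.items() if dj == d]
        scores[i] = (graph.degree(i) - 1) * sum(graph.degree(j) - 1 for j in ring)
    return scores


def _reach_scores(graph: nx.Graph, radius: int) -> dict:
    scores = {}
    for i in graph.nodes():
        dist = nx.single_source_shortest_path_length(graph, i, cutoff=radius)
        scores[i] = len(dist) - 1  # exclude the node itself
    return scores


def baseline_centralities(
    graph: nx.Graph,
    measures: Sequence[str] = BASELINE_MEASURES,
    d: int = 3,
    reach_radius: int = 2,
) -> pd.DataFrame:
    """Per-node scores for the requested simple-path centralities.

    Parameters
    ----------
    d : int
        Exact shortest-path distance used by the collective-influence
        ("percolation") formula; the seeding experiments use d = 3.
    reach_radius : int
        Radius of the ball counted by reach centrality (default 2).
    """
    nodes = _node_index(graph)
    columns = {}
    for measure in measures:
        if measure == "degree":
            scores = dict(graph.degree())
        elif measure == "betweenness":
            scores = nx.betweenness_centrality(graph, normalized=True)
        elif measure == "eigenvector":
            scores = _eigenvector_scores(graph)
        elif measure == "k_core":
            scores = nx.core_number(graph)
        elif measure == "percolation":
            scores = _percolation_scores(graph, d)
        elif measure == "closeness":
            scores = nx.closeness_centrality(graph, wf_improved=False)
        elif measure == "reach":
            scores = _reach_scores(graph, reach_radius)
        else:
            raise ValueError(f"unknown centrality measure {measure!r}")
        columns[measure] = [float(scores[i]) for i in nodes]
    return pd.DataFrame(columns, index=nodes)


def ensemble_complex_centrality(
    graph: nx.Graph, t_values: Iterable[int]
) -> pd.Series:
    """Mean complex centrality over a range of homogeneous absolute thresholds.

    Used when the true adoption threshold is unknown: CC_i is averaged
    over homogeneous absolute T in ``t_values`` (the experiments use
    T = 2..6).
    """
    t_values = list(t_values)
    if not t_values:
        raise ValueError("t_values must be nonempty")
    columns = []
    for t in t_values:
        thresholds = assign_thresholds(graph, "absolute", int(t))
        columns.append(complex_centrality(graph, thresholds))
    out = pd.concat(columns, axis=1).mean(axis=1)
    out.name = "complex_ensemble"
    return out


def minmax_normalize(scores: pd.Series) -> pd.Series:
    """Min–max normalize to [0, 1]; constant columns collapse to 0 (logged)."""
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        logger.info("constant column %s: min-max normalization degenerate", scores.name)
        return pd.Series(0.0, index=scores.index, name=scores.name)
    return (scores - lo) / (hi - lo)


def greedy_seed_selection(
    graph: nx.Graph,
    model_config: ThresholdAssignment | dict,
    budget: int,
    trials: int = 10,
    rng_seed=None,
) -> pd.DataFrame:
    """Greedy baseline: rank every node by its own expected diffusion.

    Each node is evaluated as a focal seed: ``trials`` simulations are
    run from a clustered seed set built around it and the mean final
    adoption fraction is recorded. Nodes are returned sorted by that
    estimate (descending, ties broken by label), with the top
    ``budget`` nodes flagged. This is individual-performance greedy
    selection, not submodular set optimization.

    ``model_config`` is either a :class:`ThresholdAssignment` (threshold
    model; per-focal seed budget is the focal's effective threshold) or
    a dict like ``{"model": "ic", "theta": 0.1}`` /
    ``{"model": "lt"}`` (seed budget 1).
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    rng = np.random.default_rng(rng_seed)
    n = graph.number_of_nodes()
    nodes = _node_index(graph)
    records = []
    for focal in nodes:
        total = 0.0
        for _ in range(trials):
            if isinstance(model_config, ThresholdAssignment):
                seed_budget = effective_threshold(focal, graph, model_config)
                seeds = build_seed_set(graph, focal, seed_budget, rng)
                trace = run_threshold_model(graph, model_config, seeds)
            else:
                model = model_config["model"]
                seeds = build_seed_set(graph, focal, 1, rng)
                if model == "ic":
                    trace = run_independent_cascade(
                        graph, model_config["theta"], seeds, rng
                    )
                elif model == "lt":
                    trace = run_linear_threshold(graph, seeds, rng)
                else:
                    raise ValueError(f"unknown model {model!r}")
            adoption, _ = cascade_outcome(trace, n)
            total += adoption
        records.append((focal, total / trials))
    table = pd.DataFrame(records, columns=["node", "expected_adoption"])
    table = table.sort_values(
        ["expected_adoption", "node"],
        ascending=[False, True],
        key=lambda col: col.map(_sort_key) if col.name == "node" else col,
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= budget
    if len(table) > budget and table["expected_adoption"].nunique() == 1:
        logger.info("greedy selection: all nodes tie at %.4f", table["expected_adoption"].iloc[0])
    return table
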