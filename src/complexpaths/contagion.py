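"""Threshold-contagion dynamics and robustness diffusion models.

The core model is the deterministic complex-contagion threshold model:
every node ``i`` carries an adoption threshold ``T_i`` — an absolute
count of active neighbors or a fraction of its neighborhood — and
diffusion unfolds in synchronous discrete steps. Activation is
monotone: once active, a node stays active, so the final active set is
the unique minimal fixed point containing the seeds.

Two canonical stochastic diffusion models, Independent Cascade and
Linear Threshold, are provided as robustness comparators, together with
the clustered seeding rule used throughout the experiments (a focal
node plus ``T-1`` of its neighbors, extended outward when the budget
exceeds the neighborhood).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdAssignment",
    "ActivationTrace",
    "assign_thresholds",
    "effective_threshold",
    "run_threshold_model",
    "run_independent_cascade",
    "run_linear_threshold",
    "build_seed_set",
    "cascade_outcome",
]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _sort_key(node):
    # Deterministic node ordering that tolerates mixed label types.
    return (str(type(node)), str(node))


@dataclass(frozen=True)
class ThresholdAssignment:
    """Per-node adoption thresholds.

    Parameters
    ----------
    mode : {"absolute", "fractional"}
        Absolute thresholds are positive integer counts of active
        neighbors; fractional thresholds are values in (0, 1] giving
        the required fraction of a node's neighbors.
    values : mapping
        Node -> threshold.
    heterogeneous : bool
        True when thresholds were drawn from an interval rather than
        held constant. Downstream bridge computations apply the
        reinforcement-set activability filter only in this case.
    """

    mode: str
    values: Mapping
    heterogeneous: bool = False

    def __post_init__(self):
        if self.mode not in ("absolute", "fractional"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        for node, t in self.values.items():
            _validate_threshold(self.mode, t)

    def __getitem__(self, node):
        return self.values[node]


def _validate_threshold(mode: str, value) -> None:
    if mode == "absolute":
        if value < 1 or int(value) != value:
            raise ValueError(f"absolute threshold must be an integer >= 1, got {value}")
    else:
        if not 0.0 < value <= 1.0:
            raise ValueError(f"fractional threshold must lie in (0, 1], got {value}")


def assign_thresholds(graph: nx.Graph, mode: str, spec, rng_seed=None) -> ThresholdAssignment:
    """Assign adoption thresholds to every node of ``graph``.

    ``spec`` is either a scalar (homogeneous threshold) or a pair
    ``(lo, hi)`` (heterogeneous: uniform integers on [lo, hi] for
    absolute mode, uniform reals on [lo, hi] for fractional mode).
    Draws are reproducible under ``rng_seed``.
    """
    nodes = sorted(graph.nodes(), key=_sort_key)
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        _validate_threshold(mode, lo)
        _validate_threshold(mode, hi)
        if hi < lo:
            raise ValueError(f"interval must satisfy lo <= hi, got {spec}")
        rng = _as_rng(rng_seed)
        if mode == "absolute":
            draws = rng.integers(int(lo), int(hi) + 1, size=len(nodes))
            values = {v: int(t) for v, t in zip(nodes, draws)}
        else:
            draws = rng.uniform(lo, hi, size=len(nodes))
            values = {v: float(t) for v, t in zip(nodes, draws)}
        return ThresholdAssignment(mode, values, heterogeneous=True)
    _validate_threshold(mode, spec)
    cast = int if mode == "absolute" else float
    return ThresholdAssignment(mode, {v: cast(spec) for v in nodes}, heterogeneous=False)


def effective_threshold(node, graph: nx.Graph, thresholds: ThresholdAssignment) -> int:
    """Number of active neighbors required to activate ``node``.

    Absolute thresholds are returned as-is. A fractional threshold
    ``T_i`` on a node of degree ``d`` requires ``ceil(T_i * d)`` active
    neighbors — the smallest count satisfying the stated fraction —
    floored at 1. An isolated node in fractional mode degenerates to 1.
    """
    t = thresholds[node]
    if thresholds.mode == "absolute":
        return int(t)
    degree = graph.degree(node)
    if degree == 0:
        logger.debug("isolated node %r in fractional mode: effective threshold 1", node)
        return 1
    return max(1, math.ceil(t * degree))


@dataclass(frozen=True)
class ActivationTrace:
    """Record of one diffusion run.

    ``times`` maps each *activated* node to its activation step; nodes
    absent from ``times`` never activated. Seeds have time 0 and
    activation is monotone.
    """

    times: Mapping
    seeds: frozenset
    steps: int

    @property
    def active_set(self) -> frozenset:
        return frozenset(self.times)

    def activation_time(self, node):
        """Activation step of ``node``, or None if it never activated."""
        return self.times.get(node)


def run_threshold_model(
    graph: nx.Graph, thresholds: ThresholdAssignment, seeds: Iterable
) -> ActivationTrace:
    """Synchronous threshold dynamics run to fixation.

    At each step every inactive node with at least its (effective)
    threshold of active neighbors activates; active nodes stay active.
    The run is deterministic given graph, thresholds and seeds, and the
    final active set is the minimal fixed point containing the seeds
    (synchronous and asynchronous schedules agree for these monotone
    dynamics).
    """
    seeds = frozenset(seeds)
    missing = seeds - set(graph.nodes())
    if missing:
        raise ValueError(f"seeds not in graph: {sorted(missing, key=_sort_key)}")
    times = {s: 0 for s in seeds}
    exposure: dict = defaultdict(int)
    eff_cache: dict = {}
    frontier = seeds
    step = 0
    while frontier:
        touched = set()
        for u in frontier:
            for w in graph[u]:
                if w in times:
                    continue
                exposure[w] += 1
                touched.add(w)
        step += 1
        newly = set()
        for w in touched:
            eff = eff_cache.get(w)
            if eff is None:
                eff = eff_cache[w] = effective_threshold(w, graph, thresholds)
            if exposure[w] >= eff:
                newly.add(w)
        for w in newly:
            times[w] = step
            del exposure[w]
        frontier = newly
    fixation = max(times.values(), default=0)
    return ActivationTrace(times=times, seeds=seeds, steps=fixation)


def run_independent_cascade(
    graph: nx.Graph, theta: float, seeds: Iterable, rng_seed=None
) -> ActivationTrace:
    """Independent Cascade model with uniform activation probability.

    Each newly active node gets exactly one chance to activate each of
    its currently inactive neighbors, succeeding independently with
    probability ``theta``.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    rng = _as_rng(rng_seed)
    seeds = frozenset(seeds)
    times = {s: 0 for s in seeds}
    frontier = sorted(seeds, key=_sort_key)
    step = 0
    while frontier:
        step += 1
        newly = []
        for u in frontier:
            for w in sorted(graph[u], key=_sort_key):
                if w in times:
                    continue
                if rng.random() < theta:
                    times[w] = step
                    newly.append(w)
        frontier = sorted(newly, key=_sort_key)
    fixation = max(times.values(), default=0)
    return ActivationTrace(times=times, seeds=seeds, steps=fixation)


def run_linear_threshold(graph: nx.Graph, seeds: Iterable, rng_seed=None) -> ActivationTrace:
    """Linear Threshold model with uniform edge weights 1/deg.

    Each neighbor of a node ``j`` carries influence weight ``1/deg(j)``;
    node-specific thresholds are drawn uniformly on (0, 1) afresh each
    run. A node activates once the summed weight of its active
    neighbors reaches its threshold.
    """
    rng = _as_rng(rng_seed)
    seeds = frozenset(seeds)
    nodes = sorted(graph.nodes(), key=_sort_key)
    theta = {v: rng.uniform(0.0, 1.0) for v in nodes}
    times = {s: 0 for s in seeds}
    frontier = seeds
    active_count: dict = defaultdict(int)
    step = 0
    while frontier:
        for u in frontier:
            for w in graph[u]:
                if w not in times:
                    active_count[w] += 1
        step += 1
        newly = set()
        for w, count in active_count.items():
            if w in times:
                continue
            if count / graph.degree(w) >= theta[w]:
                newly.add(w)
        for w in newly:
            times[w] = step
            active_count.pop(w, None)
        frontier = newly
    fixation = max(times.values(), default=0)
    return ActivationTrace(times=times, seeds=seeds, steps=fixation)


def build_seed_set(graph: nx.Graph, focal, budget: int, rng_seed=None) -> frozenset:
    """Clustered seed set: a focal node plus ``budget - 1`` nearby nodes.

    First ``budget - 1`` neighbors of ``focal`` are sampled uniformly
    without replacement. If the budget exceeds the neighborhood, the
    set is extended by iteratively sampling nodes adjacent to the
    already-selected set until the budget is met; if no candidates
    remain, the smaller set is returned with a logged warning.
    """
    if budget < 1:
        raise ValueError(f"seed budget must be >= 1, got {budget}")
    if focal not in graph:
        raise ValueError(f"focal node {focal!r} not in graph")
    rng = _as_rng(rng_seed)
    chosen = [focal]
    neighbors = sorted(graph[focal], key=_sort_key)
    take = min(budget - 1, len(neighbors))
    if take:
        picks = rng.choice(len(neighbors), size=take, replace=False)
        chosen.extend(neighbors[p] for p in picks)
    while len(chosen) < budget:
        selected = set(chosen)
        candidates = sorted(
            {w for u in chosen for w in graph[u] if w not in selected}, key=_sort_key
        )
        if not candidates:
            logger.warning(
                "seed budget %d unreachable from %r: returning %d nodes",
                budget,
                focal,
                len(chosen),
            )
            break
        chosen.append(candidates[rng.integers(len(candidates))])
    return frozenset(chosen)


def cascade_outcome(
    trace: ActivationTrace, n: int, cascade_fraction: float = 0.5
) -> tuple[float, bool]:
    """Adoption fraction and whether the run counts as a global cascade.

    A run is a global cascade when the final adoption fraction reaches
    ``cascade_fraction`` (inclusive; default half the population).
    """
    adoption = len(trace.times) / n
    return adoption, adoption >= cascade_fraction
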