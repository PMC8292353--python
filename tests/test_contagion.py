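import math
import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexpaths.contagion import (
    ThresholdAssignment,
    assign_thresholds,
    build_seed_set,
    cascade_outcome,
    effective_threshold,
    run_independent_cascade,
    run_linear_threshold,
    run_threshold_model,
)
from _oracles import async_fixed_point


class TestAssignThresholds:
    def test_homogeneous_absolute(self, k5):
        ta = assign_thresholds(k5, "absolute", 2)
        assert all(ta[v] == 2 for v in k5)
        assert not ta.heterogeneous

    def test_heterogeneous_absolute_support_and_reproducibility(self, k5):
        a = assign_thresholds(k5, "absolute", (2, 4), rng_seed=7)
        b = assign_thresholds(k5, "absolute", (2, 4), rng_seed=7)
        assert all(a[v] in {2, 3, 4} for v in k5)
        assert a.values == b.values
        assert a.heterogeneous

    def test_heterogeneous_fractional_in_interval(self, k5):
        ta = assign_thresholds(k5, "fractional", (0.1, 0.5), rng_seed=1)
        assert all(0.1 <= ta[v] <= 0.5 for v in k5)

    @pytest.mark.parametrize(
        "mode,spec", [("fractional", 0.0), ("fractional", 1.5), ("absolute", 0), ("absolute", (3, 2))]
    )
    def test_rejects_invalid_spec(self, k5, mode, spec):
        with pytest.raises(ValueError):
            assign_thresholds(k5, mode, spec)


class TestEffectiveThreshold:
    @pytest.mark.parametrize("t,deg,expected", [(0.5, 8, 4), (0.1, 4, 1), (0.3, 7, 3)])
    def test_fractional_ceiling(self, t, deg, expected):
        graph = nx.star_graph(deg)
        ta = assign_thresholds(graph, "fractional", t)
        assert effective_threshold(0, graph, ta) == expected

    def test_absolute_ignores_degree(self, star6):
        ta = assign_thresholds(star6, "absolute", 3)
        assert effective_threshold(0, star6, ta) == 3
        assert effective_threshold(1, star6, ta) == 3

    def test_isolated_node_degenerates_to_one(self):
        graph = nx.empty_graph(3)
        ta = assign_thresholds(graph, "fractional", 0.4)
        assert effective_threshold(0, graph, ta) == 1

    @given(deg=st.integers(1, 40), t=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractional_effective_is_smallest_satisfying_count(self, deg, t):
        graph = nx.star_graph(deg)
        ta = ThresholdAssignment("fractional", {v: t for v in graph})
        eff = effective_threshold(0, graph, ta)
        assert 1 <= eff <= deg
        assert eff / deg >= t                      # eff neighbors satisfy the fraction
        assert eff == 1 or (eff - 1) / deg < t     # eff - 1 would not


class TestThresholdModel:
    def test_k5_two_seeds_full_in_one_step(self, k5):
        ta = assign_thresholds(k5, "absolute", 2)
        trace = run_threshold_model(k5, ta, {0, 1})
        assert trace.active_set == frozenset(k5)
        assert all(trace.activation_time(v) == 1 for v in (2, 3, 4))
        assert trace.steps == 1

    def test_star_leaves_cannot_reinforce(self, star6):
        ta = assign_thresholds(star6, "absolute", 2)
        trace = run_threshold_model(star6, ta, {1, 2})
        assert trace.active_set == {0, 1, 2}
        assert trace.activation_time(3) is None

    def test_empty_seeds_no_activity(self, path5):
        ta = assign_thresholds(path5, "absolute", 2)
        trace = run_threshold_model(path5, ta, set())
        assert trace.active_set == frozenset()
        assert trace.steps == 0

    def test_unknown_seed_rejected(self, path5):
        ta = assign_thresholds(path5, "absolute", 2)
        with pytest.raises(ValueError):
            run_threshold_model(path5, ta, {"z"})

    def test_t1_is_component_reachability(self):
        for seed in range(5):
            graph = nx.gnp_random_graph(25, 0.08, seed=seed)
            ta = assign_thresholds(graph, "absolute", 1)
            trace = run_threshold_model(graph, ta, {0})
            assert trace.active_set == nx.node_connected_component(graph, 0)

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_matches_async_fixed_point(self, t):
        for seed in range(10):
            graph = nx.gnp_random_graph(8, 0.4, seed=seed)
            ta = assign_thresholds(graph, "absolute", t)
            seeds = set(random.Random(seed).sample(list(graph), 3))
            sync = run_threshold_model(graph, ta, seeds).active_set
            for scan_seed in range(3):
                assert sync == async_fixed_point(graph, ta, seeds, random.Random(scan_seed))

    def test_monotone_in_seeds(self):
        for seed in range(10):
            graph = nx.gnp_random_graph(20, 0.2, seed=seed)
            ta = assign_thresholds(graph, "absolute", 2)
            rng = random.Random(seed)
            small = set(rng.sample(list(graph), 3))
            large = small | set(rng.sample(list(graph), 3))
            final_small = run_threshold_model(graph, ta, small).active_set
            final_large = run_threshold_model(graph, ta, large).active_set
            assert final_small <= final_large

    def test_antitone_in_threshold(self):
        for seed in range(10):
            graph = nx.gnp_random_graph(20, 0.25, seed=seed)
            seeds = set(random.Random(seed).sample(list(graph), 4))
            finals = [
                run_threshold_model(graph, assign_thresholds(graph, "absolute", t), seeds).active_set
                for t in (1, 2, 3)
            ]
            assert finals[2] <= finals[1] <= finals[0]


class TestIndependentCascade:
    def test_theta_zero_only_seeds(self, k5):
        trace = run_independent_cascade(k5, 0.0, {0}, rng_seed=1)
        assert trace.active_set == {0}

    def test_theta_one_fills_component(self):
        graph = nx.disjoint_union(nx.path_graph(4), nx.path_graph(3))
        trace = run_independent_cascade(graph, 1.0, {0}, rng_seed=1)
        assert trace.active_set == {0, 1, 2, 3}

    def test_two_hop_probability(self):
        graph = nx.path_graph("abc")
        rng = np.random.default_rng(123)
        hits = sum(
            "c" in run_independent_cascade(graph, 0.5, {"a"}, rng).active_set
            for _ in range(10_000)
        )
        # P(c active) = 0.5^2; Monte-Carlo within 3 standard errors
        se = math.sqrt(0.25 * 0.75 / 10_000)
        assert abs(hits / 10_000 - 0.25) < 3 * se

    def test_reproducible(self, path5):
        a = run_independent_cascade(path5, 0.4, {"a"}, rng_seed=5)
        b = run_independent_cascade(path5, 0.4, {"a"}, rng_seed=5)
        assert a.times == b.times


class TestLinearThreshold:
    def test_all_seeded(self, k5):
        trace = run_linear_threshold(k5, set(k5), rng_seed=0)
        assert all(trace.activation_time(v) == 0 for v in k5)

    def test_degree_one_neighbor_always_adopts(self, star6):
        trace = run_linear_threshold(star6, {0}, rng_seed=3)
        assert all(trace.activation_time(leaf) == 1 for leaf in range(1, 6))

    def test_no_seeds(self, path5):
        assert run_linear_threshold(path5, set(), rng_seed=0).active_set == frozenset()


class TestSeedSet:
    def test_budget_one_is_focal(self, path5):
        assert build_seed_set(path5, "c", 1, rng_seed=0) == {"c"}

    def test_star_budget_three(self, star6):
        seeds = build_seed_set(star6, 0, 3, rng_seed=1)
        assert 0 in seeds and len(seeds) == 3
        assert seeds - {0} <= set(range(1, 6))

    def test_clustered_extension_on_path(self):
        graph = nx.path_graph("abcd")
        seeds = build_seed_set(graph, "a", 3, rng_seed=0)
        assert seeds == {"a", "b", "c"}

    def test_budget_exceeding_component_warns(self, caplog):
        graph = nx.disjoint_union(nx.path_graph(2), nx.path_graph(2))
        with caplog.at_level("WARNING"):
            seeds = build_seed_set(graph, 0, 4, rng_seed=0)
        assert seeds == {0, 1}
        assert any("unreachable" in r.message for r in caplog.records)

    def test_rejects_bad_budget(self, path5):
        with pytest.raises(ValueError):
            build_seed_set(path5, "a", 0)


class TestCascadeOutcome:
    def test_values(self):
        full = run_threshold_model(nx.complete_graph(4), assign_thresholds(nx.complete_graph(4), "absolute", 1), {0})
        assert cascade_outcome(full, 4) == (1.0, True)

    def test_boundary_inclusive(self, star6):
        ta = assign_thresholds(star6, "absolute", 2)
        trace = run_threshold_model(star6, ta, {1, 2})  # 3 of 6 active
        adoption, is_global = cascade_outcome(trace, 6, cascade_fraction=0.5)
        assert adoption == 0.5 and is_global
        _, not_global = cascade_outcome(trace, 6, cascade_fraction=0.51)
        assert not not_global
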