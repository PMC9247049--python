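"""Best-response label-switching dynamics (phase one)."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamecover import (DetectionConfig, Graph, best_response,
                       candidate_labels, candidate_payoffs, initialize,
                       payoff, run_phase_one, similarity_cache, stop_check)
from gamecover.benchmarks import planted_fixture
from conftest import random_graph


def complete_graph(n):
    return Graph([(i, j) for i in range(1, n + 1)
                  for j in range(i + 1, n + 1)])


class TestInitialize:
    def test_singleton_labels_are_node_ids(self, triangle):
        profile = initialize(triangle)
        assert profile == {1: {1}, 2: {2}, 3: {3}}

    def test_labels_all_distinct(self):
        g = random_graph(3, n=20)
        labels = [next(iter(s)) for s in initialize(g).values()]
        assert len(set(labels)) == g.n


class TestCandidateLabels:
    def test_isolated_node_sees_only_itself(self):
        g = Graph([(1, 2)], nodes=[3])
        assert candidate_labels(g, initialize(g), 3) == {3}

    def test_neighbor_labels_plus_own(self):
        g = Graph([(0, 1), (0, 2), (0, 3)])
        profile = {0: {"c"}, 1: {"a"}, 2: {"a"}, 3: {"b"}}
        assert candidate_labels(g, profile, 0) == {"a", "b", "c"}

    def test_converged_clique_has_single_candidate(self):
        g = complete_graph(5)
        cover, _ = run_phase_one(g, DetectionConfig(epsilon=0.0))
        profile = {v: set(ms) for v, ms in cover.membership_map().items()}
        assert all(len(candidate_labels(g, profile, v)) == 1 for v in g)


class TestPayoff:
    def test_zero_when_no_neighbor_holds_candidate(self, triangle):
        cache = similarity_cache(triangle)
        assert payoff(triangle, initialize(triangle), cache, 1, "zzz") == 0.0

    def test_single_label_neighbor_with_half_similarity(self):
        # neighbors share one common neighbor; HP gives sim(1,2) = 0.5
        g = Graph([(1, 2), (1, 3), (2, 3), (2, 4)])
        cache = similarity_cache(g, "HP")
        assert cache[(1, 2)] == 0.5
        profile = {1: {1}, 2: {"c"}, 3: {3}, 4: {4}}
        assert payoff(g, profile, cache, 1, "c") == pytest.approx(1.5)

    def test_multilabel_neighbor_attenuated_by_sqrt(self):
        # sims 0 and 1; the sim-1 neighbor holds 4 labels -> 1 + 2/sqrt(4)
        g = Graph([(0, 1), (0, 2)])
        profile = {0: {0}, 1: {"c"}, 2: {"c", "x", "y", "z"}}
        cache = {(0, 1): 0.0, (0, 2): 1.0}
        assert payoff(g, profile, cache, 0, "c") == pytest.approx(2.0)

    def test_candidate_payoffs_agree_with_single_label_payoff(self):
        g = random_graph(11, n=25)
        cover, _ = run_phase_one(g)
        profile = {v: set(ms) for v, ms in cover.membership_map().items()}
        cache = similarity_cache(g)
        for v in list(g)[:10]:
            table = candidate_payoffs(g, profile, cache, v)
            for lab, value in table.items():
                assert value == pytest.approx(
                    payoff(g, profile, cache, v, lab))


class TestBestResponse:
    def _graph(self):
        return Graph([(0, 1), (0, 2), (0, 3)])

    def test_strict_argmax_switches(self):
        g = self._graph()
        profile = {0: {"b"}, 1: {"a"}, 2: {"a"}, 3: {"b"}}
        cache = {k: 0.0 for k in [(0, 1), (1, 0), (0, 2), (2, 0),
                                  (0, 3), (3, 0)]}
        assert best_response(g, profile, cache, 0) == "a"

    def test_current_label_retained_on_tie(self):
        g = Graph([(0, 1), (0, 2)])
        profile = {0: {"b"}, 1: {"a"}, 2: {"b"}}
        cache = {k: 0.0 for k in [(0, 1), (1, 0), (0, 2), (2, 0)]}
        assert best_response(g, profile, cache, 0) == "b"

    def test_smallest_label_on_foreign_tie(self):
        g = self._graph()
        profile = {0: {"b"}, 1: {"a"}, 2: {"c"}, 3: {"d"}}
        cache = {k: 0.0 for k in [(0, 1), (1, 0), (0, 2), (2, 0),
                                  (0, 3), (3, 0)]}
        assert best_response(g, profile, cache, 0) == "a"


class TestStopCheck:
    @pytest.mark.parametrize("prev,curr,eps,expected", [
        (100, 101, 0.01, True),   # increase 1 <= 1
        (100, 102, 0.01, False),  # increase 2 > 1
        (0, 50, 0.5, False),      # never stop before anyone is fixed
        (10, 10, 0.0, True),      # no new fixed agents
    ])
    def test_arithmetic(self, prev, curr, eps, expected):
        assert stop_check(prev, curr, eps) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            stop_check(-1, 5, 0.1)


class TestRunPhaseOne:
    def test_two_cliques_split_exactly(self):
        g, truth = planted_fixture("two_cliques", 5, 5)
        cover, _ = run_phase_one(g, DetectionConfig(epsilon=0.0))
        assert sorted(cover.as_sets()) == sorted(truth.as_sets())

    def test_single_clique_one_community(self):
        cover, _ = run_phase_one(complete_graph(6))
        assert len(cover.communities) == 1

    def test_output_is_partition(self):
        g = random_graph(5, n=40)
        cover, _ = run_phase_one(g)
        assert cover.is_partition()
        assert set(cover.nodes) == set(g.nodes)

    def test_isolated_node_stays_singleton(self):
        g = Graph([(1, 2), (2, 3), (1, 3)], nodes=[9])
        cover, _ = run_phase_one(g)
        assert cover.memberships(9) == [9]

    def test_deterministic_runs(self):
        g = random_graph(17, n=50)
        a, ta = run_phase_one(g)
        b, tb = run_phase_one(g)
        assert a.communities == b.communities
        assert (ta.n_fixed, ta.switches, ta.stop_reason) == \
            (tb.n_fixed, tb.switches, tb.stop_reason)

    def test_trace_bounds(self):
        g = random_graph(23, n=40)
        cfg = DetectionConfig(max_iterations=50)
        _, trace = run_phase_one(g, cfg)
        assert trace.iterations <= 50
        assert all(0 <= f <= g.n for f in trace.n_fixed)

    @given(st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_nash_stable_at_zero_epsilon(self, seed):
        """Run to quiescence: no agent can improve by any single switch."""
        g = random_graph(seed, n=12 + seed % 40)
        cover, trace = run_phase_one(
            g, DetectionConfig(epsilon=0.0, max_iterations=500))
        if trace.stop_reason != "converged":
            pytest.skip("oscillating instance hit the sweep cap")
        profile = {v: set(ms) for v, ms in cover.membership_map().items()}
        cache = similarity_cache(g)
        for v in g:
            table = candidate_payoffs(g, profile, cache, v)
            current = table[next(iter(profile[v]))]
            assert max(table.values()) <= current + 1e-12

    @given(st.integers(0, 100))
    @settings(max_examples=15, deadline=None)
    def test_epsilon_trades_iterations(self, seed):
        g = random_graph(seed, n=45)
        _, t_eager = run_phase_one(
            g, DetectionConfig(epsilon=0.01, max_iterations=500))
        _, t_full = run_phase_one(
            g, DetectionConfig(epsilon=0.0, max_iterations=500))
        assert t_eager.iterations <= t_full.iterations


def test_local_improvement_during_dynamics():
    """Each adopted label never pays less than the label it replaces."""
    from gamecover.phase_one import initialize, sweep_order
    g = random_graph(31, n=35)
    cache = similarity_cache(g)
    profile = initialize(g)
    for _ in range(30):
        switches = 0
        for v in sweep_order(g, "desc"):
            table = candidate_payoffs(g, profile, cache, v)
            (old,) = profile[v]
            new = best_response(g, profile, cache, v)
            assert table[new] >= table.get(old, 0.0) - 1e-12
            if new != old:
                profile[v] = {new}
                switches += 1
        if switches == 0:
            break
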