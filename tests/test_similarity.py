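import math
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from heatnet.similarity import (
    SimilarityError,
    aggregate_disease_classes,
    compare_networks,
    hypergeometric_upper_tail,
    screen_library,
)


def enumeration_tail(x, K, N, M):
    """Exhaustive pmf enumeration oracle for the upper tail."""
    total = math.comb(M, N)
    acc = 0
    for i in range(x, min(K, N) + 1):
        if N - i <= M - K:
            acc += math.comb(K, i) * math.comb(M - K, N - i)
    return acc / total


class TestUpperTail:
    @pytest.mark.parametrize(
        "x, K, N, M, expected",
        [
            (0, 3, 2, 5, 1.0),
            (1, 1, 1, 2, 0.5),
            (3, 5, 4, 10, 55 / 210),
        ],
    )
    def test_worked_examples(self, x, K, N, M, expected):
        assert hypergeometric_upper_tail(x, K, N, M) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small_populations(self):
        for M in range(1, 10):
            for K, N in product(range(M + 1), repeat=2):
                for x in range(min(K, N) + 1):
                    p = hypergeometric_upper_tail(x, K, N, M)
                    assert p == pytest.approx(enumeration_tail(x, K, N, M), abs=1e-12)

    def test_matches_scipy_survival_function(self):
        for x, K, N, M in [(5, 40, 30, 500), (20, 40, 40, 500), (2, 10, 90, 1000)]:
            assert hypergeometric_upper_tail(x, K, N, M) == pytest.approx(
                float(hypergeom.sf(x - 1, M, K, N)), rel=1e-9)

    def test_symmetry_in_K_and_N(self):
        for M in (6, 9, 12):
            for K, N in product(range(M + 1), repeat=2):
                for x in range(min(K, N) + 1):
                    assert hypergeometric_upper_tail(x, K, N, M) == pytest.approx(
                        hypergeometric_upper_tail(x, N, K, M), abs=1e-12)

    def test_nonincreasing_in_x(self):
        M, K, N = 12, 7, 5
        ps = [hypergeometric_upper_tail(x, K, N, M) for x in range(min(K, N) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "x, K, N, M", [(3, 2, 5, 10), (1, 11, 5, 10), (-1, 2, 2, 4), (0, 2, 2, -1)]
    )
    def test_invalid_parameters_rejected(self, x, K, N, M):
        with pytest.raises(SimilarityError):
            hypergeometric_upper_tail(x, K, N, M)

    def test_deep_tail_does_not_underflow_to_zero(self):
        p = hypergeometric_upper_tail(100, 100, 100, 10_000)
        assert 0 < p < 1e-200


class TestCompareNetworks:
    def test_identical_sets_union_mode(self):
        rec = compare_networks({"a", "b", "c"}, {"a", "b", "c"}, population="union")
        assert (rec.x, rec.K, rec.N, rec.M) == (3, 3, 3, 3)
        assert rec.p_value == 1.0

    def test_disjoint_sets_universe_mode(self):
        rec = compare_networks({"a"}, {"b"}, universe_size=10)
        assert rec.x == 0 and rec.p_value == 1.0 and not rec.significant

    def test_worked_example_universe_ten(self):
        a = {f"g{i}" for i in range(1, 6)}
        b = {f"g{i}" for i in range(1, 5)}
        rec = compare_networks(a, b, universe_size=10)
        assert (rec.x, rec.K, rec.N, rec.M) == (4, 5, 4, 10)
        assert rec.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert rec.significant

    def test_empty_set_rejected(self):
        with pytest.raises(SimilarityError):
            compare_networks(set(), {"a"}, universe_size=5)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(SimilarityError):
            compare_networks({"a", "b"}, {"c"}, universe_size=2)

    @given(st.sets(st.integers(0, 30), min_size=1),
           st.sets(st.integers(0, 30), min_size=1))
    @settings(max_examples=100, derandomize=True)
    def test_union_mode_overlap_never_exceeds_null_mean(self, a, b):
        ga, gb = {f"g{i}" for i in a}, {f"g{i}" for i in b}
        rec = compare_networks(ga, gb, population="union")
        # x <= N*K/M, so union-mode p-values sit at or above the central mass
        assert rec.x * rec.M <= rec.N * rec.K


class TestScreenLibrary:
    def test_single_agent_library(self):
        ranked = screen_library("q", {"q": {"a"}, "other": {"a", "b"}},
                                universe_size=10)
        assert [r.agent_b for r in ranked] == ["other"]
        assert ranked[0].rank == 1

    def test_higher_overlap_ranks_first(self):
        q = {f"g{i}" for i in range(5)}
        lib = {"q": q,
               "hi": set(list(q)[:4]) | {"x4"},
               "lo": set(list(q)[:2]) | {"x1", "x2", "x3"}}
        ranked = screen_library("q", lib, universe_size=50)
        assert [r.agent_b for r in ranked] == ["hi", "lo"]

    def test_order_stable_under_input_shuffling(self):
        q = {"g1", "g2", "g3"}
        agents = {f"a{i}": {"g1", f"x{i}", f"y{i}"} for i in range(8)}
        lib1 = {"q": q, **agents}
        lib2 = {"q": q, **dict(reversed(list(agents.items())))}
        r1 = screen_library("q", lib1, universe_size=100)
        r2 = screen_library("q", lib2, universe_size=100)
        assert [r.agent_b for r in r1] == [r.agent_b for r in r2]
        # equal p-values break ties by agent id
        assert [r.agent_b for r in r1] == sorted(r.agent_b for r in r1)

    def test_query_excluded_and_empty_library_rejected(self):
        with pytest.raises(SimilarityError):
            screen_library("q", {"q": {"a"}}, universe_size=5)


class TestAggregateDiseaseClasses:
    def mk_ranked(self, agents):
        return screen_library("q", {"q": {"g"}, **{a: {"g"} for a in agents}},
                              universe_size=10)

    def test_both_agents_same_class(self):
        ranked = self.mk_ranked(["a1", "a2"])
        counts = aggregate_disease_classes(ranked, {"a1": {"C"}, "a2": {"C"}}, k=2)
        assert counts == [("C", 2)]

    def test_agent_with_two_classes_counts_in_each(self):
        ranked = self.mk_ranked(["a1"])
        counts = aggregate_disease_classes(ranked, {"a1": {"C1", "C2"}}, k=1)
        assert counts == [("C1", 1), ("C2", 1)]

    def test_unannotated_agent_bucketed(self):
        ranked = self.mk_ranked(["a1", "a2"])
        counts = aggregate_disease_classes(ranked, {"a1": {"C"}}, k=2)
        assert ("unannotated", 1) in counts

    def test_hand_enumerated_fixture(self):
        ranked = self.mk_ranked(["a1", "a2", "a3", "a4", "a5"])
        indications = {
            "a1": {"cardio"}, "a2": {"cardio", "neuro"}, "a3": {"neuro"},
            "a4": {"onco"}, "a5": {"cardio"},
        }
        counts = aggregate_disease_classes(ranked, indications, k=5)
        assert counts == [("cardio", 3), ("neuro", 2), ("onco", 1)]

    def test_k_larger_than_list_rejected(self):
        ranked = self.mk_ranked(["a1"])
        with pytest.raises(SimilarityError):
            aggregate_disease_classes(ranked, {}, k=2)
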