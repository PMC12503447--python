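"""Scoring, hill-climbing, bootstrap averaging and Markov blankets."""

import itertools
import math

import numpy as np
import pytest

from compnet import (
    ArcBlacklist,
    ArcConfidence,
    DAGStructure,
    ValidationError,
    averaged_network,
    bootstrap_arcs,
    hill_climb,
    markov_blanket,
    score_network,
)

from conftest import make_cohort, random_dag


def all_dags(names):
    """Every labeled DAG on the given nodes (25 for three nodes)."""
    pairs = [(u, v) for u in names for v in names if u != v]
    seen = []
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            try:
                seen.append(DAGStructure(nodes=names, arcs=frozenset(combo)))
            except ValidationError:
                continue
    return seen


class TestScoreNetwork:
    def test_hand_computed_bic_on_four_rows(self):
        """Empty graph, 2 fair-coin columns, N=4: per-node BIC by hand."""
        cohort = make_cohort(("x", "y"), [[0, 0], [1, 1], [0, 1], [1, 0]], outcome="y")
        dag = DAGStructure(nodes=("x", "y"), arcs=frozenset())
        sv = score_network(dag, cohort, score="bic")
        expected_node = 4 * math.log(0.5) - 0.5 * math.log(4)  # ll - penalty
        assert sv.per_node["x"] == pytest.approx(expected_node, abs=1e-12)
        assert sv.per_node["y"] == pytest.approx(expected_node, abs=1e-12)
        assert sv.total == pytest.approx(2 * expected_node, abs=1e-12)

    def test_arc_between_identical_columns_increases_bic(self):
        rng = np.random.default_rng(8)
        col = (rng.random(1000) < 0.5).astype(np.uint8)
        cohort = make_cohort(("x", "y"), np.column_stack([col, col]), outcome="y")
        empty = DAGStructure(nodes=("x", "y"), arcs=frozenset())
        arc = DAGStructure(nodes=("x", "y"), arcs=frozenset({("x", "y")}))
        assert (
            score_network(arc, cohort).total > score_network(empty, cohort).total
        )

    def test_decomposability_total_is_sum(self, cohort20k):
        dag = hill_climb(cohort20k)
        sv = score_network(dag, cohort20k)
        assert sv.total == pytest.approx(sum(sv.per_node.values()), rel=1e-12)

    def test_mismatched_catalog_rejected(self, cohort20k):
        dag = DAGStructure(nodes=("x", "y"), arcs=frozenset())
        with pytest.raises(ValidationError):
            score_network(dag, cohort20k)


class TestHillClimb:
    def test_independent_columns_give_empty_dag(self):
        rng = np.random.default_rng(12)
        values = (rng.random((10_000, 4)) < 0.5).astype(np.uint8)
        cohort = make_cohort(("a", "b", "c", "death"), values)
        assert hill_climb(cohort).arcs == frozenset()

    def test_chain_recovered_and_matches_exhaustive(self):
        """A->B->C cohort: learned skeleton is {A-B, B-C}; score equals the
        best of all 25 three-node DAGs."""
        rng = np.random.default_rng(13)
        n = 20_000
        a = (rng.random(n) < 0.5).astype(np.uint8)
        b = np.where(a == 1, rng.random(n) < 0.85, rng.random(n) < 0.15).astype(np.uint8)
        c = np.where(b == 1, rng.random(n) < 0.85, rng.random(n) < 0.15).astype(np.uint8)
        cohort = make_cohort(("a", "b", "c"), np.column_stack([a, b, c]), outcome="c")
        blacklist = ArcBlacklist(frozenset())
        learned = hill_climb(cohort, blacklist=blacklist)
        assert learned.skeleton() == {
            frozenset({"a", "b"}),
            frozenset({"b", "c"}),
        }
        best = max(
            score_network(d, cohort).total for d in all_dags(("a", "b", "c"))
        )
        assert score_network(learned, cohort).total == pytest.approx(best, abs=1e-9)

    def test_blacklist_respected(self, cohort20k):
        dag = hill_climb(cohort20k)  # default blacklist: no arcs out of death
        assert not any(u == "death" for u, _ in dag.arcs)

    def test_output_acyclic_and_beats_empty_graph(self, cohort20k):
        dag = hill_climb(cohort20k, restarts=2, seed=5)
        # DAGStructure construction already enforces acyclicity
        empty = DAGStructure(nodes=dag.nodes, arcs=frozenset())
        assert (
            score_network(dag, cohort20k).total
            >= score_network(empty, cohort20k).total
        )

    def test_deterministic_given_seed(self, cohort20k):
        a = hill_climb(cohort20k, restarts=3, seed=17)
        b = hill_climb(cohort20k, restarts=3, seed=17)
        assert a.arcs == b.arcs


@pytest.fixture(scope="module")
def strong_pair_conf():
    rng = np.random.default_rng(19)
    n = 5000
    a = (rng.random(n) < 0.5).astype(np.uint8)
    b = np.where(a == 1, rng.random(n) < 0.9, rng.random(n) < 0.1).astype(np.uint8)
    cohort = make_cohort(("a", "b", "death"),
                         np.column_stack([a, b, np.zeros(n, dtype=np.uint8)]))
    return bootstrap_arcs(cohort, replicates=100, seed=23, restarts=0)


class TestBootstrap:
    def test_single_replicate_strengths_are_binary(self, cohort20k):
        conf = bootstrap_arcs(cohort20k, replicates=1, seed=3, restarts=0)
        assert all(s in (0.0, 1.0) for s in conf.pairs.values())

    def test_strong_dependence_high_strength(self, strong_pair_conf):
        assert strong_pair_conf.strength("a", "b") > 0.75

    def test_direction_probabilities_sum_to_one(self, strong_pair_conf):
        for (u, v), s in strong_pair_conf.pairs.items():
            if s > 0:
                total = strong_pair_conf.direction_prob(u, v) + \
                    strong_pair_conf.direction_prob(v, u)
                assert total == pytest.approx(1.0)

    def test_zero_replicates_rejected(self, cohort20k):
        with pytest.raises(ValidationError):
            bootstrap_arcs(cohort20k, replicates=0)


class TestAveragedNetwork:
    def _conf(self, nodes, entries):
        pairs, direction = {}, {}
        for (u, v), (strength, d_uv) in entries.items():
            key = tuple(sorted((u, v)))
            pairs[key] = strength
            direction[(u, v)] = d_uv
            direction[(v, u)] = 1.0 - d_uv
        return ArcConfidence(nodes=nodes, pairs=pairs, direction=direction,
                             n_replicates=100)

    def test_single_strong_pair_majority_direction(self):
        conf = self._conf(("a", "b"), {("a", "b"): (0.9, 0.8)})
        dag = averaged_network(conf)
        assert dag.arcs == frozenset({("a", "b")})

    def test_below_strength_threshold_excluded(self):
        conf = self._conf(("a", "b"), {("a", "b"): (0.6, 0.9)})
        assert averaged_network(conf, strength_min=0.75).arcs == frozenset()

    def test_cycle_repair_drops_weakest(self):
        conf = self._conf(
            ("a", "b", "c"),
            {("a", "b"): (0.9, 1.0), ("b", "c"): (0.85, 1.0), ("c", "a"): (0.8, 1.0)},
        )
        dag = averaged_network(conf)
        assert dag.arcs == frozenset({("a", "b"), ("b", "c")})

    def test_monotone_in_strength_threshold(self, cohort20k):
        conf = bootstrap_arcs(cohort20k, replicates=20, seed=31, restarts=0)
        previous = None
        for thr in (0.3, 0.5, 0.75, 0.9):
            arcs = averaged_network(conf, strength_min=thr).arcs
            if previous is not None:
                assert arcs <= previous
            previous = arcs

    def test_invalid_threshold_rejected(self):
        conf = self._conf(("a", "b"), {("a", "b"): (0.9, 1.0)})
        with pytest.raises(ValidationError):
            averaged_network(conf, strength_min=1.01)


class TestMarkovBlanket:
    def test_chain(self):
        dag = DAGStructure(nodes=("a", "b", "c"),
                           arcs=frozenset({("a", "b"), ("b", "c")}))
        assert markov_blanket(dag, "b") == {"a", "c"}

    def test_v_structure_spouse(self):
        dag = DAGStructure(nodes=("a", "b", "c"),
                           arcs=frozenset({("a", "c"), ("b", "c")}))
        assert markov_blanket(dag, "a") == {"b", "c"}

    def test_unknown_node_rejected(self):
        dag = DAGStructure(nodes=("a",), arcs=frozenset())
        with pytest.raises(ValidationError):
            markov_blanket(dag, "zz")

    def test_matches_brute_force_on_random_dags(self):
        names = tuple(f"n{i}" for i in range(13))
        rng = np.random.default_rng(37)
        for _ in range(20):
            dag = random_dag(rng, names, arc_prob=0.2)
            for node in names:
                brute = set()
                for u, v in dag.arcs:
                    if v == node:
                        brute.add(u)
                    if u == node:
                        brute.add(v)
                        for u2, v2 in dag.arcs:
                            if v2 == v and u2 != node:
                                brute.add(u2)
                assert markov_blanket(dag, node) == brute
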