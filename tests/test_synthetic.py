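"""Ground-truth spec properties and ancestral-sampling behaviour."""

import numpy as np
import pytest

from compnet import (
    ConditionalTable,
    DAGStructure,
    ValidationError,
    VariableCatalog,
    GroundTruthSpec,
    brute_force_query,
    cohort_from_published_counts,
    exact_marginals,
    filter_any_complication,
    read_cohort,
    sample_cohort,
    summarize_sample,
    write_cohort,
)


class TestDefaultGroundTruth:
    def test_thirteen_nodes_one_outcome(self, spec):
        assert spec.catalog.size == 13
        assert spec.catalog.outcome == "death"

    def test_chest_tube_marginal_near_half(self, spec):
        """The most common complication sits near 50% prevalence."""
        marg = exact_marginals(spec)
        assert abs(marg["increased_chest_tube_drainage"] - 0.501) < 0.05

    def test_root_and_rare_prevalences(self, spec):
        marg = exact_marginals(spec)
        common = [
            marg["increased_chest_tube_drainage"],
            marg["prolonged_icu_stays"],
            marg["prolonged_mechanical_ventilation"],
        ]
        assert all(0.40 <= p <= 0.55 for p in common)
        for rare in ("stroke", "sternal_wound_infections", "pericardial_tamponade"):
            assert 0.005 <= marg[rare] <= 0.03

    def test_no_arcs_out_of_death(self, spec):
        assert not any(u == "death" for u, _ in spec.dag.arcs)

    def test_death_parents_are_severe_complications(self, spec):
        assert set(spec.dag.parents("death")) == {
            "secondary_tracheal_intubation",
            "stroke",
            "postoperative_rf",
            "mods",
        }

    def test_death_given_mods_high(self, spec):
        """Mortality conditional on MODS exceeds one half (joint enumeration)."""
        assert brute_force_query(spec.bn, "death", {"mods": 1}) >= 0.5

    def test_death_cpt_monotone_in_mods(self, spec):
        t = spec.cpts["death"]
        j = t.parents.index("mods")
        for cfg in range(t.n_configs):
            if not (cfg >> j) & 1:
                assert t.p1[cfg | (1 << j)] >= t.p1[cfg]

    def test_contains_v_structure_and_chain_to_death(self, spec):
        # v-structure: mods has two parents that are not adjacent
        mods_parents = spec.dag.parents("mods")
        assert len(mods_parents) == 2
        u, v = mods_parents
        assert (u, v) not in spec.dag.arcs and (v, u) not in spec.dag.arcs
        # directed chain of length >= 3 ending in death
        g = spec.dag.to_networkx()
        import networkx as nx

        lengths = nx.shortest_path_length(g, target="death")
        assert max(lengths.values()) >= 3


class TestSampling:
    def test_identical_seed_identical_matrix(self, spec):
        a = sample_cohort(spec, n=500, seed=42)
        b = sample_cohort(spec, n=500, seed=42)
        assert np.array_equal(a.values, b.values)
        c = sample_cohort(spec, n=500, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_degenerate_distribution(self):
        cat = VariableCatalog(names=("x", "death"), outcome="death")
        dag = DAGStructure(nodes=cat.names, arcs=frozenset())
        cpts = {
            "x": ConditionalTable(node="x", parents=(), p1=[1.0]),
            "death": ConditionalTable(node="death", parents=(), p1=[0.0]),
        }
        s = GroundTruthSpec(catalog=cat, dag=dag, cpts=cpts, n_patients=50, seed=1)
        cohort = sample_cohort(s)
        assert cohort.column("x").sum() == 50
        assert cohort.column("death").sum() == 0

    def test_conditional_frequency_matches_cpt(self):
        """Empirical P(B=1|A=1) within 3 binomial SEs of the generating 0.9."""
        cat = VariableCatalog(names=("a", "b", "death"), outcome="death")
        dag = DAGStructure(nodes=cat.names, arcs=frozenset({("a", "b")}))
        cpts = {
            "a": ConditionalTable(node="a", parents=(), p1=[0.5]),
            "b": ConditionalTable(node="b", parents=("a",), p1=[0.1, 0.9]),
            "death": ConditionalTable(node="death", parents=(), p1=[0.01]),
        }
        s = GroundTruthSpec(catalog=cat, dag=dag, cpts=cpts, n_patients=100_000, seed=7)
        cohort = sample_cohort(s)
        a, b = cohort.column("a"), cohort.column("b")
        n1 = int(a.sum())
        p_hat = float(b[a == 1].mean())
        se = np.sqrt(0.9 * 0.1 / n1)
        assert abs(p_hat - 0.9) < 3 * se

    def test_sampled_cohort_round_trips_and_filters(self, spec, tmp_path):
        cohort = sample_cohort(spec, n=2000, seed=3)
        back = read_cohort(write_cohort(cohort, tmp_path / "c.csv"))
        assert np.array_equal(back.values, cohort.values)
        filtered = filter_any_complication(back)
        assert 1 <= filtered.n_patients <= 2000

    def test_conditional_independence_of_chain(self):
        """For A -> B -> C, phi(A, C) within each stratum of B is ~0."""
        cat = VariableCatalog(names=("a", "b", "c", "death"), outcome="death")
        dag = DAGStructure(
            nodes=cat.names, arcs=frozenset({("a", "b"), ("b", "c")})
        )
        cpts = {
            "a": ConditionalTable(node="a", parents=(), p1=[0.5]),
            "b": ConditionalTable(node="b", parents=("a",), p1=[0.2, 0.8]),
            "c": ConditionalTable(node="c", parents=("b",), p1=[0.3, 0.7]),
            "death": ConditionalTable(node="death", parents=(), p1=[0.05]),
        }
        s = GroundTruthSpec(catalog=cat, dag=dag, cpts=cpts, n_patients=200_000, seed=9)
        cohort = sample_cohort(s)
        a, b, c = (cohort.column(x).astype(float) for x in ("a", "b", "c"))
        for stratum in (0, 1):
            mask = b == stratum
            r = np.corrcoef(a[mask], c[mask])[0, 1]
            assert abs(r) < 0.01  # ~4.5 SEs at this stratum size


class TestSummarize:
    def test_all_zero_prevalence(self):
        cat = VariableCatalog(names=("a", "death"), outcome="death")
        dag = DAGStructure(nodes=cat.names, arcs=frozenset())
        cpts = {
            "a": ConditionalTable(node="a", parents=(), p1=[0.5]),
            "death": ConditionalTable(node="death", parents=(), p1=[0.5]),
        }
        s = GroundTruthSpec(catalog=cat, dag=dag, cpts=cpts, n_patients=10, seed=1)
        from conftest import make_cohort

        cohort = make_cohort(("a", "death"), np.zeros((10, 2), dtype=int))
        report = summarize_sample(cohort, s)
        assert report.empirical_prevalence == {"a": 0.0, "death": 0.0}

    def test_perfectly_correlated_pair_phi_one(self, spec):
        from conftest import make_cohort

        col = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        cohort = make_cohort(("a", "death"), np.column_stack([col, col]))
        report = summarize_sample(
            cohort,
            GroundTruthSpec(
                catalog=cohort.catalog,
                dag=DAGStructure(nodes=cohort.catalog.names, arcs=frozenset()),
                cpts={
                    "a": ConditionalTable(node="a", parents=(), p1=[0.5]),
                    "death": ConditionalTable(node="death", parents=(), p1=[0.5]),
                },
                n_patients=5,
            ),
        )
        assert report.empirical_phi[0, 1] == pytest.approx(1.0)

    def test_catalog_mismatch_rejected(self, spec):
        from conftest import make_cohort

        cohort = make_cohort(("x", "death"), [[0, 1]])
        with pytest.raises(ValidationError, match="catalog"):
            summarize_sample(cohort, spec)

    def test_empirical_prevalence_converges(self, spec, cohort50k):
        """Sampled prevalence within 0.01 of the exact marginals at N=50k."""
        report = summarize_sample(cohort50k, spec)
        exact = exact_marginals(spec)
        worst = max(
            abs(report.empirical_prevalence[n] - exact[n])
            for n in spec.catalog.names
        )
        assert worst < 0.01


class TestPublishedCountsFixture:
    def test_carrier_and_death_counts_reproduced(self):
        cohort = cohort_from_published_counts()
        assert cohort.n_patients == 18_585
        death = cohort.column("death")
        assert int(death.sum()) == 734
        from compnet import PUBLISHED_COMPLICATION_COUNTS

        for name, (carriers, deaths) in PUBLISHED_COMPLICATION_COUNTS.items():
            col = cohort.column(name)
            assert int(col.sum()) == carriers
            assert int((col & death).sum()) == deaths
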