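"""Shared fixtures: the default ground truth, sampled cohorts, random BNs."""

from __future__ import annotations

import numpy as np
import pytest

from compnet import (
    CohortMatrix,
    ConditionalTable,
    DAGStructure,
    DiscreteBN,
    GroundTruthSpec,
    VariableCatalog,
    default_ground_truth,
    sample_cohort,
)


@pytest.fixture(scope="session")
def spec() -> GroundTruthSpec:
    return default_ground_truth()


@pytest.fixture(scope="session")
def cohort20k(spec) -> CohortMatrix:
    return sample_cohort(spec, n=20_000, seed=0)


@pytest.fixture(scope="session")
def cohort50k(spec) -> CohortMatrix:
    return sample_cohort(spec, n=50_000, seed=0)


def random_dag(rng: np.random.Generator, names: tuple[str, ...],
               arc_prob: float = 0.25) -> DAGStructure:
    """Random DAG: permute nodes, include forward arcs independently."""
    order = list(rng.permutation(len(names)))
    arcs = set()
    for i_pos in range(len(names)):
        for j_pos in range(i_pos + 1, len(names)):
            if rng.random() < arc_prob:
                arcs.add((names[order[i_pos]], names[order[j_pos]]))
    return DAGStructure(nodes=names, arcs=frozenset(arcs))


def random_bn(rng: np.random.Generator, n_nodes: int = 13,
              arc_prob: float = 0.25) -> DiscreteBN:
    """Random binary BN with CPT entries in [0.05, 0.95]."""
    names = tuple(f"v{i:02d}" for i in range(n_nodes))
    dag = random_dag(rng, names, arc_prob)
    tables = {}
    for name in names:
        parents = dag.parents(name)
        p1 = rng.uniform(0.05, 0.95, size=2 ** len(parents))
        tables[name] = ConditionalTable(node=name, parents=parents, p1=p1)
    return DiscreteBN(dag=dag, tables=tables)


def make_cohort(names: tuple[str, ...], rows, outcome: str | None = None) -> CohortMatrix:
    """Small literal cohort helper for unit tests."""
    catalog = VariableCatalog(names=names, outcome=outcome or names[-1])
    return CohortMatrix(catalog=catalog, values=np.asarray(rows, dtype=np.uint8))


def cpt_errors(fitted: ConditionalTable, truth: ConditionalTable):
    """Per-configuration (support, |p_fitted - p_true|), aligned by parent
    names (the two tables may order parents differently)."""
    out = []
    for cfg in range(fitted.n_configs):
        assignment = {
            p: (cfg >> j) & 1 for j, p in enumerate(fitted.parents)
        }
        t_cfg = truth.config_index(assignment)
        out.append(
            (int(fitted.counts[cfg]),
             abs(float(fitted.p1[cfg]) - float(truth.p1[t_cfg])))
        )
    return out
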