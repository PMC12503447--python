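"""Synthetic patient cohorts drawn from a configurable ground-truth network.

The registry that motivated this package is not publicly available, so every
downstream stage is exercised against cohorts sampled from a known discrete
Bayesian network. The default ground truth is a 13-node network whose
marginal prevalences are anchored to the published frequency table of a
large multicenter cardiac-surgery registry (three common "primary"
complications near 45–50% prevalence, rare severe complications at 0.5–3%),
whose death node is a noisy-OR child of the severe complications
(secondary tracheal intubation, stroke, postoperative renal failure, MODS),
and which contains the structural motifs the learning stages must handle:
a v-structure, a chain of length >= 3 ending in death, and one
near-isolated node (stroke, which in practice is driven by pre- and
intra-operative factors rather than by other complications).

Sampling is ancestral: nodes are visited in a deterministic topological
order (lexicographic tie-breaking) and each value is drawn conditional on
its sampled parents from a single seeded generator, so cohorts are
bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .catalog import DEFAULT_CATALOG, VariableCatalog
from .cohort import CohortMatrix
from .descriptives import phi_matrix
from .errors import ValidationError
from .inference import brute_force_query, joint_table
from .parameters import ConditionalTable, DiscreteBN
from .structure import DAGStructure

__all__ = [
    "GroundTruthSpec",
    "SimulationReport",
    "default_ground_truth",
    "sample_cohort",
    "summarize_sample",
    "exact_marginals",
    "exact_phi",
    "PUBLISHED_COMPLICATION_COUNTS",
    "PUBLISHED_COHORT_SIZE",
    "PUBLISHED_DEATHS",
    "cohort_from_published_counts",
]


@dataclass(frozen=True)
class GroundTruthSpec:
    """A fully specified generating network plus sampling defaults."""

    catalog: VariableCatalog
    dag: DAGStructure
    cpts: Mapping[str, ConditionalTable]
    n_patients: int = 18585
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        # DiscreteBN construction validates acyclicity and CPT/DAG agreement
        object.__setattr__(self, "_bn", DiscreteBN(dag=self.dag, tables=dict(self.cpts)))

    @property
    def bn(self) -> DiscreteBN:
        return self._bn  # type: ignore[attr-defined]


@dataclass(frozen=True)
class SimulationReport:
    """Empirical summaries of one sampled cohort against its spec."""

    empirical_prevalence: Mapping[str, float]
    empirical_phi: np.ndarray
    seed_used: int

    def __post_init__(self) -> None:
        for name, p in self.empirical_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"prevalence of {name!r} outside [0, 1]")


def _table(node: str, parents: tuple[str, ...], p1) -> ConditionalTable:
    return ConditionalTable(node=node, parents=parents, p1=np.asarray(p1, dtype=float))


def default_ground_truth(n_patients: int = 18585, seed: int = 0) -> GroundTruthSpec:
    """The standard 13-node generating network.

    CPT rows are indexed with the first listed parent as the least
    significant bit: for parents ``(a, b)`` the row order is
    (a=0,b=0), (a=1,b=0), (a=0,b=1), (a=1,b=1).

    Structure (18 arcs): the three common primary complications form the
    chain chest-tube-drainage -> prolonged-ICU -> prolonged-ventilation;
    mild complications (AF, MI, wound infection, tamponade) hang off the
    primaries; reoperation is driven by tamponade and drainage; the severe
    complications (secondary intubation, renal failure) are driven by the
    primaries and reoperation; MODS is the v-structure child of renal
    failure and secondary intubation; stroke is an isolated root; and death
    is a noisy-OR child of {secondary intubation, stroke, renal failure,
    MODS}. No arc leaves death.
    """
    cat = DEFAULT_CATALOG
    ctd = "increased_chest_tube_drainage"
    icu = "prolonged_icu_stays"
    pmv = "prolonged_mechanical_ventilation"
    af = "postoperative_af"
    mi = "postoperative_mi"
    swi = "sternal_wound_infections"
    pt = "pericardial_tamponade"
    reop = "reoperation"
    sti = "secondary_tracheal_intubation"
    stroke = "stroke"
    rf = "postoperative_rf"
    mods = "mods"
    death = "death"

    arcs = frozenset(
        {
            (ctd, icu),
            (icu, pmv),
            (ctd, af),
            (pmv, mi),
            (pmv, swi),
            (ctd, pt),
            (pt, reop),
            (ctd, reop),
            (pmv, sti),
            (reop, sti),
            (pmv, rf),
            (ctd, rf),
            (rf, mods),
            (sti, mods),
            (sti, death),
            (stroke, death),
            (rf, death),
            (mods, death),
        }
    )
    dag = DAGStructure(nodes=cat.names, arcs=arcs)

    # Noisy-OR death table over (sti, stroke, rf, mods): leak 0.016 and
    # per-cause contributions 0.30 / 0.33 / 0.40 / 0.86 — monotone in every
    # parent, with P(death | MODS alone) = 1 - 0.984 * 0.14 ≈ 0.862.
    leak = 0.016
    contrib = {sti: 0.30, stroke: 0.33, rf: 0.40, mods: 0.86}
    death_parents = (sti, stroke, rf, mods)
    death_p1 = np.empty(16)
    for cfg in range(16):
        keep = 1.0 - leak
        for j, parent in enumerate(death_parents):
            if (cfg >> j) & 1:
                keep *= 1.0 - contrib[parent]
        death_p1[cfg] = 1.0 - keep

    cpts = {
        ctd: _table(ctd, (), [0.50]),
        icu: _table(icu, (ctd,), [0.40, 0.60]),
        pmv: _table(pmv, (icu,), [0.30, 0.62]),
        af: _table(af, (ctd,), [0.012, 0.040]),
        mi: _table(mi, (pmv,), [0.006, 0.015]),
        swi: _table(swi, (pmv,), [0.005, 0.008]),
        pt: _table(pt, (ctd,), [0.005, 0.014]),
        # rows over (pt, ctd): 00, 10, 01, 11
        reop: _table(reop, (pt, ctd), [0.032, 0.50, 0.075, 0.60]),
        # rows over (pmv, reop): 00, 10, 01, 11
        sti: _table(sti, (pmv, reop), [0.005, 0.042, 0.105, 0.24]),
        stroke: _table(stroke, (), [0.005]),
        # rows over (pmv, ctd): 00, 10, 01, 11
        rf: _table(rf, (pmv, ctd), [0.003, 0.034, 0.012, 0.060]),
        # rows over (rf, sti): 00, 10, 01, 11
        mods: _table(mods, (rf, sti), [0.004, 0.28, 0.12, 0.45]),
        death: ConditionalTable(node=death, parents=death_parents, p1=death_p1),
    }
    return GroundTruthSpec(
        catalog=cat, dag=dag, cpts=cpts, n_patients=n_patients, seed=seed
    )


def sample_cohort(
    spec: GroundTruthSpec,
    n: int | None = None,
    seed: int | None = None,
) -> CohortMatrix:
    """Ancestral sampling of ``n`` patients (defaults from the spec).

    One seeded generator drives the whole draw; nodes are visited in the
    deterministic topological order of the DAG, so identical seeds give
    bitwise-identical cohorts.
    """
    n = int(spec.n_patients if n is None else n)
    seed = int(spec.seed if seed is None else seed)
    if n < 1:
        raise ValidationError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    order = spec.dag.topological_order()
    idx = {name: i for i, name in enumerate(spec.catalog.names)}
    values = np.zeros((n, spec.catalog.size), dtype=np.uint8)
    for name in order:
        t = spec.cpts[name]
        k = len(t.parents)
        if k:
            pcols = values[:, [idx[p] for p in t.parents]].astype(np.int64)
            cfg = pcols @ (1 << np.arange(k, dtype=np.int64))
            p = t.p1[cfg]
        else:
            p = np.full(n, t.p1[0])
        values[:, idx[name]] = rng.random(n) < p
    return CohortMatrix(catalog=spec.catalog, values=values)


def summarize_sample(cohort: CohortMatrix, spec: GroundTruthSpec) -> SimulationReport:
    """Empirical prevalence and phi matrix of a sampled cohort."""
    if cohort.catalog.names != spec.catalog.names:
        raise ValidationError("cohort columns do not match spec catalog")
    prevalence = {
        name: float(cohort.column(name).mean()) for name in cohort.catalog.names
    }
    phi = phi_matrix(cohort)
    return SimulationReport(
        empirical_prevalence=prevalence,
        empirical_phi=phi.values,
        seed_used=int(spec.seed),
    )


def exact_marginals(spec: GroundTruthSpec) -> dict[str, float]:
    """P(X = 1) for every node, by enumeration of the 2^V joint."""
    prob = joint_table(spec.bn)
    V = spec.catalog.size
    states = ((np.arange(2**V)[:, None] >> np.arange(V)) & 1).astype(np.uint8)
    return {
        name: float(prob[states[:, j] == 1].sum())
        for j, name in enumerate(spec.catalog.names)
    }


def exact_phi(spec: GroundTruthSpec, a: str, b: str) -> float:
    """Exact phi coefficient between two nodes under the generating joint."""
    p_a = brute_force_query(spec.bn, a)
    p_b = brute_force_query(spec.bn, b)
    p_ab = p_a * brute_force_query(spec.bn, b, {a: 1})
    cov = p_ab - p_a * p_b
    return float(cov / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b)))


# --------------------------------------------------------------------------
# published summary counts (frequency table reconstruction)
# --------------------------------------------------------------------------

#: Carrier and death counts per complication, as published for a national
#: multicenter cardiac-surgery registry cohort of 18,585 valve-surgery
#: patients with at least one perioperative complication.
PUBLISHED_COMPLICATION_COUNTS: dict[str, tuple[int, int]] = {
    "increased_chest_tube_drainage": (9312, 448),
    "prolonged_icu_stays": (9321, 460),
    "prolonged_mechanical_ventilation": (8489, 579),
    "postoperative_af": (484, 39),
    "postoperative_mi": (181, 15),
    "sternal_wound_infections": (94, 19),
    "pericardial_tamponade": (163, 33),
    "reoperation": (1068, 174),
    "secondary_tracheal_intubation": (537, 202),
    "stroke": (92, 33),
    "postoperative_rf": (453, 223),
    "mods": (299, 274),
}

PUBLISHED_COHORT_SIZE = 18585
PUBLISHED_DEATHS = 734


def cohort_from_published_counts(
    counts: Mapping[str, tuple[int, int]] | None = None,
    n_patients: int = PUBLISHED_COHORT_SIZE,
    n_deaths: int = PUBLISHED_DEATHS,
) -> CohortMatrix:
    """Synthetic patient-level matrix reproducing published marginal counts.

    Deterministically reconstructs an N x 13 binary matrix whose per-
    complication carrier counts and deaths-among-carriers equal the
    published summary table: deaths occupy the first ``n_deaths`` rows; each
    complication marks its first ``d`` death rows and the next ``c - d``
    survivor rows. Only the marginals (and carrier-death cross tabulations)
    are faithful — joint complication patterns are an artifact of the
    construction, so this fixture supports frequency/mortality arithmetic,
    not co-occurrence or network analyses.
    """
    counts = dict(PUBLISHED_COMPLICATION_COUNTS if counts is None else counts)
    cat = VariableCatalog(names=tuple(counts) + ("death",), outcome="death")
    values = np.zeros((n_patients, len(counts) + 1), dtype=np.uint8)
    values[:n_deaths, -1] = 1
    for j, (name, (carriers, deaths)) in enumerate(counts.items()):
        if not 0 <= deaths <= carriers <= n_patients:
            raise ValidationError(f"inconsistent counts for {name!r}")
        if n_deaths + (carriers - deaths) > n_patients or deaths > n_deaths:
            raise ValidationError(f"counts for {name!r} exceed cohort capacity")
        values[:deaths, j] = 1
        values[n_deaths : n_deaths + (carriers - deaths), j] = 1
    return CohortMatrix(catalog=cat, values=values)
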