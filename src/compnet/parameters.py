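"""Maximum-likelihood parameterization of a learned DAG.

Each node gets one conditional probability table (CPT): for every binary
assignment of its parents, P(node = 1 | parents). With smoothing pseudocount
``alpha = 0`` (the default) estimates are the raw empirical frequencies;
``alpha > 0`` applies symmetric Laplace smoothing toward 0.5. Parent
configurations never observed in the data are assigned 0.5 and flagged
``unsupported`` so downstream reports can annotate extrapolated entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import CohortMatrix
from .errors import ValidationError
from .structure import DAGStructure

__all__ = ["ConditionalTable", "DiscreteBN", "fit_cpts", "loglik"]


@dataclass(frozen=True)
class ConditionalTable:
    """P(node = 1 | parent configuration) for one binary node.

    Rows are indexed by the integer encoding of the parents' values with
    ``parents[j]`` contributing bit ``j`` (the first parent is the least
    significant bit). ``counts[i]`` is the number of observations of
    configuration ``i``; ``unsupported[i]`` marks rows with zero support
    whose probability is the conventional 0.5 rather than an estimate.
    """

    node: str
    parents: tuple[str, ...]
    p1: np.ndarray
    counts: np.ndarray = None
    unsupported: np.ndarray = None

    def __post_init__(self) -> None:
        parents = tuple(self.parents)
        object.__setattr__(self, "parents", parents)
        rows = 2 ** len(parents)
        p1 = np.asarray(self.p1, dtype=float).reshape(-1)
        if p1.shape[0] != rows:
            raise ValidationError(
                f"CPT for {self.node!r} needs {rows} rows, got {p1.shape[0]}"
            )
        if ((p1 < 0) | (p1 > 1)).any():
            raise ValidationError(f"CPT for {self.node!r} has probabilities outside [0, 1]")
        object.__setattr__(self, "p1", p1)
        counts = self.counts
        if counts is None:
            counts = np.zeros(rows, dtype=np.int64)
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64).reshape(-1))
        unsupported = self.unsupported
        if unsupported is None:
            unsupported = np.zeros(rows, dtype=bool)
        object.__setattr__(self, "unsupported", np.asarray(unsupported, dtype=bool).reshape(-1))

    @property
    def n_configs(self) -> int:
        return int(self.p1.shape[0])

    def config_index(self, assignment: Mapping[str, int]) -> int:
        return sum(int(assignment[p]) << j for j, p in enumerate(self.parents))


@dataclass(frozen=True)
class DiscreteBN:
    """A DAG plus one CPT per node; their product is the joint distribution."""

    dag: DAGStructure
    tables: Mapping[str, ConditionalTable]

    def __post_init__(self) -> None:
        missing = set(self.dag.nodes) - set(self.tables)
        if missing:
            raise ValidationError(f"missing CPTs for nodes: {sorted(missing)}")
        for name in self.dag.nodes:
            table = self.tables[name]
            if tuple(sorted(table.parents)) != tuple(sorted(self.dag.parents(name))):
                raise ValidationError(
                    f"CPT parents for {name!r} disagree with DAG parents"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes


def fit_cpts(
    dag: DAGStructure, cohort: CohortMatrix, alpha: float = 0.0
) -> DiscreteBN:
    """Estimate every CPT by (smoothed) maximum likelihood.

    P(node=1 | config) = (n(node=1, config) + alpha) / (n(config) + 2 alpha).
    With ``alpha = 0`` this is the pure MLE; unseen configurations then get
    0.5 with the ``unsupported`` flag set.
    """
    if tuple(dag.nodes) != tuple(cohort.catalog.names):
        raise ValidationError("DAG nodes do not match cohort catalog")
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    data = cohort.values
    idx = {n: i for i, n in enumerate(dag.nodes)}
    tables: dict[str, ConditionalTable] = {}
    for name in dag.nodes:
        parents = dag.parents(name)
        k = len(parents)
        if k:
            pcols = data[:, [idx[p] for p in parents]].astype(np.int64)
            code = pcols @ (1 << np.arange(k, dtype=np.int64))
        else:
            code = np.zeros(data.shape[0], dtype=np.int64)
        joint = code * 2 + data[:, idx[name]]
        counts = np.bincount(joint, minlength=2 ** (k + 1)).reshape(2**k, 2)
        n_cfg = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = (counts[:, 1] + alpha) / (n_cfg + 2 * alpha)
        unsupported = n_cfg == 0
        p1 = np.where(unsupported & ~np.isfinite(p1), 0.5, p1)
        p1 = np.where(np.isnan(p1), 0.5, p1)
        tables[name] = ConditionalTable(
            node=name, parents=parents, p1=p1, counts=n_cfg, unsupported=unsupported
        )
    return DiscreteBN(dag=dag, tables=tables)


def loglik(bn: DiscreteBN, cohort: CohortMatrix) -> float:
    """Log-likelihood of the cohort under the factored joint.

    Returns ``-inf`` (with a warning naming the offending node and parent
    configuration) when an observed event has probability zero under the
    model.
    """
    if tuple(bn.dag.nodes) != tuple(cohort.catalog.names):
        raise ValidationError("model nodes do not match cohort catalog")
    data = cohort.values
    idx = {n: i for i, n in enumerate(bn.dag.nodes)}
    total = 0.0
    for name in bn.dag.nodes:
        table = bn.tables[name]
        k = len(table.parents)
        if k:
            pcols = data[:, [idx[p] for p in table.parents]].astype(np.int64)
            code = pcols @ (1 << np.arange(k, dtype=np.int64))
        else:
            code = np.zeros(data.shape[0], dtype=np.int64)
        x = data[:, idx[name]]
        p = np.where(x == 1, table.p1[code], 1.0 - table.p1[code])
        if (p <= 0).any():
            i = int(np.argmax(p <= 0))
            cfg = {par: int(data[i, idx[par]]) for par in table.parents}
            warnings.warn(
                f"observed event with probability zero: node {name!r}="
                f"{int(x[i])} under parent configuration {cfg}",
                stacklevel=2,
            )
            return float("-inf")
        total += float(np.log(p).sum())
    return total
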