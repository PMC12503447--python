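"""Exact conditional-probability inference on the fitted network.

With 13 binary nodes exact inference is cheap, so two independent routes are
provided: variable elimination with a greedy min-fill ordering (the
production path) and full enumeration of the 2^V joint (the oracle used in
tests and for ground-truth marginals). The report generators produce the
two canonical probability matrices: P(target | one complication) for every
ordered pair, and P(death | combinations of complications).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .catalog import VariableCatalog
from .errors import ImpossibleEvidenceError, ValidationError
from .parameters import DiscreteBN
from .structure import DAGStructure, markov_blanket

__all__ = [
    "Evidence",
    "PosteriorTable",
    "query",
    "joint_table",
    "brute_force_query",
    "single_evidence_matrix",
    "multi_evidence_deaths",
    "default_death_combos",
    "critical_nodes",
]

Evidence = Mapping[str, int]

_ZERO_TOL = 1e-12


def _check_evidence(
    bn: DiscreteBN, evidence: Evidence, allow_outcome: bool
) -> dict[str, int]:
    out: dict[str, int] = {}
    outcome = getattr(bn.dag, "outcome", None)
    for name, value in evidence.items():
        if name not in bn.dag.nodes:
            raise ValidationError(f"unknown evidence variable {name!r}")
        if int(value) not in (0, 1):
            raise ValidationError(f"evidence {name!r} must be 0 or 1, got {value!r}")
        out[name] = int(value)
    return out


# --------------------------------------------------------------------------
# variable elimination
# --------------------------------------------------------------------------


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # shape (2,) * len(vars)


def _cpt_factor(bn: DiscreteBN, node: str) -> _Factor:
    t = bn.tables[node]
    k = len(t.parents)
    # axes: parents in order (axis j = parent j), node last
    shape = (2,) * k + (2,)
    table = np.empty(shape)
    grid = np.indices((2,) * k).reshape(k, -1).T if k else np.zeros((1, 0), dtype=int)
    for row in grid:
        cfg = int(sum(int(b) << j for j, b in enumerate(row)))
        index = tuple(int(b) for b in row)
        table[index + (1,)] = t.p1[cfg]
        table[index + (0,)] = 1.0 - t.p1[cfg]
    return _Factor(vars=t.parents + (node,), table=table)


def _reduce(factor: _Factor, evidence: Mapping[str, int]) -> _Factor:
    keep_vars = []
    indexer: list[object] = []
    for v in factor.vars:
        if v in evidence:
            indexer.append(evidence[v])
        else:
            indexer.append(slice(None))
            keep_vars.append(v)
    return _Factor(vars=tuple(keep_vars), table=factor.table[tuple(indexer)])


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    all_vars = tuple(dict.fromkeys(a.vars + b.vars))
    def expand(f: _Factor) -> np.ndarray:
        shape = tuple(2 if v in f.vars else 1 for v in all_vars)
        order = [f.vars.index(v) for v in all_vars if v in f.vars]
        return np.transpose(f.table, order).reshape(shape)
    return _Factor(vars=all_vars, table=expand(a) * expand(b))


def _sum_out(factor: _Factor, var: str) -> _Factor:
    axis = factor.vars.index(var)
    return _Factor(
        vars=tuple(v for v in factor.vars if v != var),
        table=factor.table.sum(axis=axis),
    )


def query(
    bn: DiscreteBN,
    target: str,
    evidence: Evidence | None = None,
    allow_outcome_evidence: bool = False,
) -> float:
    """Exact P(target = 1 | evidence) by variable elimination.

    The elimination order is chosen greedily, at each step summing out the
    hidden variable whose elimination produces the smallest intermediate
    factor; the result is independent of that order. Evidence on the
    outcome variable is refused unless ``allow_outcome_evidence`` is set
    (diagnostic queries reason from death back to complications).

    Raises :class:`ImpossibleEvidenceError` when the evidence has
    probability zero under the model.
    """
    if target not in bn.dag.nodes:
        raise ValidationError(f"unknown target variable {target!r}")
    ev = _check_evidence(bn, evidence or {}, allow_outcome_evidence)
    outcome = _bn_outcome(bn)
    if not allow_outcome_evidence and outcome is not None and outcome in ev and target != outcome:
        raise ValidationError(
            f"evidence on outcome {outcome!r} requires allow_outcome_evidence=True"
        )
    if target in ev:
        return float(ev[target])

    factors = [_reduce(_cpt_factor(bn, n), ev) for n in bn.dag.nodes]
    hidden = [n for n in bn.dag.nodes if n != target and n not in ev]
    while hidden:
        # greedy min-size: eliminate the variable whose product factor is smallest
        best_var, best_cost = None, None
        for v in sorted(hidden):
            involved_vars: set[str] = set()
            for f in factors:
                if v in f.vars:
                    involved_vars.update(f.vars)
            cost = 2 ** len(involved_vars - {v})
            if best_cost is None or cost < best_cost:
                best_var, best_cost = v, cost
        v = best_var
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        rest.append(_sum_out(prod, v))
        factors = rest
        hidden.remove(v)

    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f)
    if result.vars != (target,):
        result.table = result.table.reshape(2)  # pragma: no cover - safety net
    norm = float(result.table.sum())
    if norm <= _ZERO_TOL:
        raise ImpossibleEvidenceError(
            f"evidence {dict(ev)} has probability zero under the model"
        )
    return float(result.table[1] / norm)


def _bn_outcome(bn: DiscreteBN) -> str | None:
    # The DAG itself carries no outcome flag; by convention reports treat
    # the node named "death" as the outcome when present.
    return "death" if "death" in bn.dag.nodes else None


# --------------------------------------------------------------------------
# enumeration oracle
# --------------------------------------------------------------------------


def joint_table(bn: DiscreteBN) -> np.ndarray:
    """The full joint as a vector of length 2^V.

    State ``s`` assigns node ``j`` (catalog order) the bit ``(s >> j) & 1``.
    Sums to 1 up to floating-point error; used as the independent oracle for
    variable elimination and for exact ground-truth marginals.
    """
    nodes = bn.dag.nodes
    V = len(nodes)
    idx = {n: j for j, n in enumerate(nodes)}
    states = ((np.arange(2**V)[:, None] >> np.arange(V)) & 1).astype(np.uint8)
    prob = np.ones(2**V)
    for name in nodes:
        t = bn.tables[name]
        k = len(t.parents)
        if k:
            cfg = states[:, [idx[p] for p in t.parents]].astype(np.int64) @ (
                1 << np.arange(k, dtype=np.int64)
            )
        else:
            cfg = np.zeros(2**V, dtype=np.int64)
        p1 = t.p1[cfg]
        x = states[:, idx[name]]
        prob *= np.where(x == 1, p1, 1.0 - p1)
    return prob


def brute_force_query(
    bn: DiscreteBN, target: str, evidence: Evidence | None = None
) -> float:
    """P(target = 1 | evidence) by summing the enumerated joint."""
    if target not in bn.dag.nodes:
        raise ValidationError(f"unknown target variable {target!r}")
    ev = _check_evidence(bn, evidence or {}, allow_outcome=True)
    nodes = bn.dag.nodes
    V = len(nodes)
    idx = {n: j for j, n in enumerate(nodes)}
    prob = joint_table(bn)
    states = ((np.arange(2**V)[:, None] >> np.arange(V)) & 1).astype(np.uint8)
    mask = np.ones(2**V, dtype=bool)
    for name, value in ev.items():
        mask &= states[:, idx[name]] == value
    denom = float(prob[mask].sum())
    if denom <= _ZERO_TOL:
        raise ImpossibleEvidenceError(
            f"evidence {dict(ev)} has probability zero under the model"
        )
    numer = float(prob[mask & (states[:, idx[target]] == 1)].sum())
    return numer / denom


# --------------------------------------------------------------------------
# report tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorTable:
    """Matrix of P(target = 1 | evidence) values, as percentages.

    ``values[i, j]`` is 100 * P(targets[i] = 1 | evidence_labels[j]); NaN
    marks self-conditioning cells (rendered as an em dash) and cells whose
    evidence is impossible under the model.
    """

    targets: tuple[str, ...]
    evidence_labels: tuple[str, ...]
    values: np.ndarray
    config: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0) | (finite > 100)).any():
            raise ValidationError("posterior percentages must lie in [0, 100]")
        object.__setattr__(self, "values", vals)

    def cell(self, target: str, label: str) -> float:
        return float(
            self.values[self.targets.index(target), self.evidence_labels.index(label)]
        )

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, index=list(self.targets), columns=list(self.evidence_labels)
        )
        if display:
            frame = frame.map(lambda x: "—" if np.isnan(x) else f"{round_half_up(x, 1):.1f}")
        return frame

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame(display=True).to_csv(path, sep="\t", index_label="target")
        return path


def single_evidence_matrix(bn: DiscreteBN) -> PosteriorTable:
    """P(target | one complication present) for every ordered pair.

    Columns are the 12 complications as single-item evidence (value 1);
    rows are every complication plus a final death row. Self-conditioning
    cells are NaN by convention (displayed as a dash).
    """
    outcome = _bn_outcome(bn)
    complications = tuple(n for n in bn.dag.nodes if n != outcome)
    targets = complications + ((outcome,) if outcome else ())
    values = np.full((len(targets), len(complications)), np.nan)
    for j, ev_var in enumerate(complications):
        for i, target in enumerate(targets):
            if target == ev_var:
                continue
            try:
                p = query(bn, target, {ev_var: 1})
            except ImpossibleEvidenceError:
                continue  # flagged as NaN
            values[i, j] = 100.0 * p
    return PosteriorTable(
        targets=targets,
        evidence_labels=complications,
        values=values,
        config={"kind": "single_evidence", "outcome": outcome},
    )


def default_death_combos(
    catalog: VariableCatalog,
    primaries: Sequence[str] | None = None,
    secondaries: Sequence[str] | None = None,
) -> list[dict[str, int]]:
    """The canonical multi-complication evidence layout for the death table.

    Each combination sets one primary (mild, high-prevalence) complication
    plus zero, one or two secondary (critical) complications to 1 —
    mirroring the published layout of mortality given escalating
    complication chains.
    """
    names = set(catalog.names)
    if primaries is None:
        primaries = [
            n
            for n in (
                "prolonged_icu_stays",
                "increased_chest_tube_drainage",
                "prolonged_mechanical_ventilation",
            )
            if n in names
        ]
    if secondaries is None:
        secondaries = [
            n
            for n in (
                "reoperation",
                "secondary_tracheal_intubation",
                "stroke",
                "postoperative_rf",
                "mods",
            )
            if n in names
        ]
    combos: list[dict[str, int]] = []
    for p in primaries:
        combos.append({p: 1})
        for s in secondaries:
            combos.append({p: 1, s: 1})
        for s in secondaries:
            if s != "mods" and "mods" in names:
                combos.append({p: 1, s: 1, "mods": 1})
    return combos


def multi_evidence_deaths(
    bn: DiscreteBN, combos: Iterable[Evidence] | None = None
) -> PosteriorTable:
    """P(death = 1 | combination of complications), one column per combo.

    ``combos`` defaults to :func:`default_death_combos`; each combo may set
    1–3 complications to 1. An empty combo list yields an empty table.
    """
    outcome = _bn_outcome(bn)
    if outcome is None:
        raise ValidationError("model has no death node; cannot build death table")
    if combos is None:
        cat = VariableCatalog(names=bn.dag.nodes, outcome=outcome)
        combos = default_death_combos(cat)
    combos = [dict(c) for c in combos]
    labels = []
    values = np.full((1, len(combos)), np.nan)
    for j, combo in enumerate(combos):
        if outcome in combo:
            raise ValidationError("death cannot appear in a death-table combo")
        labels.append("+".join(f"{k}={v}" for k, v in sorted(combo.items())))
        try:
            values[0, j] = 100.0 * query(bn, outcome, combo)
        except ImpossibleEvidenceError:
            continue
    return PosteriorTable(
        targets=(outcome,),
        evidence_labels=tuple(labels),
        values=values,
        config={"kind": "multi_evidence_deaths", "outcome": outcome},
    )


def critical_nodes(dag: DAGStructure, outcome: str = "death") -> frozenset[str]:
    """The critical complications: the Markov blanket of the outcome node.

    These are the variables that screen death off from the rest of the
    network — its parents, children and co-parents of children.
    """
    return markov_blanket(dag, outcome)
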