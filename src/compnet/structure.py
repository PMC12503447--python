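"""Score-based structure learning for the complication network.

The learning strategy is the one standard in discrete Bayesian-network
practice: greedy hill-climbing over single-arc moves (add / delete /
reverse) maximizing a decomposable score (BIC by default), constrained by an
arc blacklist that forbids arcs out of the terminal outcome, followed by
nonparametric bootstrap model averaging — each replicate resamples patients
with replacement and relearns a network; arcs are then kept when their
bootstrap strength exceeds a threshold and oriented by majority direction.

All randomness is driven by explicit integer seeds; replicate seeds are
derived as ``master_seed + replicate_index`` so any single replicate can be
reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from ._util import derive_seed
from .catalog import VariableCatalog
from .cohort import CohortMatrix
from .errors import ValidationError

__all__ = [
    "DAGStructure",
    "ArcBlacklist",
    "ScoreValue",
    "ArcConfidence",
    "markov_blanket",
    "score_network",
    "hill_climb",
    "bootstrap_arcs",
    "averaged_network",
]

_SCORES = ("bic", "loglik")
_EPS = 1e-9  # minimum score gain accepted as a strict improvement


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph over named nodes.

    Invariants enforced at construction: no self-loops, arcs reference known
    nodes only, and the arc set admits a topological order.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        arcs = frozenset((str(u), str(v)) for u, v in self.arcs)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arcs", arcs)
        known = set(nodes)
        for u, v in arcs:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in known or v not in known:
                raise ValidationError(f"arc ({u!r}, {v!r}) references unknown node")
        if arcs and not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValidationError("arc set contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(v for u, v in self.arcs if u == node))

    def topological_order(self) -> tuple[str, ...]:
        """Deterministic topological sort with lexicographic tie-breaking."""
        return tuple(nx.lexicographical_topological_sort(self.to_networkx()))

    def skeleton(self) -> frozenset[frozenset[str]]:
        """The undirected arc set."""
        return frozenset(frozenset(a) for a in self.arcs)

    def _check(self, node: str) -> None:
        if node not in self.nodes:
            raise ValidationError(f"unknown node {node!r}")


@dataclass(frozen=True)
class ArcBlacklist:
    """Forbidden directed arcs, checked during search and averaging.

    The canonical instance forbids every arc whose source is the terminal
    outcome: death cannot cause a complication.
    """

    forbidden: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "forbidden", frozenset((str(u), str(v)) for u, v in self.forbidden)
        )

    @classmethod
    def no_arcs_from(cls, source: str, nodes: Iterable[str]) -> "ArcBlacklist":
        return cls(frozenset((source, v) for v in nodes if v != source))

    @classmethod
    def default_for(cls, catalog: VariableCatalog) -> "ArcBlacklist":
        return cls.no_arcs_from(catalog.outcome, catalog.names)

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.forbidden

    def validate_against(self, nodes: Iterable[str]) -> None:
        known = set(nodes)
        for u, v in self.forbidden:
            if u not in known or v not in known:
                raise ValidationError(
                    f"blacklisted arc ({u!r}, {v!r}) references unknown node"
                )


@dataclass(frozen=True)
class ScoreValue:
    """Decomposable network score: total plus per-node family terms."""

    total: float
    per_node: Mapping[str, float]
    score: str = "bic"


@dataclass(frozen=True)
class ArcConfidence:
    """Bootstrap arc strengths and direction probabilities.

    For each unordered pair ``{u, v}`` (stored under its sorted tuple),
    ``strength`` is the fraction of bootstrap networks containing the arc in
    either direction, and ``direction`` maps each orientation to the
    fraction — among replicates containing the pair — orienting it that way,
    so the two orientations always sum to 1 whenever strength > 0.
    """

    nodes: tuple[str, ...]
    pairs: Mapping[tuple[str, str], float]            # sorted pair -> strength
    direction: Mapping[tuple[str, str], float]        # ordered arc -> prob
    n_replicates: int

    def strength(self, u: str, v: str) -> float:
        return float(self.pairs.get(tuple(sorted((u, v))), 0.0))

    def direction_prob(self, u: str, v: str) -> float:
        """P(u -> v | the pair is present); 0.0 for absent pairs."""
        return float(self.direction.get((u, v), 0.0))


def markov_blanket(dag: DAGStructure, node: str) -> frozenset[str]:
    """Parents, children and co-parents of children, excluding the node.

    Conditioning on the blanket renders ``node`` independent of every other
    variable in the network.
    """
    dag._check(node)
    parents = set(dag.parents(node))
    children = set(dag.children(node))
    spouses = {p for c in children for p in dag.parents(c)}
    return frozenset((parents | children | spouses) - {node})


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------


class _FamilyScorer:
    """Cached decomposable family scores for one cohort.

    The BIC family score is the maximized multinomial log-likelihood of the
    node given its parents minus ``(log N / 2)`` per free parameter; a
    binary node with k parents has 2^k free parameters. Larger is better.
    """

    def __init__(self, data: np.ndarray, score: str = "bic") -> None:
        if score not in _SCORES:
            raise ValidationError(f"unknown score {score!r}; choose from {_SCORES}")
        self.data = np.ascontiguousarray(data, dtype=np.uint8)
        self.n = data.shape[0]
        self.score = score
        self._penalty_unit = 0.5 * np.log(self.n) if score == "bic" else 0.0
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ps = sorted(parents)
        k = len(ps)
        if k:
            code = self.data[:, ps].astype(np.int64) @ (1 << np.arange(k, dtype=np.int64))
            joint = code * 2 + self.data[:, node]
        else:
            joint = self.data[:, node].astype(np.int64)
        counts = np.bincount(joint, minlength=2 ** (k + 1)).reshape(2**k, 2)
        row_n = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(counts > 0, np.log(counts / row_n[:, None]), 0.0)
        ll = float(np.sum(counts * logp))
        val = ll - self._penalty_unit * (2**k)
        self._cache[key] = val
        return val


def score_network(
    dag: DAGStructure, cohort: CohortMatrix, score: str = "bic"
) -> ScoreValue:
    """Score a DAG on a cohort with a decomposable criterion.

    ``total`` equals the sum of the per-node family scores exactly (the
    decomposability the hill-climber exploits).
    """
    if tuple(dag.nodes) != tuple(cohort.catalog.names):
        raise ValidationError("DAG nodes do not match cohort catalog")
    scorer = _FamilyScorer(cohort.values, score)
    per_node = {}
    for i, name in enumerate(dag.nodes):
        pidx = frozenset(dag.nodes.index(p) for p in dag.parents(name))
        per_node[name] = scorer.family(i, pidx)
    return ScoreValue(total=float(sum(per_node.values())), per_node=per_node, score=score)


# --------------------------------------------------------------------------
# hill climbing
# --------------------------------------------------------------------------


def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    """Iterative DFS reachability on the adjacency-list representation."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        for nxt in children[stack.pop()]:
            if nxt == dst:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _climb(
    scorer: _FamilyScorer,
    names: tuple[str, ...],
    parents: list[frozenset[int]],
    forbidden: set[tuple[int, int]],
) -> tuple[list[frozenset[int]], float]:
    """Greedy ascent from an initial parent assignment to a local optimum."""
    n = len(names)
    children: list[set[int]] = [set() for _ in range(n)]
    for v in range(n):
        for u in parents[v]:
            children[u].add(v)
    fam = [scorer.family(v, parents[v]) for v in range(n)]

    # candidate (u, v) pairs in deterministic lexicographic-name order
    order = sorted(range(n), key=lambda i: names[i])
    pairs = [(u, v) for u in order for v in order if u != v]

    while True:
        best_delta = 0.0
        best: tuple[str, str, str, tuple] | None = None  # sort key + payload
        def consider(delta: float, key: tuple[str, str, str], payload: tuple) -> None:
            nonlocal best_delta, best
            if delta <= _EPS:
                return
            if delta > best_delta + _EPS or (
                best is not None
                and abs(delta - best_delta) <= _EPS
                and key < best[:3]
            ):
                best_delta, best = delta, (*key, payload)

        for u, v in pairs:
            if v not in children[u]:
                # add u -> v (skipped if it would close a cycle, including
                # the 2-cycle when v -> u already exists)
                if (u, v) not in forbidden and not _has_path(children, v, u):
                    delta = scorer.family(v, parents[v] | {u}) - fam[v]
                    consider(delta, (names[u], names[v], "add"), ("add", u, v))
            else:
                # delete u -> v
                delta = scorer.family(v, parents[v] - {u}) - fam[v]
                consider(delta, (names[u], names[v], "delete"), ("delete", u, v))
                # reverse u -> v (becomes v -> u)
                if (v, u) not in forbidden:
                    children[u].discard(v)
                    cycle = _has_path(children, u, v)
                    children[u].add(v)
                    if not cycle:
                        delta = (
                            scorer.family(v, parents[v] - {u})
                            - fam[v]
                            + scorer.family(u, parents[u] | {v})
                            - fam[u]
                        )
                        consider(
                            delta, (names[u], names[v], "reverse"), ("reverse", u, v)
                        )
        if best is None or best_delta <= _EPS:
            break
        move, u, v = best[3]
        if move == "add":
            parents[v] = parents[v] | {u}
            children[u].add(v)
        elif move == "delete":
            parents[v] = parents[v] - {u}
            children[u].discard(v)
        else:  # reverse
            parents[v] = parents[v] - {u}
            parents[u] = parents[u] | {v}
            children[u].discard(v)
            children[v].add(u)
        fam[v] = scorer.family(v, parents[v])
        fam[u] = scorer.family(u, parents[u])
    return parents, float(sum(fam))


def _random_start(
    forbidden: set[tuple[int, int]],
    n: int,
    rng: np.random.Generator,
    n_arcs: int | None = None,
) -> list[frozenset[int]]:
    """A seeded random DAG used as a restart's initial state.

    Greedy ascent from the empty graph resolves score-equivalent arc
    orientations by the deterministic tie-break, which can lock compound
    misorientations in place (single reversal moves cannot undo them).
    Restarting from random graphs explores different orientation basins,
    which perturbing the current optimum by arc additions alone does not.
    """
    n_arcs = n if n_arcs is None else n_arcs
    out: list[set[int]] = [set() for _ in range(n)]
    children: list[set[int]] = [set() for _ in range(n)]
    added = 0
    for _attempt in range(20 * n_arcs):
        if added >= n_arcs:
            break
        u, v = (int(x) for x in rng.integers(0, n, size=2))
        if u == v or v in children[u] or u in children[v] or (u, v) in forbidden:
            continue
        if _has_path(children, v, u):
            continue
        out[v].add(u)
        children[u].add(v)
        added += 1
    return [frozenset(p) for p in out]


def hill_climb(
    cohort: CohortMatrix,
    blacklist: ArcBlacklist | None = None,
    score: str = "bic",
    restarts: int = 0,
    seed: int = 0,
) -> DAGStructure:
    """Greedy hill-climbing structure search.

    Starts from the empty graph and repeatedly applies the best strictly
    score-improving single-arc move (add, delete or reverse) that keeps the
    graph acyclic and blacklist-compliant, until a local optimum. Ties are
    broken toward the lexicographically smallest ``(source, target, move)``
    so runs are fully deterministic. Optional random restarts re-climb from
    seeded random initial DAGs and keep the best-scoring optimum, escaping
    the orientation traps of a single greedy pass.
    """
    names = tuple(cohort.catalog.names)
    blacklist = blacklist if blacklist is not None else ArcBlacklist.default_for(cohort.catalog)
    blacklist.validate_against(names)
    idx = {n: i for i, n in enumerate(names)}
    forbidden = {(idx[u], idx[v]) for u, v in blacklist.forbidden}
    scorer = _FamilyScorer(cohort.values, score)
    n = len(names)

    parents, best_score = _climb(scorer, names, [frozenset()] * n, forbidden)
    if restarts > 0:
        rng = np.random.default_rng(derive_seed(seed, 0))
        for _ in range(int(restarts)):
            start = _random_start(forbidden, n, rng)
            cand, cand_score = _climb(scorer, names, start, forbidden)
            if cand_score > best_score + _EPS:
                parents, best_score = cand, cand_score

    arcs = frozenset(
        (names[u], names[v]) for v in range(n) for u in parents[v]
    )
    return DAGStructure(nodes=names, arcs=arcs)


# --------------------------------------------------------------------------
# bootstrap model averaging
# --------------------------------------------------------------------------


def bootstrap_arcs(
    cohort: CohortMatrix,
    blacklist: ArcBlacklist | None = None,
    replicates: int = 1000,
    seed: int = 0,
    score: str = "bic",
    restarts: int = 4,
) -> ArcConfidence:
    """Bootstrap model averaging over hill-climbed networks.

    Each replicate resamples N patients with replacement (seeded with
    ``seed + replicate_index``), learns a network, and tallies each arc's
    presence and orientation. Strength is the fraction of replicates
    containing the pair in either direction; direction probability is
    conditional on presence.

    Replicate searches use 4 random restarts by default: a single greedy
    pass resolves score-equivalent orientations by its deterministic
    tie-break, so every replicate would fall into the same orientation
    basin and its artifacts would masquerade as high-strength arcs.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    names = tuple(cohort.catalog.names)
    blacklist = blacklist if blacklist is not None else ArcBlacklist.default_for(cohort.catalog)
    n = cohort.n_patients
    arc_counts: dict[tuple[str, str], int] = {}
    for r in range(int(replicates)):
        rng = np.random.default_rng(derive_seed(seed, r))
        rows = rng.integers(0, n, size=n)
        boot = CohortMatrix(catalog=cohort.catalog, values=cohort.values[rows])
        dag = hill_climb(boot, blacklist=blacklist, score=score,
                         restarts=restarts, seed=derive_seed(seed, r))
        for arc in dag.arcs:
            arc_counts[arc] = arc_counts.get(arc, 0) + 1

    pairs: dict[tuple[str, str], float] = {}
    direction: dict[tuple[str, str], float] = {}
    seen_pairs = {tuple(sorted((u, v))) for u, v in arc_counts}
    for a, b in sorted(seen_pairs):
        n_ab = arc_counts.get((a, b), 0)
        n_ba = arc_counts.get((b, a), 0)
        present = n_ab + n_ba
        pairs[(a, b)] = present / replicates
        direction[(a, b)] = n_ab / present
        direction[(b, a)] = n_ba / present
    return ArcConfidence(
        nodes=names, pairs=pairs, direction=direction, n_replicates=int(replicates)
    )


def averaged_network(
    conf: ArcConfidence,
    strength_min: float = 0.75,
    direction_min: float = 0.5,
    blacklist: ArcBlacklist | None = None,
) -> DAGStructure:
    """Threshold the bootstrap tallies into a single averaged DAG.

    Pairs with strength strictly above ``strength_min`` are kept and
    oriented in their majority direction provided that direction's
    probability is at least ``direction_min``. Should the kept arcs contain
    a directed cycle (possible because replicates disagree), the
    lowest-strength arc on each cycle is dropped until the graph is acyclic
    — preserving the strongest evidence.
    """
    for thr, label in ((strength_min, "strength_min"), (direction_min, "direction_min")):
        if not (0.0 <= thr <= 1.0):
            raise ValidationError(f"{label} must lie in [0, 1], got {thr}")
    arcs: dict[tuple[str, str], float] = {}
    for (a, b), strength in conf.pairs.items():
        if strength <= strength_min:
            continue
        d_ab = conf.direction_prob(a, b)
        d_ba = conf.direction_prob(b, a)
        u, v = (a, b) if d_ab >= d_ba else (b, a)
        if max(d_ab, d_ba) < direction_min:
            continue
        if blacklist is not None and not blacklist.allows(u, v):
            # fall back to the admissible orientation when it clears the bar
            u, v = v, u
            if not blacklist.allows(u, v) or min(d_ab, d_ba) < direction_min:
                continue
        arcs[(u, v)] = strength

    g = nx.DiGraph()
    g.add_nodes_from(conf.nodes)
    g.add_edges_from(arcs)
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        weakest = min(((u, v) for u, v, _ in cycle), key=lambda e: (arcs[e], e))
        g.remove_edge(*weakest)
        del arcs[weakest]
    return DAGStructure(nodes=conf.nodes, arcs=frozenset(arcs))
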