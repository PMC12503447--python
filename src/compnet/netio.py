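"""JSON and DOT serialization of networks.

One JSON schema covers plain DAGs, bootstrap-averaged networks (arcs carry
strength and direction probability) and fully parameterized models (CPTs
embedded per node), so the ground-truth spec of the simulator and the
learned network round-trip through the same reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .catalog import VariableCatalog
from .errors import FormatError
from .parameters import ConditionalTable, DiscreteBN
from .structure import ArcConfidence, DAGStructure
from .synthetic import GroundTruthSpec

__all__ = [
    "network_to_json",
    "save_network",
    "load_dag",
    "load_bn",
    "load_ground_truth",
    "save_ground_truth",
    "to_dot",
]


def _cpt_payload(table: ConditionalTable) -> dict:
    rows = []
    for cfg in range(table.n_configs):
        rows.append(
            {
                "config": [(cfg >> j) & 1 for j in range(len(table.parents))],
                "p1": float(table.p1[cfg]),
                "n": int(table.counts[cfg]),
                "unsupported": bool(table.unsupported[cfg]),
            }
        )
    return {"node": table.node, "parents": list(table.parents), "table": rows}


def network_to_json(
    dag: DAGStructure,
    outcome: str | None = None,
    confidence: ArcConfidence | None = None,
    bn: DiscreteBN | None = None,
    score: Mapping[str, float] | None = None,
    config: Mapping[str, object] | None = None,
) -> dict:
    arcs = []
    for u, v in sorted(dag.arcs):
        entry: dict[str, object] = {"from": u, "to": v}
        if confidence is not None:
            entry["strength"] = confidence.strength(u, v)
            entry["direction_prob"] = confidence.direction_prob(u, v)
        arcs.append(entry)
    payload: dict[str, object] = {"nodes": list(dag.nodes), "arcs": arcs}
    if outcome is not None:
        payload["outcome"] = outcome
    if bn is not None:
        payload["cpts"] = [_cpt_payload(bn.tables[n]) for n in dag.nodes]
    if score is not None:
        payload["score"] = dict(score)
    if config is not None:
        payload["config"] = dict(config)
    return payload


def save_network(path: str | Path, **kwargs) -> Path:
    path = Path(path)
    path.write_text(json.dumps(network_to_json(**kwargs), indent=2) + "\n")
    return path


def _load(path: str | Path) -> dict:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read network JSON {path}: {exc}") from exc
    if "nodes" not in payload or "arcs" not in payload:
        raise FormatError(f"network JSON {path} lacks 'nodes'/'arcs'")
    return payload


def load_dag(path: str | Path) -> DAGStructure:
    payload = _load(path)
    arcs = frozenset((a["from"], a["to"]) for a in payload["arcs"])
    return DAGStructure(nodes=tuple(payload["nodes"]), arcs=arcs)


def _tables_from_payload(payload: dict) -> dict[str, ConditionalTable]:
    tables: dict[str, ConditionalTable] = {}
    for entry in payload["cpts"]:
        parents = tuple(entry["parents"])
        k = len(parents)
        p1 = np.empty(2**k)
        counts = np.zeros(2**k, dtype=np.int64)
        unsupported = np.zeros(2**k, dtype=bool)
        for row in entry["table"]:
            cfg = sum(int(b) << j for j, b in enumerate(row["config"]))
            p1[cfg] = row["p1"]
            counts[cfg] = row.get("n", 0)
            unsupported[cfg] = row.get("unsupported", False)
        tables[entry["node"]] = ConditionalTable(
            node=entry["node"], parents=parents, p1=p1,
            counts=counts, unsupported=unsupported,
        )
    return tables


def load_bn(path: str | Path) -> DiscreteBN:
    payload = _load(path)
    if "cpts" not in payload:
        raise FormatError(f"network JSON {path} has no CPTs; use load_dag")
    dag = DAGStructure(
        nodes=tuple(payload["nodes"]),
        arcs=frozenset((a["from"], a["to"]) for a in payload["arcs"]),
    )
    return DiscreteBN(dag=dag, tables=_tables_from_payload(payload))


def save_ground_truth(spec: GroundTruthSpec, path: str | Path) -> Path:
    payload = network_to_json(
        spec.dag,
        outcome=spec.catalog.outcome,
        bn=spec.bn,
        config={"n_patients": spec.n_patients, "seed": spec.seed},
    )
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_ground_truth(path: str | Path) -> GroundTruthSpec:
    payload = _load(path)
    if "cpts" not in payload:
        raise FormatError(f"ground-truth JSON {path} has no CPTs")
    outcome = payload.get("outcome", "death")
    catalog = VariableCatalog(names=tuple(payload["nodes"]), outcome=outcome)
    dag = DAGStructure(
        nodes=catalog.names,
        arcs=frozenset((a["from"], a["to"]) for a in payload["arcs"]),
    )
    config = payload.get("config", {})
    return GroundTruthSpec(
        catalog=catalog,
        dag=dag,
        cpts=_tables_from_payload(payload),
        n_patients=int(config.get("n_patients", 18585)),
        seed=int(config.get("seed", 0)),
    )


def to_dot(
    dag: DAGStructure,
    confidence: ArcConfidence | None = None,
    outcome: str | None = None,
) -> str:
    """Graphviz DOT text for the network (arc labels = bootstrap strength)."""
    lines = ["digraph complications {", "  rankdir=LR;"]
    for node in dag.nodes:
        shape = "doublecircle" if node == outcome else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v in sorted(dag.arcs):
        if confidence is not None:
            s = confidence.strength(u, v)
            d = confidence.direction_prob(u, v)
            lines.append(f'  "{u}" -> "{v}" [label="{s:.2f}/{d:.2f}"];')
        else:
            lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
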