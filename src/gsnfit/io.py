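"""Versioned JSON document format and Graphviz DOT export.

The on-disk dialect is ``{"format": "gsn-argument", "version": 1, ...}``.
Saving is canonical — nodes sorted by uid, edges sorted by
(source, target, kind), keys sorted, two-space indent, UTF-8, trailing
newline — so equal graphs serialize to identical bytes on any platform.
Child order, which sorting would destroy, is preserved through an explicit
``ordinal`` field on every edge (the child's position among its parent's
children at insertion time).

Loading raises on documents that cannot yield a usable graph (wrong format
tag, unknown kind, duplicated uid, edge to a missing node) and reports
every soft rule violation through :func:`gsnfit.core.validate`.
"""

from __future__ import annotations

import json
from typing import Any

from .core import (
    ArgumentEdge,
    ArgumentGraph,
    ArgumentNode,
    EdgeKind,
    NodeKind,
    Status,
    ValidationIssue,
    validate,
)
from .errors import (
    DanglingEdgeError,
    DocumentFormatError,
    DuplicateUidError,
    GraphValidationError,
)

__all__ = ["save", "load", "export_dot", "FORMAT_TAG", "FORMAT_VERSION"]

FORMAT_TAG = "gsn-argument"
FORMAT_VERSION = 1


def _require_well_formed(graph: ArgumentGraph) -> None:
    errors = [i for i in validate(graph) if i.severity == "error"]
    if errors:
        raise GraphValidationError(errors)


def save(graph: ArgumentGraph, meta: dict[str, str] | None = None) -> str:
    """Serialize a well-formed graph to canonical JSON text.

    ``meta`` overrides the graph's own metadata mapping when given.
    Byte-identical across repeated calls on equal graphs.
    """
    _require_well_formed(graph)
    ordinal: dict[tuple[str, str, str], int] = {}
    position: dict[str, int] = {}
    for e in graph.edges:
        k = position.get(e.source, 0)
        position[e.source] = k + 1
        ordinal[(e.source, e.target, e.kind.value)] = k
    doc: dict[str, Any] = {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "meta": dict(meta if meta is not None else graph.meta),
        "root": graph.root,
        "nodes": [
            {
                "uid": n.uid,
                "kind": n.kind.value,
                "statement": n.statement,
                "label": n.label,
                "links": list(n.links),
                "status": n.status.value,
                "collapsed": n.collapsed,
            }
            for _, n in sorted(graph.nodes.items())
        ],
        "edges": sorted(
            (
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind.value,
                    "ordinal": ordinal[(e.source, e.target, e.kind.value)],
                }
                for e in graph.edges
            ),
            key=lambda r: (r["source"], r["target"], r["kind"]),
        ),
    }
    return json.dumps(doc, ensure_ascii=False, indent=2, sort_keys=True) + "\n"


def _expect(condition: bool, message: str) -> None:
    if not condition:
        raise DocumentFormatError(message)


def load(text: str) -> tuple[ArgumentGraph, list[ValidationIssue]]:
    """Decode a document into a graph plus its validation issues.

    Unusable documents raise (:class:`DocumentFormatError`,
    :class:`DuplicateUidError`, :class:`DanglingEdgeError`); structural rule
    violations that still yield a usable graph are returned as issues.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentFormatError(f"not valid JSON: {exc}") from exc
    _expect(isinstance(doc, dict), "document must be a JSON object")
    _expect(doc.get("format") == FORMAT_TAG,
            f"format tag must be {FORMAT_TAG!r}, got {doc.get('format')!r}")
    _expect(doc.get("version") == FORMAT_VERSION,
            f"unsupported version {doc.get('version')!r}")
    for key in ("root", "nodes", "edges"):
        _expect(key in doc, f"missing required key {key!r}")

    graph = ArgumentGraph()
    graph.meta = {str(k): str(v) for k, v in dict(doc.get("meta") or {}).items()}
    graph.root = doc["root"]

    for rec in doc["nodes"]:
        _expect(isinstance(rec, dict) and "uid" in rec and "kind" in rec,
                "each node record needs at least uid and kind")
        uid = rec["uid"]
        _expect(isinstance(uid, str) and uid != "", "node uid must be non-empty text")
        if uid in graph.nodes:
            raise DuplicateUidError(f"uid {uid!r} declared more than once")
        try:
            kind = NodeKind(rec["kind"])
        except ValueError:
            raise DocumentFormatError(f"unknown node kind {rec['kind']!r}") from None
        try:
            status = Status(rec.get("status", "developed"))
        except ValueError:
            raise DocumentFormatError(f"unknown status {rec.get('status')!r}") from None
        graph.nodes[uid] = ArgumentNode(
            uid=uid,
            kind=kind,
            statement=str(rec.get("statement", "")),
            label=str(rec.get("label", "")),
            links=[str(u) for u in rec.get("links", [])],
            status=status,
            collapsed=bool(rec.get("collapsed", False)),
        )

    decoded_edges = []
    for rec in doc["edges"]:
        _expect(isinstance(rec, dict) and "source" in rec and "target" in rec
                and "kind" in rec, "each edge record needs source, target and kind")
        try:
            kind = EdgeKind(rec["kind"])
        except ValueError:
            raise DocumentFormatError(f"unknown edge kind {rec['kind']!r}") from None
        for endpoint in (rec["source"], rec["target"]):
            if endpoint not in graph.nodes:
                raise DanglingEdgeError(
                    f"edge references undeclared uid {endpoint!r}"
                )
        decoded_edges.append(
            (int(rec.get("ordinal", 0)), ArgumentEdge(rec["source"], rec["target"], kind))
        )
    # rebuild per-parent insertion order from the ordinals
    decoded_edges.sort(key=lambda t: (t[1].source, t[0], t[1].target, t[1].kind.value))
    graph.edges = [e for _, e in decoded_edges]
    return graph, validate(graph)


# -- DOT export --------------------------------------------------------------

_DOT_SHAPE = {
    NodeKind.GOAL: "shape=box",
    NodeKind.STRATEGY: "shape=parallelogram",
    NodeKind.CONTEXT: "shape=box, style=rounded",
    NodeKind.ASSUMPTION: "shape=ellipse",
    NodeKind.JUSTIFICATION: "shape=ellipse",
    NodeKind.EVIDENCE: "shape=circle",
}

_DOT_TAG = {NodeKind.ASSUMPTION: " [A]", NodeKind.JUSTIFICATION: " [J]"}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def export_dot(graph: ArgumentGraph) -> str:
    """Render the graph as Graphviz DOT text (one-way export).

    Shapes follow the notation (goals boxes, strategies parallelograms,
    context rounded, assumption/justification ellipses tagged [A]/[J],
    evidence circles); supported_by edges carry a filled arrowhead,
    in_context_of an empty one. Output is deterministic.
    """
    _require_well_formed(graph)
    lines = ["digraph argument {", "  rankdir=TB;", "  node [fontsize=10];"]
    for uid, n in sorted(graph.nodes.items()):
        text = (f"{n.label}: " if n.label else "") + n.statement + _DOT_TAG.get(n.kind, "")
        if n.status is Status.UNDEVELOPED:
            text += " ◇"  # open diamond, the undeveloped marker
        lines.append(f'  "{_dot_escape(uid)}" [{_DOT_SHAPE[n.kind]}, label="{_dot_escape(text)}"];')
    for e in sorted(graph.edges, key=lambda e: (e.source, e.target, e.kind.value)):
        head = "normal" if e.kind is EdgeKind.SUPPORTED_BY else "empty"
        lines.append(
            f'  "{_dot_escape(e.source)}" -> "{_dot_escape(e.target)}" [arrowhead={head}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
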