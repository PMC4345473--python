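"""Typed argument graphs in a goal-structuring-notation (GSN) dialect.

An argument is a rooted tree of typed nodes. *Goals* (claims) are the
statements the argument seeks to substantiate; *strategies* decompose a
claim into sub-claims; *evidence* nodes terminate branches with statistical
results or literature; *context*, *assumption* and *justification* nodes
scope a claim or strategy without extending the support chain. Two edge
kinds mirror the two GSN connector styles: ``supported_by`` (drawn with a
solid arrowhead) carries the support hierarchy, ``in_context_of`` (open
arrowhead) attaches the scoping nodes.

Goals that cannot currently be substantiated — gaps in the biological
understanding — are marked ``undeveloped`` and drawn with an open diamond;
they must be childless so the marker is unambiguous.

The construction API (:func:`create_graph`, :meth:`ArgumentGraph.add_child`,
...) can only produce well-formed graphs; :func:`validate` additionally
accepts arbitrary hand-built or decoded graphs and reports every rule
violation as a :class:`ValidationIssue` instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .errors import (
    EdgeTypingError,
    GraphValidationError,
    InvalidArgumentError,
    NodeNotFoundError,
)

__all__ = [
    "NodeKind",
    "EdgeKind",
    "Status",
    "ArgumentNode",
    "ArgumentEdge",
    "ArgumentGraph",
    "ValidationIssue",
    "ArgumentMetrics",
    "create_graph",
    "validate",
    "assign_labels",
    "undeveloped_claims",
    "metrics",
]


class NodeKind(str, Enum):
    GOAL = "goal"
    STRATEGY = "strategy"
    CONTEXT = "context"
    ASSUMPTION = "assumption"
    JUSTIFICATION = "justification"
    EVIDENCE = "evidence"


#: Node kinds attached with in_context_of edges (the "scoping" family).
CONTEXT_FAMILY = frozenset(
    {NodeKind.CONTEXT, NodeKind.ASSUMPTION, NodeKind.JUSTIFICATION}
)


class EdgeKind(str, Enum):
    SUPPORTED_BY = "supported_by"
    IN_CONTEXT_OF = "in_context_of"


class Status(str, Enum):
    DEVELOPED = "developed"
    UNDEVELOPED = "undeveloped"


@dataclass
class ArgumentNode:
    """One argument element.

    ``label`` is the dotted identifier written by :func:`assign_labels`
    (empty until labelling); ``links`` holds URIs to external evidence
    (publications, analysis reports); ``collapsed`` is a rendering hint
    that hides the node's subtree and is drawn as a filled diamond.
    """

    uid: str
    kind: NodeKind
    statement: str
    label: str = ""
    links: list[str] = field(default_factory=list)
    status: Status = Status.DEVELOPED
    collapsed: bool = False


@dataclass(frozen=True)
class ArgumentEdge:
    source: str
    target: str
    kind: EdgeKind


@dataclass
class ValidationIssue:
    """One well-formedness violation.

    ``code`` is one of the fixed rule codes (NO_ROOT, ROOT_NOT_GOAL,
    MULTIPLE_ROOTS, CYCLE, UNREACHABLE, BAD_EDGE_TYPING, EVIDENCE_NOT_LEAF,
    UNDEVELOPED_NOT_GOAL, UNDEVELOPED_WITH_CHILDREN, DANGLING_EDGE,
    DUPLICATE_UID); ``severity`` is "error" or "warning".
    """

    code: str
    severity: str
    uids: list[str]
    message: str


@dataclass
class ArgumentMetrics:
    """Completeness summary a reviewer can scan before reading the tree.

    A *terminal goal* is a goal none of whose supported_by children are
    goals or strategies — the front line of the argument. It is
    *substantiated* when at least one evidence node hangs off it;
    ``coverage`` is the substantiated fraction (0 when there are no
    terminal goals).
    """

    n_by_kind: dict[str, int]
    max_depth: int
    n_undeveloped: int
    n_terminal_goals: int
    n_substantiated_terminal_goals: int
    coverage: float


# (parent kind, child kind) pairs reachable through add_child. The value is
# the inferred edge kind; "warn" marks pairings validate() flags as warnings.
_LEGAL_CHILD: dict[tuple[NodeKind, NodeKind], EdgeKind] = {}
for _p in (NodeKind.GOAL, NodeKind.STRATEGY):
    for _c in CONTEXT_FAMILY:
        _LEGAL_CHILD[(_p, _c)] = EdgeKind.IN_CONTEXT_OF
_LEGAL_CHILD[(NodeKind.GOAL, NodeKind.GOAL)] = EdgeKind.SUPPORTED_BY
_LEGAL_CHILD[(NodeKind.GOAL, NodeKind.STRATEGY)] = EdgeKind.SUPPORTED_BY
_LEGAL_CHILD[(NodeKind.GOAL, NodeKind.EVIDENCE)] = EdgeKind.SUPPORTED_BY
_LEGAL_CHILD[(NodeKind.STRATEGY, NodeKind.GOAL)] = EdgeKind.SUPPORTED_BY
# permitted but reported as a warning by validate(): the notation anchors
# evidence to claims, not to the reasoning step itself
_LEGAL_CHILD[(NodeKind.STRATEGY, NodeKind.EVIDENCE)] = EdgeKind.SUPPORTED_BY


@dataclass
class ArgumentGraph:
    """A rooted tree of argument nodes with ordered children.

    ``edges`` preserves insertion order; the per-parent ordering of children
    is the canonical child order used by labelling, serialization and
    layout.
    """

    nodes: dict[str, ArgumentNode] = field(default_factory=dict)
    edges: list[ArgumentEdge] = field(default_factory=list)
    root: str = ""
    meta: dict[str, str] = field(default_factory=dict)
    _uid_counter: int = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def new(cls, root_statement: str) -> "ArgumentGraph":
        if not root_statement or not root_statement.strip():
            raise InvalidArgumentError("root statement must be non-empty")
        g = cls()
        uid = g._next_uid()
        g.nodes[uid] = ArgumentNode(uid=uid, kind=NodeKind.GOAL, statement=root_statement)
        g.root = uid
        return g

    def _next_uid(self) -> str:
        while True:
            self._uid_counter += 1
            uid = f"n{self._uid_counter}"
            if uid not in self.nodes:
                return uid

    def add_child(
        self,
        parent_uid: str,
        kind: NodeKind | str,
        statement: str,
        *,
        uid: str | None = None,
        links: list[str] | None = None,
    ) -> str:
        """Add a node under ``parent_uid``, inferring the edge kind.

        Context-family children attach with in_context_of, everything else
        with supported_by. Returns the new node's uid.
        """
        kind = NodeKind(kind)
        if not statement or not statement.strip():
            raise InvalidArgumentError("statement must be non-empty")
        parent = self.node(parent_uid)
        pairing = _LEGAL_CHILD.get((parent.kind, kind))
        if pairing is None:
            raise EdgeTypingError(
                f"a {kind.value} node cannot be a child of a {parent.kind.value} node"
            )
        if parent.status is Status.UNDEVELOPED and pairing is EdgeKind.SUPPORTED_BY:
            raise EdgeTypingError(
                "an undeveloped goal cannot acquire supporting children; "
                "mark it developed first"
            )
        if uid is None:
            uid = self._next_uid()
        elif uid in self.nodes:
            raise InvalidArgumentError(f"uid {uid!r} already exists")
        self.nodes[uid] = ArgumentNode(
            uid=uid, kind=kind, statement=statement, links=list(links or [])
        )
        self.edges.append(ArgumentEdge(source=parent_uid, target=uid, kind=pairing))
        return uid

    def set_status(self, uid: str, status: Status | str) -> "ArgumentGraph":
        """Mark a goal developed/undeveloped.

        Undeveloped is only meaningful on a goal with no supporting
        children: the open-diamond marker flags a claim nothing argues for.
        """
        status = Status(status)
        node = self.node(uid)
        if status is Status.UNDEVELOPED:
            if node.kind is not NodeKind.GOAL:
                raise EdgeTypingError(
                    f"only goals may be undeveloped, not {node.kind.value}"
                )
            if self.children(uid, EdgeKind.SUPPORTED_BY):
                raise EdgeTypingError(
                    "a goal with supporting children cannot be undeveloped"
                )
        node.status = status
        return self

    def collapse(self, uid: str, flag: bool = True) -> "ArgumentGraph":
        """Set the rendering-time collapsed flag; structure is unchanged."""
        node = self.node(uid)
        if not self.children(uid, EdgeKind.SUPPORTED_BY):
            raise InvalidArgumentError(
                f"node {uid!r} has no supporting children to collapse"
            )
        node.collapsed = bool(flag)
        return self

    # -- access ------------------------------------------------------------

    def node(self, uid: str) -> ArgumentNode:
        try:
            return self.nodes[uid]
        except KeyError:
            raise NodeNotFoundError(f"no node with uid {uid!r}") from None

    def children(self, uid: str, kind: EdgeKind | None = None) -> list[str]:
        """Child uids of ``uid`` in insertion order, optionally per edge kind."""
        return [
            e.target
            for e in self.edges
            if e.source == uid and (kind is None or e.kind == kind)
        ]

    def parent(self, uid: str) -> str | None:
        for e in self.edges:
            if e.target == uid:
                return e.source
        return None

    def node_by_label(self, label: str) -> ArgumentNode:
        for n in self.nodes.values():
            if n.label == label:
                return n
        raise NodeNotFoundError(f"no node with label {label!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArgumentGraph):
            return NotImplemented
        if self.root != other.root or set(self.nodes) != set(other.nodes):
            return False
        for uid, n in self.nodes.items():
            m = other.nodes[uid]
            if (n.kind, n.statement, n.links, n.status, n.collapsed) != (
                m.kind, m.statement, m.links, m.status, m.collapsed
            ):
                return False
        # per-parent ordered children, not global edge-list order
        for uid in self.nodes:
            for ek in EdgeKind:
                if self.children(uid, ek) != other.children(uid, ek):
                    return False
        return True


def create_graph(root_statement: str) -> ArgumentGraph:
    """Start a new argument from its top-level claim."""
    return ArgumentGraph.new(root_statement)


# -- validation -------------------------------------------------------------


def _issue(code, severity, uids, message) -> ValidationIssue:
    return ValidationIssue(code=code, severity=severity, uids=sorted(uids), message=message)


def validate(graph: ArgumentGraph) -> list[ValidationIssue]:
    """Check the GSN well-formedness rules; empty result ⇔ well-formed.

    Accepts arbitrary (possibly hand-built or decoded) graphs. The rules:
    a single goal root; acyclic; everything reachable from the root;
    supported_by only from goals/strategies onto goals/strategies/evidence
    (strategies onto goals or evidence only); evidence nodes are leaves;
    in_context_of only from goals/strategies onto context-family nodes;
    undeveloped only on childless goals; no dangling edge endpoints; unique
    uids. A supported_by edge from a strategy straight to evidence is legal
    but flagged as a warning, since the notation anchors evidence to claims.
    """
    issues: list[ValidationIssue] = []

    # uid bookkeeping: mapping keys disagreeing with node.uid, or two keys
    # carrying the same node.uid, indicate a corrupt/duplicated identity
    bad_uid: set[str] = set()
    seen_uids: dict[str, str] = {}
    for key, node in graph.nodes.items():
        if node.uid != key or not node.uid:
            bad_uid.add(key)
        elif node.uid in seen_uids:
            bad_uid.add(key)
        else:
            seen_uids[node.uid] = key
    if bad_uid:
        issues.append(
            _issue(
                "DUPLICATE_UID", "error", bad_uid,
                "node uid duplicated or inconsistent with its mapping key",
            )
        )
    known = set(graph.nodes) - bad_uid

    # dangling edges are excluded from every later check
    dangling = [
        e for e in graph.edges if e.source not in known or e.target not in known
    ]
    if dangling:
        issues.append(
            _issue(
                "DANGLING_EDGE", "error",
                {u for e in dangling for u in (e.source, e.target) if u not in known},
                f"{len(dangling)} edge(s) reference undeclared uids",
            )
        )
    edges = [e for e in graph.edges if e not in dangling]

    # root
    has_root = graph.root in known
    if not has_root:
        issues.append(
            _issue("NO_ROOT", "error", [graph.root] if graph.root else [],
                   "graph root is missing or not a declared node")
        )
    elif graph.nodes[graph.root].kind is not NodeKind.GOAL:
        issues.append(
            _issue("ROOT_NOT_GOAL", "error", [graph.root],
                   "the root of an argument must be a goal (the top-level claim)")
        )

    dg = nx.MultiDiGraph()
    dg.add_nodes_from(known)
    dg.add_edges_from((e.source, e.target) for e in edges)

    cyclic: set[str] = set()
    for scc in nx.strongly_connected_components(dg):
        if len(scc) > 1 or dg.has_edge(next(iter(scc)), next(iter(scc))):
            cyclic |= scc
    if cyclic:
        issues.append(
            _issue("CYCLE", "error", cyclic,
                   "argument contains a cycle; it must be a tree")
        )

    if has_root:
        parented = {e.target for e in edges}
        extra_roots = {
            u for u in known
            if u != graph.root and u not in parented
            and graph.nodes[u].kind is NodeKind.GOAL
        }
        if extra_roots:
            issues.append(
                _issue("MULTIPLE_ROOTS", "error", extra_roots,
                       "parentless goal(s) beside the declared root")
            )
        reachable = {graph.root} | nx.descendants(dg, graph.root)
        unreachable = known - reachable - extra_roots - cyclic
        if unreachable:
            issues.append(
                _issue("UNREACHABLE", "error", unreachable,
                       "node(s) not reachable from the root")
            )

    # edge typing; evidence sources get the more specific EVIDENCE_NOT_LEAF
    evidence_sources: set[str] = set()
    typing_errors: set[str] = set()
    typing_warnings: set[str] = set()
    for e in edges:
        sk = graph.nodes[e.source].kind
        tk = graph.nodes[e.target].kind
        if sk is NodeKind.EVIDENCE:
            evidence_sources.add(e.source)
            continue
        if e.kind is EdgeKind.SUPPORTED_BY:
            if sk not in (NodeKind.GOAL, NodeKind.STRATEGY) or tk in CONTEXT_FAMILY:
                typing_errors.add(e.source); typing_errors.add(e.target)
            elif sk is NodeKind.STRATEGY and tk is NodeKind.STRATEGY:
                typing_errors.add(e.source); typing_errors.add(e.target)
            elif sk is NodeKind.STRATEGY and tk is NodeKind.EVIDENCE:
                typing_warnings.add(e.source); typing_warnings.add(e.target)
        else:  # in_context_of
            if sk not in (NodeKind.GOAL, NodeKind.STRATEGY) or tk not in CONTEXT_FAMILY:
                typing_errors.add(e.source); typing_errors.add(e.target)
    if evidence_sources:
        issues.append(
            _issue("EVIDENCE_NOT_LEAF", "error", evidence_sources,
                   "evidence nodes must be leaves")
        )
    if typing_errors:
        issues.append(
            _issue("BAD_EDGE_TYPING", "error", typing_errors,
                   "edge connects node kinds the notation does not allow")
        )
    if typing_warnings:
        issues.append(
            _issue("BAD_EDGE_TYPING", "warning", typing_warnings,
                   "evidence attached directly to a strategy; anchor it to a claim")
        )

    # undeveloped markers
    undeveloped_not_goal = {
        u for u in known
        if graph.nodes[u].status is Status.UNDEVELOPED
        and graph.nodes[u].kind is not NodeKind.GOAL
    }
    if undeveloped_not_goal:
        issues.append(
            _issue("UNDEVELOPED_NOT_GOAL", "error", undeveloped_not_goal,
                   "only goals may carry the undeveloped marker")
        )
    supported_children = {
        e.source for e in edges if e.kind is EdgeKind.SUPPORTED_BY
    }
    undeveloped_with_children = {
        u for u in known
        if graph.nodes[u].status is Status.UNDEVELOPED
        and graph.nodes[u].kind is NodeKind.GOAL
        and u in supported_children
    }
    if undeveloped_with_children:
        issues.append(
            _issue("UNDEVELOPED_WITH_CHILDREN", "error", undeveloped_with_children,
                   "an undeveloped goal must have no supporting children")
        )
    return issues


def require_well_formed(graph: ArgumentGraph) -> None:
    """Raise :class:`GraphValidationError` when validate() reports errors."""
    errors = [i for i in validate(graph) if i.severity == "error"]
    if errors:
        raise GraphValidationError(errors)


# -- labelling ---------------------------------------------------------------

_CONTEXT_SUFFIX = {
    NodeKind.CONTEXT: "C",
    NodeKind.ASSUMPTION: "A",
    NodeKind.JUSTIFICATION: "J",
}


def assign_labels(graph: ArgumentGraph) -> dict[str, str]:
    """Write hierarchical dotted labels onto the nodes and return them.

    The root claim is "1"; the k-th supported_by child of a node labelled
    L is "L.k" (insertion order); context-family children get per-kind
    suffixes "L-C1", "L-A1", "L-J1". Idempotent.
    """
    require_well_formed(graph)
    labels: dict[str, str] = {}

    def walk(uid: str, label: str) -> None:
        labels[uid] = label
        graph.nodes[uid].label = label
        counters = {"C": 0, "A": 0, "J": 0}
        for child in graph.children(uid, EdgeKind.IN_CONTEXT_OF):
            suffix = _CONTEXT_SUFFIX[graph.nodes[child].kind]
            counters[suffix] += 1
            ctx_label = f"{label}-{suffix}{counters[suffix]}"
            labels[child] = ctx_label
            graph.nodes[child].label = ctx_label
        for k, child in enumerate(graph.children(uid, EdgeKind.SUPPORTED_BY), start=1):
            walk(child, f"{label}.{k}")

    walk(graph.root, "1")
    return labels


def _label_sort_key(label: str) -> tuple:
    parts = []
    for piece in label.replace("-", ".").split("."):
        parts.append((0, int(piece)) if piece.isdigit() else (1, piece))
    return tuple(parts)


def undeveloped_claims(graph: ArgumentGraph) -> list[str]:
    """Uids of undeveloped goals, sorted by dotted label.

    These are the argument's stated gaps: claims for which no evidence or
    decomposition currently exists.
    """
    assign_labels(graph)
    uids = [
        u for u, n in graph.nodes.items()
        if n.kind is NodeKind.GOAL and n.status is Status.UNDEVELOPED
    ]
    return sorted(uids, key=lambda u: _label_sort_key(graph.nodes[u].label))


# -- metrics ------------------------------------------------------------------


def metrics(graph: ArgumentGraph) -> ArgumentMetrics:
    """Completeness summary: kind counts, support depth, evidence coverage."""
    require_well_formed(graph)

    n_by_kind = {k.value: 0 for k in NodeKind}
    for n in graph.nodes.values():
        n_by_kind[n.kind.value] += 1

    depth: dict[str, int] = {}

    def walk(uid: str, d: int) -> None:
        depth[uid] = d
        for c in graph.children(uid, EdgeKind.IN_CONTEXT_OF):
            depth[c] = d  # scoping nodes share their anchor's level
        for c in graph.children(uid, EdgeKind.SUPPORTED_BY):
            walk(c, d + 1)

    walk(graph.root, 1)

    terminal, substantiated = 0, 0
    for uid, n in graph.nodes.items():
        if n.kind is not NodeKind.GOAL:
            continue
        kids = [graph.nodes[c] for c in graph.children(uid, EdgeKind.SUPPORTED_BY)]
        if any(k.kind in (NodeKind.GOAL, NodeKind.STRATEGY) for k in kids):
            continue
        terminal += 1
        if any(k.kind is NodeKind.EVIDENCE for k in kids):
            substantiated += 1

    n_undeveloped = sum(
        1 for n in graph.nodes.values()
        if n.kind is NodeKind.GOAL and n.status is Status.UNDEVELOPED
    )
    return ArgumentMetrics(
        n_by_kind=n_by_kind,
        max_depth=max(depth.values()),
        n_undeveloped=n_undeveloped,
        n_terminal_goals=terminal,
        n_substantiated_terminal_goals=substantiated,
        coverage=substantiated / terminal if terminal else 0.0,
    )


def format_metrics(m: ArgumentMetrics) -> str:
    """Plain-text report used by the CLI stats command."""
    lines = ["nodes by kind:"]
    for kind, count in m.n_by_kind.items():
        lines.append(f"  {kind:14s}{count}")
    lines += [
        f"max support depth: {m.max_depth}",
        f"undeveloped claims: {m.n_undeveloped}",
        f"terminal goals: {m.n_terminal_goals}",
        f"substantiated terminal goals: {m.n_substantiated_terminal_goals}",
        f"evidence coverage: {m.coverage:.3f}",
    ]
    return "\n".join(lines)
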