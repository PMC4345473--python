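"""Shared fixtures: small graphs and the single-rule mutation registry."""

from __future__ import annotations

import numpy as np
import pytest

from gsnfit import (
    ArgumentEdge,
    ArgumentNode,
    EdgeKind,
    NodeKind,
    Status,
    build_case_study,
    create_graph,
)


@pytest.fixture
def simple_graph():
    """root goal -> strategy -> goal -> evidence, plus a context on the root."""
    g = create_graph("the simulation is an adequate representation")
    ctx = g.add_child(g.root, NodeKind.CONTEXT, "purpose: hypothesis generation")
    s = g.add_child(g.root, NodeKind.STRATEGY, "argue over behaviour responses")
    c = g.add_child(s, NodeKind.GOAL, "velocity matches ex vivo observation")
    e = g.add_child(c, NodeKind.EVIDENCE, "Mann-Whitney U comparison")
    g.uids = {"ctx": ctx, "s": s, "c": c, "e": e}
    return g


@pytest.fixture
def case_study():
    return build_case_study()


@pytest.fixture
def rng():
    return np.random.default_rng(20150306)


def _flat_graph():
    """root goal -> goal child + context: safe base for kind flips."""
    g = create_graph("top-level claim")
    c = g.add_child(g.root, NodeKind.GOAL, "subclaim")
    ctx = g.add_child(g.root, NodeKind.CONTEXT, "scope")
    g.uids = {"c": c, "ctx": ctx}
    return g


def _deep_graph():
    g = create_graph("top-level claim")
    ctx = g.add_child(g.root, NodeKind.CONTEXT, "scope")
    s = g.add_child(g.root, NodeKind.STRATEGY, "argue over responses")
    c = g.add_child(s, NodeKind.GOAL, "subclaim")
    e = g.add_child(c, NodeKind.EVIDENCE, "statistics")
    g.uids = {"ctx": ctx, "s": s, "c": c, "e": e}
    return g


def _mut_no_root():
    g = _deep_graph()
    g.root = "missing"
    return g


def _mut_root_not_goal():
    g = _flat_graph()
    g.nodes[g.root].kind = NodeKind.STRATEGY
    return g


def _mut_multiple_roots():
    g = _deep_graph()
    g.nodes["orphan"] = ArgumentNode("orphan", NodeKind.GOAL, "a second root")
    return g


def _mut_cycle():
    g = _deep_graph()
    # goal -> strategy is legal typing, but closes a loop
    g.edges.append(ArgumentEdge(g.uids["c"], g.uids["s"], EdgeKind.SUPPORTED_BY))
    return g


def _mut_unreachable():
    g = _deep_graph()
    g.nodes["island"] = ArgumentNode("island", NodeKind.CONTEXT, "detached scope")
    return g


def _mut_bad_edge_typing():
    g = _deep_graph()
    # context held by a supported_by edge
    g.edges = [
        ArgumentEdge(e.source, e.target, EdgeKind.SUPPORTED_BY)
        if e.target == g.uids["ctx"] else e
        for e in g.edges
    ]
    return g


def _mut_evidence_not_leaf():
    g = _deep_graph()
    g.nodes["extra"] = ArgumentNode("extra", NodeKind.GOAL, "below evidence")
    g.edges.append(ArgumentEdge(g.uids["e"], "extra", EdgeKind.SUPPORTED_BY))
    return g


def _mut_undeveloped_not_goal():
    g = _deep_graph()
    g.nodes[g.uids["s"]].status = Status.UNDEVELOPED
    return g


def _mut_undeveloped_with_children():
    g = _deep_graph()
    g.nodes[g.uids["c"]].status = Status.UNDEVELOPED
    return g


def _mut_dangling_edge():
    g = _deep_graph()
    g.edges.append(ArgumentEdge(g.uids["c"], "ghost", EdgeKind.SUPPORTED_BY))
    return g


def _mut_duplicate_uid():
    g = _deep_graph()
    g.nodes["dup"] = ArgumentNode(g.uids["c"], NodeKind.GOAL, "uid clash")
    return g


#: code -> builder producing a graph violating exactly that one rule
RULE_MUTATIONS = {
    "NO_ROOT": _mut_no_root,
    "ROOT_NOT_GOAL": _mut_root_not_goal,
    "MULTIPLE_ROOTS": _mut_multiple_roots,
    "CYCLE": _mut_cycle,
    "UNREACHABLE": _mut_unreachable,
    "BAD_EDGE_TYPING": _mut_bad_edge_typing,
    "EVIDENCE_NOT_LEAF": _mut_evidence_not_leaf,
    "UNDEVELOPED_NOT_GOAL": _mut_undeveloped_not_goal,
    "UNDEVELOPED_WITH_CHILDREN": _mut_undeveloped_with_children,
    "DANGLING_EDGE": _mut_dangling_edge,
    "DUPLICATE_UID": _mut_duplicate_uid,
}
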