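"""Argument-graph model: construction, validation, labelling, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gsnfit
from gsnfit import (
    EdgeKind,
    EdgeTypingError,
    GraphValidationError,
    InvalidArgumentError,
    NodeKind,
    NodeNotFoundError,
    Status,
    assign_labels,
    create_graph,
    metrics,
    undeveloped_claims,
    validate,
)
from gsnfit.testing import random_argument_graph

from conftest import RULE_MUTATIONS


class TestConstruction:
    def test_create_graph_roots_a_goal(self):
        g = create_graph("our model is an adequate representation of the biology")
        assert g.nodes[g.root].kind is NodeKind.GOAL
        assert g.nodes[g.root].status is Status.DEVELOPED
        assert metrics(g).max_depth == 1

    def test_empty_statement_rejected(self):
        with pytest.raises(InvalidArgumentError):
            create_graph("")
        with pytest.raises(InvalidArgumentError):
            create_graph("   ")

    @pytest.mark.parametrize(
        "kind,expected_edge",
        [
            (NodeKind.STRATEGY, EdgeKind.SUPPORTED_BY),
            (NodeKind.GOAL, EdgeKind.SUPPORTED_BY),
            (NodeKind.EVIDENCE, EdgeKind.SUPPORTED_BY),
            (NodeKind.CONTEXT, EdgeKind.IN_CONTEXT_OF),
            (NodeKind.ASSUMPTION, EdgeKind.IN_CONTEXT_OF),
            (NodeKind.JUSTIFICATION, EdgeKind.IN_CONTEXT_OF),
        ],
    )
    def test_edge_kind_inferred_from_child_kind(self, kind, expected_edge):
        g = create_graph("claim")
        g.add_child(g.root, kind, "child")
        assert g.edges[-1].kind is expected_edge

    def test_unknown_parent_raises(self):
        g = create_graph("claim")
        with pytest.raises(NodeNotFoundError):
            g.add_child("nope", NodeKind.GOAL, "child")

    def test_evidence_is_a_leaf(self, simple_graph):
        with pytest.raises(EdgeTypingError):
            simple_graph.add_child(simple_graph.uids["e"], NodeKind.GOAL, "below")

    def test_strategy_under_strategy_rejected(self, simple_graph):
        with pytest.raises(EdgeTypingError):
            simple_graph.add_child(
                simple_graph.uids["s"], NodeKind.STRATEGY, "nested reasoning"
            )

    def test_child_order_is_insertion_order(self):
        g = create_graph("claim")
        s = g.add_child(g.root, NodeKind.STRATEGY, "split")
        kids = [g.add_child(s, NodeKind.GOAL, f"sub {i}") for i in range(4)]
        assert g.children(s, EdgeKind.SUPPORTED_BY) == kids


class TestStatus:
    def test_leaf_goal_may_be_undeveloped(self, simple_graph):
        g = simple_graph
        leaf = g.add_child(g.uids["s"], NodeKind.GOAL, "no data yet")
        g.set_status(leaf, Status.UNDEVELOPED)
        assert g.nodes[leaf].status is Status.UNDEVELOPED
        assert validate(g) == []

    def test_undeveloped_rejected_on_strategy(self, simple_graph):
        with pytest.raises(EdgeTypingError):
            simple_graph.set_status(simple_graph.uids["s"], Status.UNDEVELOPED)

    def test_undeveloped_rejected_on_supported_goal(self, simple_graph):
        with pytest.raises(EdgeTypingError):
            simple_graph.set_status(simple_graph.root, Status.UNDEVELOPED)

    def test_undeveloped_goal_refuses_new_support(self):
        g = create_graph("claim")
        leaf = g.add_child(g.root, NodeKind.GOAL, "gap in knowledge")
        g.set_status(leaf, Status.UNDEVELOPED)
        with pytest.raises(EdgeTypingError):
            g.add_child(leaf, NodeKind.EVIDENCE, "surprise data")


class TestCollapse:
    def test_collapse_round_trip_preserves_graph(self, simple_graph):
        g = simple_graph
        before_nodes = {u: (n.kind, n.statement) for u, n in g.nodes.items()}
        g.collapse(g.uids["s"], True)
        assert g.nodes[g.uids["s"]].collapsed
        g.collapse(g.uids["s"], False)
        assert not g.nodes[g.uids["s"]].collapsed
        assert {u: (n.kind, n.statement) for u, n in g.nodes.items()} == before_nodes

    def test_collapsing_leaf_rejected(self, simple_graph):
        with pytest.raises(InvalidArgumentError):
            simple_graph.collapse(simple_graph.uids["e"], True)


class TestValidate:
    def test_constructed_graph_is_clean(self, simple_graph):
        assert validate(simple_graph) == []

    @pytest.mark.parametrize("code", sorted(RULE_MUTATIONS))
    def test_each_mutation_reports_exactly_its_code(self, code):
        g = RULE_MUTATIONS[code]()
        issues = validate(g)
        assert [i.code for i in issues] == [code]
        assert issues[0].severity == "error"
        assert issues[0].uids and issues[0].message

    def test_strategy_to_evidence_is_a_warning(self):
        g = create_graph("claim")
        s = g.add_child(g.root, NodeKind.STRATEGY, "argue directly")
        g.add_child(s, NodeKind.EVIDENCE, "statistics")
        issues = validate(g)
        assert [(i.code, i.severity) for i in issues] == [("BAD_EDGE_TYPING", "warning")]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_construction_api_closure(self, seed):
        """Anything grown through the construction API validates clean."""
        g = random_argument_graph(np.random.default_rng(seed))
        assert validate(g) == []


class TestLabels:
    def test_root_strategy_four_subclaims(self):
        g = create_graph("claim")
        s = g.add_child(g.root, NodeKind.STRATEGY, "split four ways")
        for i in range(4):
            g.add_child(s, NodeKind.GOAL, f"sub {i}")
        labels = set(assign_labels(g).values())
        assert {"1", "1.1", "1.1.1", "1.1.2", "1.1.3", "1.1.4"} == labels

    def test_single_root_label(self):
        g = create_graph("claim")
        assert list(assign_labels(g).values()) == ["1"]

    def test_context_family_suffixes(self, simple_graph):
        g = simple_graph
        g.add_child(g.root, NodeKind.ASSUMPTION, "an assumption")
        g.add_child(g.root, NodeKind.CONTEXT, "more scope")
        labels = assign_labels(g)
        root_ctx = sorted(
            labels[c] for c in g.children(g.root, EdgeKind.IN_CONTEXT_OF)
        )
        assert root_ctx == ["1-A1", "1-C1", "1-C2"]

    def test_idempotent_and_prefix_structured(self, case_study):
        first = assign_labels(case_study)
        second = assign_labels(case_study)
        assert first == second
        assert len(set(first.values())) == len(first)
        for e in case_study.edges:
            if e.kind is EdgeKind.SUPPORTED_BY:
                assert first[e.target].startswith(first[e.source] + ".")

    def test_malformed_graph_rejected(self):
        g = RULE_MUTATIONS["CYCLE"]()
        with pytest.raises(GraphValidationError):
            assign_labels(g)


class TestUndevelopedClaims:
    def test_sorted_by_label(self):
        g = create_graph("claim")
        s = g.add_child(g.root, NodeKind.STRATEGY, "split")
        uids = [g.add_child(s, NodeKind.GOAL, f"sub {i}") for i in range(3)]
        for u in (uids[2], uids[0]):
            g.set_status(u, Status.UNDEVELOPED)
        got = undeveloped_claims(g)
        assert got == [uids[0], uids[2]]

    def test_no_gaps_means_empty(self, simple_graph):
        assert undeveloped_claims(simple_graph) == []

    def test_single_undeveloped_root(self):
        g = create_graph("claim")
        g.set_status(g.root, Status.UNDEVELOPED)
        assert undeveloped_claims(g) == [g.root]


class TestMetrics:
    def test_root_only(self):
        m = metrics(create_graph("claim"))
        assert (m.n_terminal_goals, m.n_substantiated_terminal_goals) == (1, 0)
        assert m.coverage == 0.0

    def test_single_evidence_gives_full_coverage(self):
        g = create_graph("claim")
        g.add_child(g.root, NodeKind.EVIDENCE, "statistics")
        assert metrics(g).coverage == 1.0

    def test_kind_counts_partition_nodes(self, case_study):
        m = metrics(case_study)
        assert sum(m.n_by_kind.values()) == len(case_study.nodes)

    def test_coverage_monotone_under_new_evidence(self, simple_graph):
        g = simple_graph
        leaf = g.add_child(g.uids["s"], NodeKind.GOAL, "unsubstantiated")
        before = metrics(g).coverage
        g.add_child(leaf, NodeKind.EVIDENCE, "new statistics")
        assert metrics(g).coverage >= before


def test_public_api_is_importable():
    for name in gsnfit.__all__:
        assert getattr(gsnfit, name) is not None
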