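"""Random well-formed argument generators for property testing.

Used by the package's own test suite and the reproducibility script.
Graphs are grown exclusively through the construction API, so everything
returned is well-formed by construction.
"""

from __future__ import annotations

import numpy as np

from .core import ArgumentGraph, EdgeKind, NodeKind, Status, create_graph

__all__ = ["random_argument_graph"]

_STATEMENTS = [
    "the simulated cell behaviour is representative",
    "cell counts derive from flow cytometry data",
    "the abstraction of the chemokine pathway is appropriate",
    "environment dimensions match stereomicroscopy measurements",
    "aggregation formation is reproduced by hour 72",
    "velocity and displacement match ex vivo observation",
    "the argument over adhesion factors is complete",
    "published knockout experiments are replicated",
]


def random_argument_graph(
    rng: np.random.Generator,
    max_nodes: int = 20,
    p_undeveloped: float = 0.15,
    p_collapse: float = 0.1,
) -> ArgumentGraph:
    """Grow a random well-formed argument tree.

    Children are attached to uniformly chosen existing nodes whenever the
    pairing is legal (strategy→evidence, which validates with a warning, is
    never generated). Some childless goals are marked undeveloped and some
    supported nodes collapsed, mirroring real arguments.
    """
    n_nodes = int(rng.integers(1, max_nodes + 1))
    g = create_graph(str(rng.choice(_STATEMENTS)))
    uids = [g.root]
    child_kinds = {
        NodeKind.GOAL: [
            NodeKind.GOAL, NodeKind.STRATEGY, NodeKind.EVIDENCE,
            NodeKind.CONTEXT, NodeKind.ASSUMPTION, NodeKind.JUSTIFICATION,
        ],
        NodeKind.STRATEGY: [
            NodeKind.GOAL, NodeKind.CONTEXT, NodeKind.ASSUMPTION,
            NodeKind.JUSTIFICATION,
        ],
    }
    while len(uids) < n_nodes:
        parent = uids[int(rng.integers(0, len(uids)))]
        pk = g.nodes[parent].kind
        options = child_kinds.get(pk)
        if not options:
            continue
        kind = options[int(rng.integers(0, len(options)))]
        uid = g.add_child(parent, kind, str(rng.choice(_STATEMENTS)))
        uids.append(uid)

    for uid in uids:
        node = g.nodes[uid]
        if (
            node.kind is NodeKind.GOAL
            and not g.children(uid, EdgeKind.SUPPORTED_BY)
            and rng.random() < p_undeveloped
        ):
            g.set_status(uid, Status.UNDEVELOPED)
        elif g.children(uid, EdgeKind.SUPPORTED_BY) and rng.random() < p_collapse:
            g.collapse(uid, True)
    return g
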