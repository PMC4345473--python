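"""The lymphoid-tissue case-study argument.

A machine-readable fitness-for-purpose argument for an agent-based
simulation of Peyer's Patch development in pre-natal mice. Haematopoietic
LTin/LTi cells migrate into the developing gut from embryonic day 12.5–14.5
and aggregate around adhesion-factor-expressing stromal LTo cells over
72 hours; the simulator's purpose is to generate hypotheses about why cell
behaviour changes near a forming aggregation. The argument decomposes the
top-level adequacy claim over the underlying biological data, the
abstractions made, 12-hour cell behaviour and 72-hour aggregation
formation.

Statements marked in the document metadata as partly paraphrased summarize
figure-only content of the source argument; the claim, strategy and
undeveloped-claim structure follows the published description. The argument
ships both as a builder function and as a packaged JSON document
(``data/peyers_patch_argument.json``); the two are byte-identical.
"""

from __future__ import annotations

from importlib import resources
from typing import Callable

from .core import (
    ArgumentGraph,
    EdgeKind,
    NodeKind,
    Status,
    assign_labels,
    create_graph,
    validate,
)

__all__ = ["build_case_study", "case_study_facts", "packaged_case_study_text"]

# synthetic placeholder: the original analyses live behind publication
# paywalls and lab archives; real deployments would point at their DOIs
DOI_LINK = "https://example.org/lymphoid-simulator/evidence"

META = {
    "title": "Fitness-for-purpose argument: Peyer's Patch development simulator",
    "purpose": (
        "Record the case that an agent-based simulation of lymphoid tissue "
        "development is an adequate representation of the biology for the "
        "purpose of studying haematopoietic cell aggregation."
    ),
    "provenance": (
        "Claim/strategy structure follows the published description of the "
        "argument; statements not quoted in the running text are "
        "paraphrased, and evidence hyperlinks are synthetic placeholders."
    ),
}


def build_case_study() -> ArgumentGraph:
    """Construct the Peyer's Patch fitness-for-purpose argument."""
    g = create_graph("our model is an adequate representation of the biology")
    g.meta = dict(META)
    root = g.root

    g.add_child(
        root, NodeKind.CONTEXT,
        "Adequate representation: the simulation reproduces emergent cell "
        "behaviour that is statistically similar to that observed in ex vivo "
        "culture of the developing gut.",
    )
    g.add_child(
        root, NodeKind.CONTEXT,
        "Purpose of the simulation: to provide biologically relevant "
        "hypotheses as to why cell behaviour becomes statistically different "
        "in the vicinity of initial haematopoietic cell aggregations.",
    )

    s1 = g.add_child(
        root, NodeKind.STRATEGY,
        "Argue over the scientific context, the adequacy of our abstraction "
        "and adequacy of experimental results.",
    )

    # --- claim 1.1.1: adequacy of the underlying biological data ----------
    c111 = g.add_child(
        s1, NodeKind.GOAL,
        "The biological data upon which the simulation is based are "
        "available, adequate and accurate.",
    )
    s1111 = g.add_child(
        c111, NodeKind.STRATEGY,
        "Argue over the properties of haematopoietic (LTin/LTi) cells "
        "captured in the implementation.",
    )
    c11111 = g.add_child(
        s1111, NodeKind.GOAL,
        "LTin/LTi cell counts through the time course are derived "
        "appropriately from flow cytometry data.",
    )
    g.add_child(
        c11111, NodeKind.EVIDENCE,
        "Flow cytometry data converted into estimates of cell numbers through "
        "the time course of the simulation.",
        links=[DOI_LINK],
    )
    s1112 = g.add_child(
        c111, NodeKind.STRATEGY,
        "Argue over the properties of stromal (LTo) cells captured in the "
        "implementation.",
    )
    c11121 = g.add_child(
        s1112, NodeKind.GOAL,
        "LTo cell attributes (adhesion factor expression, location) reflect "
        "published experimental observation.",
    )
    g.add_child(
        c11121, NodeKind.EVIDENCE,
        "Data mined from the literature on LTo cell behaviour and adhesion "
        "factor expression.",
        links=[DOI_LINK],
    )
    s1113 = g.add_child(
        c111, NodeKind.STRATEGY,
        "Argue over the representation of the intestine environment.",
    )
    c11131 = g.add_child(
        s1113, NodeKind.GOAL,
        "The dimensions of the simulated gastrointestinal tract are "
        "representative of the developing gut.",
    )
    g.add_child(
        c11131, NodeKind.EVIDENCE,
        "Stereomicroscopy measurements of the developing gut used to set "
        "environment dimensions.",
        links=[DOI_LINK],
    )
    s1114 = g.add_child(
        c111, NodeKind.STRATEGY,
        "Argue over haematopoietic cell aggregation characteristics.",
    )
    c11141 = g.add_child(
        s1114, NodeKind.GOAL,
        "Aggregations of haematopoietic cells form in the simulation at the "
        "developmental stage observed in culture.",
    )
    g.add_child(
        c11141, NodeKind.EVIDENCE,
        "Aggregations observed in ex vivo culture imaging at the "
        "corresponding developmental hour.",
        links=[DOI_LINK],
    )
    c11142 = g.add_child(
        s1114, NodeKind.GOAL,
        "Simulated aggregations are quantitatively similar to aggregations "
        "of haematopoietic cells observed in vivo.",
    )
    # no quantitative biological data on aggregations existed at development
    # time: the claim is stated but cannot be substantiated
    g.set_status(c11142, Status.UNDEVELOPED)

    # --- claim 1.1.2: adequacy of abstractions ----------------------------
    c112 = g.add_child(
        s1, NodeKind.GOAL,
        "The abstractions made in the model of lymphoid tissue development "
        "are appropriate.",
    )
    c1121 = g.add_child(
        c112, NodeKind.GOAL,
        "A pathway consisting of one chemokine and one receptor is "
        "sufficient to capture the chemokine mechanism.",
    )
    g.add_child(
        c1121, NodeKind.EVIDENCE,
        "Inhibition of receptor CXCR5 causes a significant difference in the "
        "formation of cell aggregation, while inhibition of CCR7 does not.",
        links=[DOI_LINK],
    )
    c1122 = g.add_child(
        c112, NodeKind.GOAL,
        "Abstracting adhesion factor expression to the single most "
        "influential pathway is appropriate.",
    )
    g.add_child(
        c1122, NodeKind.EVIDENCE,
        "Experimental results showing one adhesion pathway has a more "
        "significant impact on cell aggregation than the others.",
        links=[DOI_LINK],
    )
    c1123 = g.add_child(
        c112, NodeKind.GOAL,
        "Representing the intestine environment as a continuous space with "
        "measured dimensions is appropriate.",
    )
    g.add_child(
        c1123, NodeKind.ASSUMPTION,
        "At this developmental stage the gut surface can be treated as flat; "
        "curvature does not materially affect cell contact dynamics.",
    )
    c1124 = g.add_child(
        c112, NodeKind.GOAL,
        "The abstraction of cell signalling into discrete state transitions "
        "is appropriate.",
    )
    g.add_child(
        c1124, NodeKind.JUSTIFICATION,
        "State transitions are specified in UML state diagrams traceable to "
        "the biological observations they encode.",
    )

    # --- claim 1.1.3: 12-hour cell behaviour ------------------------------
    c113 = g.add_child(
        s1, NodeKind.GOAL,
        "Simulated cell behaviour at the 12 h time-point is representative "
        "of that observed in the laboratory.",
    )
    s1131 = g.add_child(
        c113, NodeKind.STRATEGY,
        "Argue that simulated cell behaviour responses (velocity and "
        "displacement) are statistically similar to ex vivo observations, "
        "both close to and far from a forming aggregation.",
    )
    g.add_child(
        s1131, NodeKind.CONTEXT,
        "Statistical test: two-sided Mann-Whitney U test on per-track "
        "velocity and displacement.",
    )
    g.add_child(
        s1131, NodeKind.JUSTIFICATION,
        "A rank-based test is appropriate: behaviour responses are not "
        "normally distributed and sample sizes are modest.",
    )
    c11311 = g.add_child(
        s1131, NodeKind.GOAL,
        "Behaviour of cells close to (less than 50 um from) a forming "
        "aggregation is statistically similar in simulation and culture.",
    )
    g.add_child(
        c11311, NodeKind.EVIDENCE,
        "Mann-Whitney U test statistics reveal no statistical difference "
        "between simulated and ex vivo velocity and displacement for cells "
        "within 50 um of a forming aggregation.",
        links=[DOI_LINK],
    )
    c11312 = g.add_child(
        s1131, NodeKind.GOAL,
        "Behaviour of cells far from (more than 50 um from) a forming "
        "aggregation is statistically similar in simulation and culture.",
    )
    g.add_child(
        c11312, NodeKind.EVIDENCE,
        "Mann-Whitney U test statistics reveal no statistical difference "
        "between simulated and ex vivo velocity and displacement for cells "
        "more than 50 um from a forming aggregation.",
        links=[DOI_LINK],
    )

    # --- claim 1.1.4: 72-hour aggregation formation -----------------------
    c114 = g.add_child(
        s1, NodeKind.GOAL,
        "The simulator reproduces the formation of aggregations of "
        "haematopoietic cells by hour 72 of the process.",
    )
    s1141 = g.add_child(
        c114, NodeKind.STRATEGY,
        "Argue that a representative number of aggregations is formed in "
        "the intestine environment.",
    )
    g.add_child(
        s1141, NodeKind.GOAL,
        "The number of aggregations formed in silico is representative of "
        "Peyer's Patch counts observed in vivo.",
    )
    s1142 = g.add_child(
        c114, NodeKind.STRATEGY,
        "Argue that previously published experimental results examining "
        "aggregations under different physiological conditions are "
        "replicated.",
    )
    c11421 = g.add_child(
        s1142, NodeKind.GOAL,
        "The simulator reproduces laboratory gene knockout experiments "
        "affecting aggregation formation.",
    )
    g.add_child(
        c11421, NodeKind.EVIDENCE,
        "Published gene knockout experiments replicated in simulation.",
        links=[DOI_LINK],
    )
    s1143 = g.add_child(
        c114, NodeKind.STRATEGY,
        "Argue that the simulation captures appropriately the spatial "
        "characteristics of aggregations.",
    )
    c11431 = g.add_child(
        s1143, NodeKind.GOAL,
        "The spatial characteristics of simulated aggregations are "
        "appropriate.",
    )
    g.add_child(
        c11431, NodeKind.EVIDENCE,
        "Expert opinion of collaborating experimental biologists on "
        "aggregation morphology.",
    )

    assign_labels(g)
    return g


def packaged_case_study_text() -> str:
    """The shipped JSON document, byte-identical to save(build_case_study())."""
    return (
        resources.files("gsnfit").joinpath("data/peyers_patch_argument.json")
        .read_text(encoding="utf-8")
    )


def case_study_facts() -> list[tuple[str, Callable[[ArgumentGraph], bool]]]:
    """Executable structural assertions about the case-study argument.

    Each entry is (description, check); every check returns True on
    :func:`build_case_study`. They encode the argument's text-attested
    structure and drive the acceptance tests.
    """

    def by_label(g: ArgumentGraph, label: str):
        assign_labels(g)
        return g.node_by_label(label)

    def n_children(g: ArgumentGraph, label: str, kind: NodeKind) -> int:
        node = by_label(g, label)
        return sum(
            1 for c in g.children(node.uid, EdgeKind.SUPPORTED_BY)
            if g.nodes[c].kind is kind
        )

    return [
        (
            "the argument is well-formed (validate returns no issues)",
            lambda g: validate(g) == [],
        ),
        (
            "the top-level claim states the model adequately represents the biology",
            lambda g: "adequate representation of the biology"
            in g.nodes[g.root].statement,
        ),
        (
            "the top-level strategy leads to four sub-claims",
            lambda g: n_children(g, "1.1", NodeKind.GOAL) == 4,
        ),
        (
            "claims 1.1.1-1.1.4 exist and are goals",
            lambda g: all(
                by_label(g, lbl).kind is NodeKind.GOAL
                for lbl in ("1.1.1", "1.1.2", "1.1.3", "1.1.4")
            ),
        ),
        (
            "claim 1.1.1 (biological data adequacy) is argued over four strategies",
            lambda g: n_children(g, "1.1.1", NodeKind.STRATEGY) == 4,
        ),
        (
            "claim 1.1.2 (abstractions) is argued over four abstraction sub-claims",
            lambda g: n_children(g, "1.1.2", NodeKind.GOAL) == 4,
        ),
        (
            "claim 1.1.3 (12 h behaviour) is supported through strategy 1.1.3.1",
            lambda g: by_label(g, "1.1.3.1").kind is NodeKind.STRATEGY,
        ),
        (
            "strategy 1.1.3.1 leads to near and far behaviour claims",
            lambda g: n_children(g, "1.1.3.1", NodeKind.GOAL) == 2,
        ),
        (
            "both behaviour claims carry Mann-Whitney evidence with a hyperlink",
            lambda g: all(
                any(
                    g.nodes[c].kind is NodeKind.EVIDENCE
                    and "Mann-Whitney" in g.nodes[c].statement
                    and g.nodes[c].links
                    for c in g.children(by_label(g, lbl).uid, EdgeKind.SUPPORTED_BY)
                )
                for lbl in ("1.1.3.1.1", "1.1.3.1.2")
            ),
        ),
        (
            "claim 1.1.4 (aggregation formation) is argued over three strategies",
            lambda g: n_children(g, "1.1.4", NodeKind.STRATEGY) == 3,
        ),
        (
            "claim 1.1.1.4.2 is the argument's one undeveloped claim",
            lambda g: (
                by_label(g, "1.1.1.4.2").status is Status.UNDEVELOPED
                and sum(
                    1 for n in g.nodes.values()
                    if n.status is Status.UNDEVELOPED
                ) == 1
            ),
        ),
        (
            "the root claim carries context stating the simulation's purpose",
            lambda g: any(
                g.nodes[c].kind is NodeKind.CONTEXT
                and "purpose" in g.nodes[c].statement.lower()
                for c in g.children(g.root, EdgeKind.IN_CONTEXT_OF)
            ),
        ),
    ]
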