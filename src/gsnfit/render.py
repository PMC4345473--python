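"""Deterministic layered tree layout and SVG/PNG rendering.

The drawing conventions follow goal structuring notation: goals are
rectangles, strategies parallelograms, context rounded rectangles,
assumptions/justifications ellipses tagged "A"/"J", evidence circles.
Support edges end in a solid (filled) arrowhead, context edges in a white
(open) one. An undeveloped goal carries a small open diamond below its box;
a collapsed node (whose subtree is hidden) a filled one.

Layout is a bottom-up subtree-width scheme in the Reingold–Tilford family,
simplified because the structure is a strict tree: each node's slot is the
wider of its own cluster (the node box plus its context-family attachments,
drawn to its right in the same vertical band) and the sum of its children's
slots, and every cluster is centred in its slot. Support depth defines the
layer; y grows downward. The result is overlap-free with every parent
strictly above its supported children.
"""

from __future__ import annotations

import io as _io
import math
import textwrap
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from PIL import Image, ImageDraw

from .core import (
    ArgumentGraph,
    EdgeKind,
    NodeKind,
    Status,
    validate,
)
from .errors import GraphValidationError, InvalidArgumentError

__all__ = ["LayoutBox", "Layout", "layout", "render_svg", "render_png"]

# canvas units are abstract; with the default font they read as pixels
CHAR_W = 6.6
LINE_H = 14.0
PAD = 8.0
WRAP_COLS = 26
MIN_W, MIN_H = 70.0, 40.0
H_GAP = 28.0       # between sibling subtrees
CTX_GAP = 18.0     # between a node and its context attachments
V_GAP = 46.0       # between layers
MARGIN = 20.0
DIAMOND = 9.0      # half-diagonal of the status/collapse markers


@dataclass
class LayoutBox:
    uid: str
    x: float
    y: float
    width: float
    height: float


@dataclass
class Layout:
    boxes: dict[str, LayoutBox] = field(default_factory=dict)
    width: float = 0.0
    height: float = 0.0


def _wrap(node) -> list[str]:
    lines = textwrap.wrap(node.statement, WRAP_COLS) or [""]
    if node.label:
        lines = [node.label] + lines
    return lines


def _box_size(node) -> tuple[float, float]:
    lines = _wrap(node)
    w = max(MIN_W, 2 * PAD + CHAR_W * max(len(s) for s in lines))
    h = max(MIN_H, 2 * PAD + LINE_H * len(lines))
    if node.kind is NodeKind.STRATEGY:
        w += 16  # skew allowance for the parallelogram
    if node.kind is NodeKind.EVIDENCE:
        # circles need a square envelope wide enough for the text diagonal
        d = max(w, h, math.hypot(w, h) * 0.82)
        w = h = d
    return w, h


def _require_well_formed(graph: ArgumentGraph) -> None:
    errors = [i for i in validate(graph) if i.severity == "error"]
    if errors:
        raise GraphValidationError(errors)


def visible_nodes(graph: ArgumentGraph) -> set[str]:
    """Uids drawn after honouring collapsed flags (subtrees hidden)."""
    out: set[str] = set()

    def walk(uid: str) -> None:
        out.add(uid)
        if graph.nodes[uid].collapsed:
            return
        for c in graph.children(uid):
            walk(c)

    walk(graph.root)
    return out


def layout(graph: ArgumentGraph) -> Layout:
    """Compute non-overlapping box positions for every visible node."""
    _require_well_formed(graph)

    sizes = {u: _box_size(graph.nodes[u]) for u in graph.nodes}

    def ctx_children(uid: str) -> list[str]:
        if graph.nodes[uid].collapsed:
            return []
        return graph.children(uid, EdgeKind.IN_CONTEXT_OF)

    def sup_children(uid: str) -> list[str]:
        if graph.nodes[uid].collapsed:
            return []
        return graph.children(uid, EdgeKind.SUPPORTED_BY)

    def cluster_width(uid: str) -> float:
        w = sizes[uid][0]
        for c in ctx_children(uid):
            w += CTX_GAP + sizes[c][0]
        return w

    slot: dict[str, float] = {}

    def measure(uid: str) -> float:
        kids = sup_children(uid)
        kids_w = sum(measure(c) for c in kids) + H_GAP * max(0, len(kids) - 1)
        slot[uid] = max(cluster_width(uid), kids_w)
        return slot[uid]

    measure(graph.root)

    # depth → band height (clusters share the band of their anchor)
    depth: dict[str, int] = {}

    def set_depth(uid: str, d: int) -> None:
        depth[uid] = d
        for c in ctx_children(uid):
            depth[c] = d
        for c in sup_children(uid):
            set_depth(c, d + 1)

    set_depth(graph.root, 0)
    n_bands = max(depth.values()) + 1
    band_h = [0.0] * n_bands
    for uid, d in depth.items():
        band_h[d] = max(band_h[d], sizes[uid][1])
    band_y = [MARGIN] * n_bands
    for d in range(1, n_bands):
        band_y[d] = band_y[d - 1] + band_h[d - 1] + V_GAP

    boxes: dict[str, LayoutBox] = {}

    def place(uid: str, x0: float) -> None:
        d = depth[uid]
        cw = cluster_width(uid)
        cx = x0 + (slot[uid] - cw) / 2
        w, h = sizes[uid]
        boxes[uid] = LayoutBox(uid, cx, band_y[d], w, h)
        run = cx + w
        for c in ctx_children(uid):
            cwc, chc = sizes[c]
            boxes[c] = LayoutBox(c, run + CTX_GAP, band_y[d], cwc, chc)
            run += CTX_GAP + cwc
        child_x = x0
        for c in sup_children(uid):
            place(c, child_x)
            child_x += slot[c] + H_GAP

    place(graph.root, MARGIN)

    width = max(b.x + b.width for b in boxes.values()) + MARGIN
    height = max(b.y + b.height for b in boxes.values()) + MARGIN + DIAMOND * 2
    return Layout(boxes=boxes, width=width, height=height)


# -- SVG ---------------------------------------------------------------------

_FONT = 'font-family="Helvetica,Arial,sans-serif" font-size="11"'


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _pts(points: list[tuple[float, float]]) -> str:
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)


def _shape_element(node, b: LayoutBox) -> ET.Element:
    k = node.kind
    if k is NodeKind.GOAL:
        return ET.Element("rect", x=_fmt(b.x), y=_fmt(b.y),
                          width=_fmt(b.width), height=_fmt(b.height))
    if k is NodeKind.CONTEXT:
        return ET.Element("rect", x=_fmt(b.x), y=_fmt(b.y),
                          width=_fmt(b.width), height=_fmt(b.height),
                          rx=_fmt(min(14.0, b.height / 2)))
    if k is NodeKind.STRATEGY:
        s = 14.0
        return ET.Element("polygon", points=_pts([
            (b.x + s, b.y), (b.x + b.width, b.y),
            (b.x + b.width - s, b.y + b.height), (b.x, b.y + b.height),
        ]))
    if k in (NodeKind.ASSUMPTION, NodeKind.JUSTIFICATION):
        return ET.Element("ellipse", cx=_fmt(b.x + b.width / 2),
                          cy=_fmt(b.y + b.height / 2),
                          rx=_fmt(b.width / 2), ry=_fmt(b.height / 2))
    # evidence: the notation's circle
    r = max(b.width, b.height) / 2
    return ET.Element("circle", cx=_fmt(b.x + b.width / 2),
                      cy=_fmt(b.y + b.height / 2), r=_fmt(r))


def _diamond(cx: float, cy: float, filled: bool) -> ET.Element:
    e = ET.Element("polygon", points=_pts([
        (cx, cy - DIAMOND), (cx + DIAMOND, cy), (cx, cy + DIAMOND), (cx - DIAMOND, cy),
    ]))
    e.set("class", "marker-collapsed" if filled else "marker-undeveloped")
    e.set("fill", "#000" if filled else "#fff")
    e.set("stroke", "#000")
    return e


def render_svg(graph: ArgumentGraph, layout_: Layout) -> str:
    """Render the laid-out graph as standalone SVG text.

    A pure function of its inputs: equal (graph, layout) pairs give
    byte-identical output.
    """
    visible = visible_nodes(graph)
    missing = visible - set(layout_.boxes)
    if missing:
        raise InvalidArgumentError(
            f"layout lacks boxes for visible nodes: {sorted(missing)}"
        )

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=_fmt(layout_.width),
        height=_fmt(layout_.height),
        viewBox=f"0 0 {_fmt(layout_.width)} {_fmt(layout_.height)}",
    )
    defs = ET.SubElement(svg, "defs")
    for mid, fill in (("arrow-solid", "#000"), ("arrow-open", "#fff")):
        marker = ET.SubElement(
            defs, "marker", id=mid, markerWidth="10", markerHeight="8",
            refX="9", refY="4", orient="auto", markerUnits="userSpaceOnUse",
        )
        path = ET.SubElement(marker, "polygon", points="0,0 10,4 0,8")
        path.set("fill", fill)
        path.set("stroke", "#000")

    boxes = layout_.boxes
    # edges under nodes; canonical order for byte stability
    for e in sorted(graph.edges, key=lambda e: (e.source, e.target, e.kind.value)):
        if e.source not in visible or e.target not in visible:
            continue
        s, t = boxes[e.source], boxes[e.target]
        if e.kind is EdgeKind.SUPPORTED_BY:
            x1, y1 = s.x + s.width / 2, s.y + s.height
            x2, y2 = t.x + t.width / 2, t.y
            marker_id = "arrow-solid"
        else:
            x1, y1 = s.x + s.width, s.y + s.height / 2
            x2, y2 = t.x, t.y + t.height / 2
            marker_id = "arrow-open"
        line = ET.SubElement(svg, "line", x1=_fmt(x1), y1=_fmt(y1),
                             x2=_fmt(x2), y2=_fmt(y2))
        line.set("stroke", "#000")
        line.set("marker-end", f"url(#{marker_id})")

    for uid in sorted(visible):
        node = graph.nodes[uid]
        b = boxes[uid]
        group = ET.Element("g", id=f"node-{uid}")
        shape = _shape_element(node, b)
        if shape.get("fill") is None:
            shape.set("fill", "#fff")
        shape.set("stroke", "#000")
        group.append(shape)

        lines = _wrap(node)
        y0 = b.y + (b.height - LINE_H * len(lines)) / 2 + LINE_H - 3
        text = ET.SubElement(group, "text", x=_fmt(b.x + b.width / 2), y=_fmt(y0))
        text.set("text-anchor", "middle")
        text.set("font-family", "Helvetica,Arial,sans-serif")
        text.set("font-size", "11")
        for i, linetext in enumerate(lines):
            tspan = ET.SubElement(text, "tspan", x=_fmt(b.x + b.width / 2),
                                  dy="0" if i == 0 else _fmt(LINE_H))
            if i == 0 and node.label:
                tspan.set("font-weight", "bold")
            tspan.text = linetext

        if node.kind in (NodeKind.ASSUMPTION, NodeKind.JUSTIFICATION):
            tag = ET.SubElement(group, "text", x=_fmt(b.x + b.width - 6),
                                y=_fmt(b.y + b.height - 4))
            tag.set("font-family", "Helvetica,Arial,sans-serif")
            tag.set("font-size", "10")
            tag.text = "A" if node.kind is NodeKind.ASSUMPTION else "J"

        cx = b.x + b.width / 2
        if node.collapsed:
            group.append(_diamond(cx, b.y + b.height + DIAMOND + 2, filled=True))
        elif node.kind is NodeKind.GOAL and node.status is Status.UNDEVELOPED:
            group.append(_diamond(cx, b.y + b.height + DIAMOND + 2, filled=False))

        if node.kind is NodeKind.EVIDENCE and node.links:
            anchor = ET.Element("a", href=node.links[0])
            anchor.append(group)
            svg.append(anchor)
        else:
            svg.append(group)

    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


# -- PNG ---------------------------------------------------------------------


def render_png(graph: ArgumentGraph, layout_: Layout, scale: float = 1.0) -> bytes:
    """Rasterize the diagram to PNG bytes at the requested scale.

    Image dimensions are ``ceil(canvas × scale)``. Deterministic for equal
    inputs on one platform.
    """
    if not scale or scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    visible = visible_nodes(graph)
    missing = visible - set(layout_.boxes)
    if missing:
        raise InvalidArgumentError(
            f"layout lacks boxes for visible nodes: {sorted(missing)}"
        )

    w = math.ceil(layout_.width * scale)
    h = math.ceil(layout_.height * scale)
    img = Image.new("RGB", (w, h), "white")
    draw = ImageDraw.Draw(img)
    s = scale

    def arrow(x1, y1, x2, y2, filled: bool) -> None:
        draw.line([(x1 * s, y1 * s), (x2 * s, y2 * s)], fill="black")
        ang = math.atan2(y2 - y1, x2 - x1)
        ln, half = 10 * s, 4 * s
        tip = (x2 * s, y2 * s)
        left = (tip[0] - ln * math.cos(ang) - half * math.sin(ang),
                tip[1] - ln * math.sin(ang) + half * math.cos(ang))
        right = (tip[0] - ln * math.cos(ang) + half * math.sin(ang),
                 tip[1] - ln * math.sin(ang) - half * math.cos(ang))
        draw.polygon([tip, left, right],
                     fill="black" if filled else "white", outline="black")

    for e in sorted(graph.edges, key=lambda e: (e.source, e.target, e.kind.value)):
        if e.source not in visible or e.target not in visible:
            continue
        a, b = layout_.boxes[e.source], layout_.boxes[e.target]
        if e.kind is EdgeKind.SUPPORTED_BY:
            arrow(a.x + a.width / 2, a.y + a.height, b.x + b.width / 2, b.y, True)
        else:
            arrow(a.x + a.width, a.y + a.height / 2, b.x, b.y + b.height / 2, False)

    for uid in sorted(visible):
        node = graph.nodes[uid]
        b = layout_.boxes[uid]
        x0, y0, x1, y1 = b.x * s, b.y * s, (b.x + b.width) * s, (b.y + b.height) * s
        k = node.kind
        if k is NodeKind.GOAL:
            draw.rectangle([x0, y0, x1, y1], fill="white", outline="black")
        elif k is NodeKind.CONTEXT:
            draw.rounded_rectangle([x0, y0, x1, y1], radius=10 * s,
                                   fill="white", outline="black")
        elif k is NodeKind.STRATEGY:
            sk = 14 * s
            draw.polygon([(x0 + sk, y0), (x1, y0), (x1 - sk, y1), (x0, y1)],
                         fill="white", outline="black")
        elif k in (NodeKind.ASSUMPTION, NodeKind.JUSTIFICATION):
            draw.ellipse([x0, y0, x1, y1], fill="white", outline="black")
            draw.text((x1 - 10 * s, y1 - 12 * s),
                      "A" if k is NodeKind.ASSUMPTION else "J", fill="black")
        else:
            draw.ellipse([x0, y0, x1, y1], fill="white", outline="black")

        for i, linetext in enumerate(_wrap(node)):
            tw = draw.textlength(linetext)
            draw.text(((x0 + x1) / 2 - tw / 2, y0 + 4 * s + i * LINE_H * s),
                      linetext, fill="black")

        cx, cy = (x0 + x1) / 2, y1 + (DIAMOND + 2) * s
        d = DIAMOND * s
        if node.collapsed:
            draw.polygon([(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)],
                         fill="black", outline="black")
        elif k is NodeKind.GOAL and node.status is Status.UNDEVELOPED:
            draw.polygon([(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)],
                         fill="white", outline="black")

    buf = _io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
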