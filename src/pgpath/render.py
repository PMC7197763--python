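"""SVG rendering, background merging and HTML info windows.

The symbol standard: drugs and metabolites share one shape (a pill-shaped
rounded rectangle) and are told apart by fill color — prodrug amber vs.
active drug blue, inactive metabolite grey vs. active metabolite blue.
Gene roles differ in both shape and color: enzymes are green rounded
rectangles, transporters purple ellipses, carriers teal ellipses, targets
red rectangles.  'major' (significant metabolizing enzyme) and 'active'
(therapeutic metabolite) markers are rendered as small badge glyphs next to
their node.  All colors are theme-overridable.

When a GVB table is supplied, gene fills are overridden by the burden
gradient (:func:`pgpath.personalize.gvb_to_color`).

A built-in schematic vector frame (the compartment boxes of the standard
body plan) is always drawn beneath the nodes, so diagrams are complete
without raster artwork; a PNG background can additionally be embedded
beneath everything for visual fidelity.
"""

from __future__ import annotations

import base64
import html as _html
import io
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree
from PIL import Image, UnidentifiedImageError

from .errors import ImageDecodeError, ScoreRangeError, TypeMismatchError, ValidationError
from .gpml import COMPARTMENT_SIZE, NODE_SIZES, arrowhead_for
from .model import (
    DrugNode,
    GeneNode,
    MetaboliteNode,
    PathwayDocument,
    node_id,
    validate_pathway,
)
from .personalize import ColorScale, gvb_to_color
from .vocab import DrugKind, GeneRole

SVG_NS = "http://www.w3.org/2000/svg"
S = "{%s}" % SVG_NS

HGNC_URL = "https://www.genenames.org/data/gene-symbol-report/#!/symbol/{}"
HMDB_URL = "https://hmdb.ca/metabolites/{}"


@dataclass
class Theme:
    """Symbol/color standard; every value can be overridden via config."""

    prodrug: str = "#F0A830"
    active_drug: str = "#2B6CB0"
    inactive_metabolite: str = "#B0B0B0"
    active_metabolite: str = "#2B6CB0"
    enzyme: str = "#3C8C4A"
    transporter: str = "#7B4FA6"
    carrier: str = "#2AA198"
    target: str = "#C0392B"
    compartment_fill: str = "#F6F2EA"
    compartment_border: str = "#8A8070"
    edge_color: str = "#444444"
    text_color: str = "#111111"
    scale: ColorScale = field(default_factory=ColorScale)


@dataclass
class RenderedDiagram:
    """An SVG diagram plus the hooks needed to assemble the final HTML."""

    svg_text: str
    node_anchor_index: dict  # node id -> SVG element id
    info_windows: dict = field(default_factory=dict)  # element id -> HTML fragment
    description: Optional[str] = None
    has_background: bool = False


def _fmt(x: float) -> str:
    return f"{float(x):.6f}"


def element_id(node) -> str:
    """Stable SVG element id: gene:<HGNC> / drug:<HMDB> / met:<id>."""
    if isinstance(node, GeneNode):
        return f"gene:{node.symbol}"
    if isinstance(node, DrugNode):
        return f"drug:{node.id}"
    return f"met:{node.id}"


def _node_fill(node, theme: Theme) -> str:
    if isinstance(node, DrugNode):
        return theme.prodrug if node.drug_kind is DrugKind.PRODRUG else theme.active_drug
    if isinstance(node, MetaboliteNode):
        return theme.active_metabolite if node.active else theme.inactive_metabolite
    return {
        GeneRole.ENZYME: theme.enzyme,
        GeneRole.TRANSPORTER: theme.transporter,
        GeneRole.CARRIER: theme.carrier,
        GeneRole.TARGET: theme.target,
    }[node.role]


def _add_marker_defs(svg, theme: Theme):
    defs = etree.SubElement(svg, S + "defs")
    arrow = etree.SubElement(
        defs, S + "marker", id="arrow", markerWidth="10", markerHeight="8",
        refX="9", refY="4", orient="auto",
    )
    etree.SubElement(arrow, S + "path", d="M0,0 L9,4 L0,8 z", fill=theme.edge_color)
    open_arrow = etree.SubElement(
        defs, S + "marker", id="open-arrow", markerWidth="10", markerHeight="8",
        refX="9", refY="4", orient="auto",
    )
    etree.SubElement(
        open_arrow, S + "path", d="M0,0 L9,4 L0,8", fill="none",
        stroke=theme.edge_color, **{"stroke-width": "1.4"},
    )
    tee = etree.SubElement(
        defs, S + "marker", id="tee", markerWidth="8", markerHeight="10",
        refX="4", refY="5", orient="auto",
    )
    etree.SubElement(
        tee, S + "line", x1="4", y1="0", x2="4", y2="10",
        stroke=theme.edge_color, **{"stroke-width": "2"},
    )
    ball = etree.SubElement(
        defs, S + "marker", id="ball", markerWidth="8", markerHeight="8",
        refX="4", refY="4", orient="auto",
    )
    etree.SubElement(ball, S + "circle", cx="4", cy="4", r="3", fill=theme.edge_color)


_MARKER_BY_ARROWHEAD = {
    "mim-conversion": "arrow",
    "mim-translocation": "open-arrow",
    "mim-binding": "ball",
    "mim-inhibition": "tee",
    "mim-stimulation": "open-arrow",
    "Arrow": "arrow",
}


def _badge(group, x, y, letter, color, eid):
    etree.SubElement(
        group, S + "circle", cx=_fmt(x), cy=_fmt(y), r="7",
        fill=color, stroke="#333333", **{"stroke-width": "0.8"}, id=eid,
    )
    t = etree.SubElement(
        group, S + "text", x=_fmt(x), y=_fmt(y + 3.2),
        **{"text-anchor": "middle", "font-size": "9", "font-family": "sans-serif", "fill": "#FFFFFF"},
    )
    t.text = letter


def render_svg(
    doc: PathwayDocument,
    background: Optional[bytes] = None,
    gvb=None,
    theme: Optional[Theme] = None,
) -> RenderedDiagram:
    """Render a validated pathway document to SVG.

    One addressable shape element per node, positioned at the document
    layout.  ``background`` optionally embeds PNG bytes beneath all layers;
    ``gvb`` recolors gene nodes along the burden gradient.
    """
    theme = theme or Theme()
    violations = validate_pathway(doc)
    if violations:
        raise ValidationError(violations)
    gene_colors = {}
    if gvb is not None:
        for gene in doc.gene_nodes():
            score = gvb.score(gene.symbol)
            if not 0.0 < score <= 1.0:
                raise ScoreRangeError(f"GVB score {score} for {gene.symbol} outside (0, 1]")
            gene_colors[gene.symbol] = gvb_to_color(score, theme.scale)

    width = max((xy[0] for xy in doc.layout.values()), default=0.0) + 160.0
    height = max((xy[1] for xy in doc.layout.values()), default=0.0) + 160.0
    svg = etree.Element(
        S + "svg", nsmap={None: SVG_NS},
        width=_fmt(width), height=_fmt(height),
        viewBox=f"0 0 {_fmt(width)} {_fmt(height)}",
    )
    _add_marker_defs(svg, theme)

    if background is not None:
        _decode_png(background)
        etree.SubElement(
            svg, S + "image", x="0", y="0", width=_fmt(width), height=_fmt(height),
            href="data:image/png;base64," + base64.b64encode(background).decode("ascii"),
            preserveAspectRatio="none", id="background",
        )

    # built-in vector frame: one labelled box per compartment
    frame = etree.SubElement(svg, S + "g", id="frame")
    cw, ch = COMPARTMENT_SIZE
    for c in doc.compartments:
        x, y = doc.layout[c.id]
        etree.SubElement(
            frame, S + "rect", x=_fmt(x - cw / 2), y=_fmt(y - ch / 2),
            width=_fmt(cw), height=_fmt(ch), rx="10",
            fill=theme.compartment_fill, stroke=theme.compartment_border,
            **{"stroke-width": "1.2", "fill-opacity": "0.7"}, id=f"compartment:{c.id}",
        )
        label = etree.SubElement(
            frame, S + "text", x=_fmt(x - cw / 2 + 6), y=_fmt(y - ch / 2 + 14),
            **{"font-size": "11", "font-family": "sans-serif", "fill": theme.compartment_border},
        )
        label.text = c.name

    edges_g = etree.SubElement(svg, S + "g", id="edges")
    for e in doc.edges:
        if e.source not in doc.layout or e.target not in doc.layout:
            continue
        sx, sy = doc.layout[e.source]
        tx, ty = doc.layout[e.target]
        marker = _MARKER_BY_ARROWHEAD.get(arrowhead_for(e), "arrow")
        etree.SubElement(
            edges_g, S + "line", x1=_fmt(sx), y1=_fmt(sy), x2=_fmt(tx), y2=_fmt(ty),
            stroke=theme.edge_color,
            **{"stroke-width": "1.4", "marker-end": f"url(#{marker})"},
        )

    anchor_index = {}
    info_windows = {}
    nodes_g = etree.SubElement(svg, S + "g", id="nodes")
    for n in doc.nodes:
        nid = node_id(n)
        eid = element_id(n)
        anchor_index[nid] = eid
        x, y = doc.layout[nid]
        if isinstance(n, GeneNode):
            w, h = NODE_SIZES["gene"]
            fill = gene_colors.get(n.symbol, _node_fill(n, theme))
            common = dict(fill=fill, stroke="#222222", id=eid)
            common["stroke-width"] = "1"
            common["class"] = f"node gene role-{n.role.value}"
            if n.role in (GeneRole.TRANSPORTER, GeneRole.CARRIER):
                etree.SubElement(
                    nodes_g, S + "ellipse", cx=_fmt(x), cy=_fmt(y),
                    rx=_fmt(w / 2), ry=_fmt(h / 2), **common,
                )
            else:
                rx = "8" if n.role is GeneRole.ENZYME else "0"
                etree.SubElement(
                    nodes_g, S + "rect", x=_fmt(x - w / 2), y=_fmt(y - h / 2),
                    width=_fmt(w), height=_fmt(h), rx=rx, **common,
                )
            if n.major:
                _badge(nodes_g, x + w / 2 + 9, y - h / 2, "M", "#8B0000", f"{eid}:major")
            label_text = n.symbol
            info_windows[eid] = make_info_window(n)
        else:
            w, h = NODE_SIZES["drug" if isinstance(n, DrugNode) else "metabolite"]
            cls = "node drug" if isinstance(n, DrugNode) else "node metabolite"
            etree.SubElement(
                nodes_g, S + "rect", x=_fmt(x - w / 2), y=_fmt(y - h / 2),
                width=_fmt(w), height=_fmt(h), rx=_fmt(h / 2),
                fill=_node_fill(n, theme), stroke="#222222",
                **{"stroke-width": "1", "class": cls}, id=eid,
            )
            if isinstance(n, MetaboliteNode) and n.active:
                _badge(nodes_g, x + w / 2 + 9, y - h / 2, "A", "#1F4E8C", f"{eid}:active")
            label_text = n.name
            if isinstance(n, DrugNode):
                info_windows[eid] = make_info_window(n)
        t = etree.SubElement(
            nodes_g, S + "text", x=_fmt(x), y=_fmt(y + 3.5),
            **{
                "text-anchor": "middle",
                "font-size": "10",
                "font-family": "sans-serif",
                "fill": theme.text_color,
                "pointer-events": "none",
            },
        )
        t.text = label_text

    svg_text = etree.tostring(svg, pretty_print=True).decode("utf-8")
    return RenderedDiagram(
        svg_text=svg_text,
        node_anchor_index=anchor_index,
        info_windows=info_windows,
        description=doc.description,
        has_background=background is not None,
    )


def _decode_png(png_bytes: bytes) -> None:
    try:
        with Image.open(io.BytesIO(png_bytes)) as img:
            img.verify()
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError) as exc:
        raise ImageDecodeError(f"background bytes are not a decodable image: {exc}") from exc


def _field_rows(pairs) -> str:
    rows = []
    for label, value in pairs:
        value = value if value not in (None, "") else "—"
        rows.append(
            f"<tr><th>{_html.escape(label)}</th><td>{_html.escape(str(value))}</td></tr>"
        )
    return "".join(rows)


def make_info_window(node, extra=None) -> str:
    """HTML pop-up fragment for a drug or gene node.

    Drug windows list the clinical fields (name, ATC class, indications,
    adverse effects, interactions, PK notes) and link to the HMDB record;
    gene windows list symbol, gene name, interaction/action context,
    chromosomal location and expression tissue (from ``extra``) and link to
    the HGNC symbol report.  Metabolites have no window.
    """
    extra = extra or {}
    if isinstance(node, MetaboliteNode):
        raise TypeMismatchError("metabolite nodes have no information window")
    if isinstance(node, DrugNode):
        info = node.clinical_info
        rows = _field_rows(
            [
                ("Drug name", node.name),
                ("ATC class", info.atc_class if info else ""),
                ("Indications", info.indications if info else ""),
                ("Adverse drug effects", info.adverse_effects if info else ""),
                ("Drug interactions", info.interactions if info else ""),
                ("Pharmacokinetics", info.pk_notes if info else ""),
            ]
        )
        url = HMDB_URL.format(node.id)
        title = _html.escape(node.name)
    elif isinstance(node, GeneNode):
        rows = _field_rows(
            [
                ("Gene symbol", node.symbol),
                ("Gene name", node.gene_name),
                ("Interaction type", extra.get("interaction_type", "")),
                ("Chromosomal location", extra.get("chromosomal_location", "")),
                ("Expression tissue", extra.get("expression_tissue", "")),
                ("Action type", extra.get("action_type", "")),
                ("Description", node.description),
            ]
        )
        url = HGNC_URL.format(node.symbol)
        title = _html.escape(node.symbol)
    else:
        raise TypeMismatchError(f"no information window for node type {type(node).__name__}")
    return (
        f'<div class="info-window"><h3>{title}</h3><table>{rows}</table>'
        f'<p><a href="{url}" target="_blank" rel="noopener">External record</a></p></div>'
    )


_POPUP_SCRIPT = """
document.querySelectorAll('[data-window]').forEach(function (el) {
  el.addEventListener('click', function () {
    document.querySelectorAll('.popup').forEach(function (w) { w.style.display = 'none'; });
    var w = document.getElementById(el.getAttribute('data-window'));
    if (w) { w.style.display = 'block'; }
  });
});
document.querySelectorAll('.popup .close').forEach(function (btn) {
  btn.addEventListener('click', function () { btn.parentElement.style.display = 'none'; });
});
"""


def _to_html(diagram: RenderedDiagram, png_bytes: Optional[bytes] = None) -> str:
    """Assemble the self-contained SVG + HTML page."""
    layers = []
    if png_bytes is not None:
        b64 = base64.b64encode(png_bytes).decode("ascii")
        layers.append(
            f'<img class="background" src="data:image/png;base64,{b64}" alt="background frame"/>'
        )
    svg_text = diagram.svg_text
    # attach the pop-up hooks onto the node anchors
    for nid, eid in sorted(diagram.node_anchor_index.items()):
        if eid in diagram.info_windows:
            svg_text = svg_text.replace(f'id="{eid}"', f'id="{eid}" data-window="win:{eid}"', 1)
    layers.append(f'<div class="overlay">{svg_text}</div>')

    popups = []
    for eid in sorted(diagram.info_windows):
        popups.append(
            f'<div class="popup" id="win:{eid}" style="display:none">'
            f'<button class="close">close</button>{diagram.info_windows[eid]}</div>'
        )
    if diagram.description:
        popups.append(
            '<div class="popup description-window" id="win:description">'
            f"<h3>Pathway description</h3><p>{_html.escape(diagram.description)}</p></div>"
        )

    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
        "<style>"
        ".stage{position:relative}"
        ".stage img.background{position:absolute;left:0;top:0;z-index:0}"
        ".stage .overlay{position:relative;z-index:1}"
        ".popup{position:fixed;right:16px;top:16px;z-index:2;background:#fff;"
        "border:1px solid #888;padding:8px;max-width:360px;font-family:sans-serif}"
        ".popup table th{text-align:left;padding-right:8px;vertical-align:top}"
        "</style></head><body>"
        f'<div class="stage">{"".join(layers)}</div>'
        f'{"".join(popups)}'
        f"<script>{_POPUP_SCRIPT}</script>"
        "</body></html>\n"
    )


def merge_with_background(diagram: RenderedDiagram, png_bytes: bytes) -> str:
    """Merge a rendered diagram with a PNG background into one HTML document.

    The PNG is base64-embedded as the bottom layer, the SVG overlaid on top,
    and info-window script hooks attached to the node anchors.  The PD
    description window is included when the diagram carries a description.
    """
    _decode_png(png_bytes)
    return _to_html(diagram, png_bytes)
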