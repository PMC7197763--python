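"""GPML (Graphical Pathway Markup Language) serialization.

Documents are written in the 2013a dialect.  Each pathway node becomes a
``DataNode`` carrying exactly one external cross-reference (HGNC symbol for
genes, HMDB-style accession for drugs and metabolites), each edge becomes an
``Interaction`` whose arrowhead class encodes its interaction/action type in
MIM style, and each compartment becomes a labelled ``Shape``.  Schema fields
that GPML has no native slot for (drug kind, 'major'/'active' markers, gene
role, compartment level, ...) are stored as PathVisio dynamic properties
(``Attribute`` elements) under ``pgpath:`` keys, so writing and re-reading a
document is lossless.  Files authored by other tools are read on a
best-effort basis: edge types are inferred from the arrowhead class, and an
:class:`~pgpath.errors.UnknownArrowheadWarning` is emitted (with both types
left null) when the class is outside the documented mapping.

Output is deterministic: element order follows document order and floats are
formatted with 6 decimals, so identical documents serialize byte-identically.
"""

from __future__ import annotations

import json
import warnings

from lxml import etree

from .errors import ParseError, UnknownArrowheadWarning, ValidationError
from .model import (
    ClinicalInfo,
    Compartment,
    DrugNode,
    Edge,
    GeneNode,
    MetaboliteNode,
    PathwayDocument,
    node_id,
    validate_pathway,
)
from .vocab import (
    ActionType,
    CompartmentLevel,
    DrugKind,
    GeneRole,
    InteractionType,
    PathwayKind,
)

NS = "http://pathvisio.org/GPML/2013a"
E = "{%s}" % NS
NSMAP = {None: NS}

#: MIM-style arrowhead class per edge type; the action type takes precedence
#: over the interaction type when both are present.
ARROWHEAD_BY_ACTION = {
    ActionType.INHIBITOR: "mim-inhibition",
    ActionType.INDUCER: "mim-stimulation",
}
ARROWHEAD_BY_INTERACTION = {
    InteractionType.METABOLISM: "mim-conversion",
    InteractionType.TRANSPORTATION: "mim-translocation",
    InteractionType.BINDING: "mim-binding",
    InteractionType.EXCRETION: "Arrow",
}
#: Best-effort reverse mapping used for files without pgpath attributes.
EDGE_TYPES_BY_ARROWHEAD = {
    "mim-inhibition": (None, ActionType.INHIBITOR),
    "mim-stimulation": (None, ActionType.INDUCER),
    "mim-conversion": (InteractionType.METABOLISM, None),
    "mim-translocation": (InteractionType.TRANSPORTATION, None),
    "mim-binding": (InteractionType.BINDING, None),
    "Arrow": (InteractionType.EXCRETION, None),
}

NODE_SIZES = {"drug": (100.0, 30.0), "metabolite": (100.0, 26.0), "gene": (84.0, 26.0)}
COMPARTMENT_SIZE = (170.0, 120.0)


def _fmt(x: float) -> str:
    return f"{float(x):.6f}"


def _attr(parent, key, value):
    etree.SubElement(parent, E + "Attribute", Key=f"pgpath:{key}", Value=value)


def arrowhead_for(edge: Edge) -> str:
    if edge.action_type in ARROWHEAD_BY_ACTION:
        return ARROWHEAD_BY_ACTION[edge.action_type]
    if edge.interaction_type in ARROWHEAD_BY_INTERACTION:
        return ARROWHEAD_BY_INTERACTION[edge.interaction_type]
    return "Arrow"


def write_gpml(doc: PathwayDocument) -> str:
    """Serialize a validated pathway document to GPML text."""
    violations = validate_pathway(doc)
    if violations:
        raise ValidationError(violations)

    root = etree.Element(
        E + "Pathway",
        nsmap=NSMAP,
        Name=f"{doc.drug.name} {doc.pathway_kind.value} pathway",
        Organism="Homo sapiens",
        Version="1",
    )
    if doc.description:
        comment = etree.SubElement(root, E + "Comment", Source="pgpath:description")
        comment.text = doc.description
    _attr(root, "kind", doc.pathway_kind.value)
    if doc.administration_route:
        _attr(root, "administration_route", doc.administration_route)

    extent_x = max((xy[0] for xy in doc.layout.values()), default=0.0) + 160.0
    extent_y = max((xy[1] for xy in doc.layout.values()), default=0.0) + 160.0
    etree.SubElement(root, E + "Graphics", BoardWidth=_fmt(extent_x), BoardHeight=_fmt(extent_y))

    for n in doc.nodes:
        nid = node_id(n)
        x, y = doc.layout[nid]
        if isinstance(n, GeneNode):
            kind, label, db, xref = "gene", n.symbol, "HGNC", n.symbol
        elif isinstance(n, DrugNode):
            kind, label, db, xref = "drug", n.name, "HMDB", n.id
        else:
            kind, label, db, xref = "metabolite", n.name, "HMDB", n.id
        dn = etree.SubElement(
            root,
            E + "DataNode",
            TextLabel=label,
            GraphId=nid,
            Type="GeneProduct" if kind == "gene" else "Metabolite",
        )
        _attr(dn, "node_kind", kind)
        if isinstance(n, DrugNode):
            _attr(dn, "drug_kind", n.drug_kind.value)
            if n.clinical_info is not None:
                _attr(dn, "clinical_info", json.dumps(vars(n.clinical_info), sort_keys=True))
        elif isinstance(n, MetaboliteNode):
            _attr(dn, "active", "true" if n.active else "false")
            _attr(dn, "parent_drug", n.parent_drug)
        else:
            _attr(dn, "role", n.role.value)
            _attr(dn, "major", "true" if n.major else "false")
            _attr(dn, "compartment", n.compartment)
            _attr(dn, "gene_name", n.gene_name)
            if n.description:
                _attr(dn, "description", n.description)
        w, h = NODE_SIZES[kind]
        etree.SubElement(
            dn,
            E + "Graphics",
            CenterX=_fmt(x),
            CenterY=_fmt(y),
            Width=_fmt(w),
            Height=_fmt(h),
        )
        etree.SubElement(dn, E + "Xref", Database=db, ID=xref)

    for e in doc.edges:
        ix = etree.SubElement(root, E + "Interaction")
        if e.interaction_type:
            _attr(ix, "interaction_type", e.interaction_type.value)
        if e.action_type:
            _attr(ix, "action_type", e.action_type.value)
        g = etree.SubElement(ix, E + "Graphics")
        sx, sy = doc.layout.get(e.source, (0.0, 0.0))
        tx, ty = doc.layout.get(e.target, (0.0, 0.0))
        etree.SubElement(g, E + "Point", X=_fmt(sx), Y=_fmt(sy), GraphRef=e.source)
        etree.SubElement(
            g, E + "Point", X=_fmt(tx), Y=_fmt(ty), GraphRef=e.target, ArrowHead=arrowhead_for(e)
        )

    for c in doc.compartments:
        x, y = doc.layout[c.id]
        sh = etree.SubElement(root, E + "Shape", TextLabel=c.name, GraphId=c.id)
        _attr(sh, "level", c.level.value)
        w, h = COMPARTMENT_SIZE
        etree.SubElement(
            sh,
            E + "Graphics",
            CenterX=_fmt(x),
            CenterY=_fmt(y),
            Width=_fmt(w),
            Height=_fmt(h),
            ShapeType="Rectangle",
        )

    etree.SubElement(root, E + "InfoBox", CenterX="0.0", CenterY="0.0")
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def _attrs_of(el) -> dict:
    out = {}
    for a in el.findall(E + "Attribute"):
        key = a.get("Key", "")
        if key.startswith("pgpath:"):
            out[key[len("pgpath:"):]] = a.get("Value", "")
    return out


def _round6(x: str) -> float:
    return round(float(x), 6)


def read_gpml(text) -> PathwayDocument:
    """Parse GPML text into a pathway document.

    Inverse of :func:`write_gpml` for documents this module produced
    (lossless round-trip, layout floats compared at 1e-6).  Foreign GPML is
    accepted with edge types inferred from arrowhead classes.
    """
    data = text.encode("utf-8") if isinstance(text, str) else text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed GPML: {exc}") from exc
    if etree.QName(root).localname != "Pathway":
        raise ParseError(f"root element is {root.tag!r}, expected Pathway")

    ns = etree.QName(root).namespace
    p = ("{%s}" % ns) if ns else ""

    meta = _attrs_of(root)
    kind = PathwayKind(meta.get("kind", "PK"))
    description = None
    for c in root.findall(p + "Comment"):
        if c.get("Source") == "pgpath:description":
            description = c.text or ""

    nodes: list = []
    layout: dict = {}
    drug = None
    for dn in root.findall(p + "DataNode"):
        gid = dn.get("GraphId") or dn.get("TextLabel") or ""
        attrs = _attrs_of(dn)
        g = dn.find(p + "Graphics")
        if g is not None and g.get("CenterX") is not None:
            layout[gid] = (_round6(g.get("CenterX")), _round6(g.get("CenterY")))
        xref = dn.find(p + "Xref")
        xref_id = xref.get("ID") if xref is not None else gid
        kind_attr = attrs.get("node_kind")
        if kind_attr is None:  # foreign file: map by DataNode Type
            kind_attr = "gene" if dn.get("Type") == "GeneProduct" else "metabolite"
        if kind_attr == "drug":
            info = None
            if "clinical_info" in attrs:
                info = ClinicalInfo(**json.loads(attrs["clinical_info"]))
            drug = DrugNode(
                id=xref_id,
                name=dn.get("TextLabel", ""),
                drug_kind=DrugKind(attrs.get("drug_kind", "active_drug")),
                clinical_info=info,
            )
            nodes.append(drug)
        elif kind_attr == "gene":
            nodes.append(
                GeneNode(
                    symbol=xref_id,
                    gene_name=attrs.get("gene_name", dn.get("TextLabel", "")),
                    role=GeneRole(attrs.get("role", "enzyme")),
                    major=attrs.get("major", "false") == "true",
                    compartment=attrs.get("compartment", ""),
                    description=attrs.get("description", ""),
                )
            )
        else:
            nodes.append(
                MetaboliteNode(
                    id=xref_id,
                    name=dn.get("TextLabel", ""),
                    active=attrs.get("active", "false") == "true",
                    parent_drug=attrs.get("parent_drug", ""),
                )
            )

    edges: list = []
    for ix in root.findall(p + "Interaction"):
        attrs = _attrs_of(ix)
        points = ix.findall(f"{p}Graphics/{p}Point")
        if len(points) < 2:
            raise ParseError("Interaction element lacks the two anchor points")
        source = points[0].get("GraphRef", "")
        target = points[-1].get("GraphRef", "")
        if "interaction_type" in attrs or "action_type" in attrs:
            itype = InteractionType(attrs["interaction_type"]) if "interaction_type" in attrs else None
            atype = ActionType(attrs["action_type"]) if "action_type" in attrs else None
        else:
            arrow = points[-1].get("ArrowHead", "")
            if arrow in EDGE_TYPES_BY_ARROWHEAD:
                itype, atype = EDGE_TYPES_BY_ARROWHEAD[arrow]
            else:
                warnings.warn(
                    f"unmapped arrowhead class {arrow!r}; edge kept with null types",
                    UnknownArrowheadWarning,
                    stacklevel=2,
                )
                itype, atype = None, None
        edges.append(Edge(source, target, itype, atype))

    compartments: list = []
    for sh in root.findall(p + "Shape"):
        attrs = _attrs_of(sh)
        gid = sh.get("GraphId") or ""
        g = sh.find(p + "Graphics")
        if g is not None and g.get("CenterX") is not None:
            layout[gid] = (_round6(g.get("CenterX")), _round6(g.get("CenterY")))
        compartments.append(
            Compartment(
                id=gid,
                name=sh.get("TextLabel", gid),
                level=CompartmentLevel(attrs.get("level", "anatomical")),
            )
        )

    if drug is None:
        # foreign file: promote the first small-molecule node to the
        # principal drug (one-drug-centered convention)
        for i, n in enumerate(nodes):
            if isinstance(n, MetaboliteNode):
                drug = DrugNode(id=n.id, name=n.name, drug_kind=DrugKind.ACTIVE_DRUG)
                nodes[i] = drug
                break
        else:
            raise ParseError("document contains no drug or metabolite node")

    return PathwayDocument(
        pathway_kind=kind,
        drug=drug,
        nodes=nodes,
        edges=edges,
        compartments=compartments,
        layout=layout,
        administration_route=meta.get("administration_route"),
        description=description,
    )
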