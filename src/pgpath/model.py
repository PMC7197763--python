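"""Domain types for standardized single-drug PK/PD pathway documents.

A :class:`PathwayDocument` is *one-drug-centered*: it models every reaction a
single administered drug undergoes (pharmacokinetics, ADME at the systemic
level) or every action it exerts in the target cell (pharmacodynamics), and
nothing else.  Nodes are drugs, metabolites and genes; edges carry interaction
and action types from the controlled vocabularies in :mod:`pgpath.vocab`;
compartments anchor genes to their physiological location so that an impaired
protein can be read straight off the diagram.

:func:`validate_pathway` enforces the whole taxonomy and returns a
deterministic, ordered list of violations instead of raising, so callers can
render all problems at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .vocab import (
    PK_ACTION_TYPES,
    ActionType,
    CompartmentLevel,
    DrugKind,
    GeneRole,
    InteractionType,
    PathwayKind,
    compartment_level_for,
)


@dataclass(frozen=True)
class ClinicalInfo:
    """Free-text clinical annotation shown in a drug's pop-up window."""

    atc_class: str = ""
    indications: str = ""
    adverse_effects: str = ""
    interactions: str = ""
    pk_notes: str = ""


@dataclass(frozen=True)
class DrugNode:
    """The administered drug: an active drug, or a prodrug requiring bioactivation."""

    id: str  # HMDB-style accession
    name: str
    drug_kind: DrugKind
    clinical_info: Optional[ClinicalInfo] = None


@dataclass(frozen=True)
class MetaboliteNode:
    """An enzymatic product of the drug; ``active`` marks the therapeutic form."""

    id: str
    name: str
    active: bool
    parent_drug: str  # DrugNode id in the same document


@dataclass(frozen=True)
class GeneNode:
    """A protein-coding gene interacting with the drug, placed in a compartment."""

    symbol: str  # HGNC symbol
    gene_name: str
    role: GeneRole
    major: bool  # significant metabolizing enzyme; only valid for enzymes
    compartment: str  # Compartment id
    description: str = ""


Node = Union[DrugNode, MetaboliteNode, GeneNode]


@dataclass(frozen=True)
class Compartment:
    """A physiological location: organ, transport structure, route or organelle."""

    id: str
    name: str
    level: CompartmentLevel


@dataclass(frozen=True)
class Edge:
    """A directed reaction between two nodes.

    ``target`` normally names a node; for excretion edges it may instead name
    a transport compartment (bile duct, urinary tract, gut lumen), the final
    destination of an eliminated metabolite.
    """

    source: str
    target: str
    interaction_type: Optional[InteractionType] = None
    action_type: Optional[ActionType] = None


@dataclass
class PathwayDocument:
    """A complete single-drug PK or PD pathway with 2-D layout.

    ``layout`` maps node *and* compartment ids to (x, y) canvas centers in
    abstract units, origin top-left with y increasing downward (SVG
    convention).  Coordinates are stored rounded to 6 decimals so documents
    round-trip exactly through GPML.
    """

    pathway_kind: PathwayKind
    drug: DrugNode
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    compartments: list = field(default_factory=list)
    layout: dict = field(default_factory=dict)
    administration_route: Optional[str] = None  # PK only: Compartment id
    description: Optional[str] = None  # PD only

    def node_ids(self) -> list:
        return [node_id(n) for n in self.nodes]

    def gene_nodes(self) -> list:
        return [n for n in self.nodes if isinstance(n, GeneNode)]

    def metabolite_nodes(self) -> list:
        return [n for n in self.nodes if isinstance(n, MetaboliteNode)]


def node_id(node: Node) -> str:
    """The identifier under which a node is addressed in edges and layout."""
    if isinstance(node, GeneNode):
        return node.symbol
    return node.id


@dataclass(frozen=True)
class Violation:
    """One taxonomy violation; ``ref`` names the offending node/edge/compartment."""

    code: str
    ref: str
    message: str


def _check(violations, cond, code, ref, message):
    if not cond:
        violations.append(Violation(code, ref, message))


def validate_pathway(doc: PathwayDocument, extra_vocabulary=None) -> list:
    """Check every schema invariant on ``doc``.

    Returns an empty list iff the document conforms to the standardized
    taxonomy.  Violations are reported deterministically: document-level
    checks first, then compartments, nodes and edges in document order.

    ``extra_vocabulary`` optionally maps :class:`CompartmentLevel` to extra
    allowed compartment names (configured vocabulary extensions); names
    accepted through it are not violations.
    """
    v: list = []
    extra = {level: frozenset(names) for level, names in (extra_vocabulary or {}).items()}

    comp_ids = [c.id for c in doc.compartments]
    comp_set = set(comp_ids)
    ids = doc.node_ids()
    id_set = set(ids)
    drug_nodes = [n for n in doc.nodes if isinstance(n, DrugNode)]

    # --- document level ---------------------------------------------------
    _check(v, bool(doc.drug.id), "DRUG_ID_EMPTY", node_id(doc.drug), "principal drug id must be non-empty")
    _check(
        v,
        len(drug_nodes) == 1 and drug_nodes[0] == doc.drug,
        "PRINCIPAL_DRUG",
        node_id(doc.drug),
        "document must contain exactly one DrugNode, the principal drug",
    )
    if doc.pathway_kind is PathwayKind.PK:
        if doc.administration_route is None:
            v.append(Violation("ROUTE_MISSING", "<document>", "PK pathway requires an administration route"))
        else:
            route = next((c for c in doc.compartments if c.id == doc.administration_route), None)
            if route is None:
                v.append(Violation("ROUTE_UNRESOLVED", doc.administration_route, "administration route does not name a compartment"))
            elif route.level is not CompartmentLevel.ADMINISTRATION:
                v.append(Violation("ROUTE_NOT_ADMINISTRATION", route.id, "administration route must be an administration-level compartment"))
    else:
        _check(v, bool(doc.description), "DESCRIPTION_MISSING", "<document>", "PD pathway requires a description")

    # --- compartments -----------------------------------------------------
    seen = set()
    for c in doc.compartments:
        if c.id in seen:
            v.append(Violation("DUPLICATE_COMPARTMENT_ID", c.id, "compartment id reused within the pathway"))
        seen.add(c.id)
        allowed = compartment_level_for(c.name) is c.level or c.name in extra.get(c.level, frozenset())
        _check(v, allowed, "COMPARTMENT_NAME_UNKNOWN", c.id, f"name {c.name!r} is not in the {c.level.value} vocabulary")

    # --- nodes ------------------------------------------------------------
    seen = set()
    for n in doc.nodes:
        nid = node_id(n)
        if nid in seen:
            v.append(Violation("DUPLICATE_NODE_ID", nid, "node id reused within the pathway"))
        seen.add(nid)
        _check(v, nid in doc.layout, "LAYOUT_MISSING", nid, "node has no layout coordinates")
        if isinstance(n, MetaboliteNode):
            parent = next((d for d in drug_nodes if d.id == n.parent_drug), None)
            _check(v, parent is not None, "PARENT_DRUG_UNRESOLVED", nid, "metabolite parent_drug must name a DrugNode in the document")
        elif isinstance(n, GeneNode):
            _check(v, not n.symbol == "", "GENE_SYMBOL_EMPTY", nid, "gene symbol must be non-empty")
            _check(
                v,
                not (n.major and n.role is not GeneRole.ENZYME),
                "MAJOR_NOT_ENZYME",
                nid,
                "'major' marker is restricted to enzymes",
            )
            _check(v, n.compartment in comp_set, "COMPARTMENT_UNRESOLVED", nid, f"gene compartment {n.compartment!r} does not resolve")

    # --- edges ------------------------------------------------------------
    roles = {n.symbol: n.role for n in doc.gene_nodes()}
    for i, e in enumerate(doc.edges):
        ref = f"edge[{i}]:{e.source}->{e.target}"
        _check(
            v,
            e.interaction_type is not None or e.action_type is not None,
            "EDGE_TYPES_BOTH_NULL",
            ref,
            "edge must carry an interaction type and/or an action type",
        )
        src_ok = e.source in id_set
        tgt_ok = e.target in id_set or (
            e.interaction_type is InteractionType.EXCRETION and e.target in comp_set
        )
        _check(v, src_ok and tgt_ok, "EDGE_ENDPOINT_UNRESOLVED", ref, "edge endpoints must resolve to nodes (excretion may target a compartment)")
        if e.interaction_type is InteractionType.METABOLISM and src_ok and e.target in id_set:
            enzyme_side = roles.get(e.source) is GeneRole.ENZYME or roles.get(e.target) is GeneRole.ENZYME
            chem_side = (e.source in id_set and e.source not in roles) or (e.target in id_set and e.target not in roles)
            _check(
                v,
                enzyme_side and chem_side,
                "METABOLISM_EDGE_NODES",
                ref,
                "metabolism edges connect an enzyme gene with a drug or metabolite",
            )
        if e.interaction_type is InteractionType.TRANSPORTATION:
            mover = roles.get(e.source) or roles.get(e.target)
            _check(
                v,
                mover in (GeneRole.TRANSPORTER, GeneRole.CARRIER),
                "TRANSPORT_EDGE_NODES",
                ref,
                "transportation edges must involve a transporter or carrier gene",
            )
        if doc.pathway_kind is PathwayKind.PK and e.action_type is not None:
            _check(
                v,
                e.action_type in PK_ACTION_TYPES,
                "PK_ACTION_FORBIDDEN",
                ref,
                f"PK pathways restrict action types to inhibitor/inducer/substrate, got {e.action_type.value}",
            )
    return v
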