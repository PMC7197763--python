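"""Construct validated PK/PD pathway documents from interaction records.

The PK builder realizes the ADME narrative: the drug enters through an
administration route, is metabolized by enzymes (placed in the liver by
default), moved by transporters (intestines by default) and carriers
(arterial plasma), and its metabolites are excreted through the bile duct
(when produced in the liver) or the urinary tract.  A prodrug gains an
*active* metabolite downstream of each major (activating) enzyme; every
other enzymatic product is an inactive metabolite.

The PD builder depicts the drug's mechanism of action in the target cell:
the actor (the active metabolite for a prodrug, otherwise the drug itself)
acts on each target gene with the record's action type.
"""

from __future__ import annotations

from .errors import (
    EmptyInputError,
    MixedDrugError,
    NoTargetError,
    UnplacedGeneError,
    ValidationError,
)
from .model import (
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
    compartment_level_for,
    slug,
)

#: Default compartment per role when no placement map is given.
DEFAULT_PLACEMENT = {
    GeneRole.ENZYME: "liver",
    GeneRole.TRANSPORTER: "intestines",
    GeneRole.CARRIER: "artery",
    GeneRole.TARGET: "cell membrane",
}

_ROUND = 6


def _xy(x: float, y: float) -> tuple:
    return (round(float(x), _ROUND), round(float(y), _ROUND))


def _single_drug(records):
    if not records:
        raise EmptyInputError("no interaction records given")
    drugs = {(r.drug_id, r.drug_name) for r in records}
    if len(drugs) > 1:
        raise MixedDrugError(f"records name {len(drugs)} drugs; pathways are one-drug-centered")
    return drugs.pop()


def _compartment_for(name: str) -> Compartment:
    level = compartment_level_for(name)
    if level is None:
        # caller-supplied extension; validate_pathway will flag it unless the
        # name was registered through config (see pgpath.config)
        level = CompartmentLevel.ANATOMICAL
    return Compartment(id=slug(name), name=name, level=level)


def _resolve_placement(records, placement, default_by_role):
    """gene symbol -> compartment *name*; explicit maps must be complete."""
    genes = {r.gene_symbol: r.resolved_role() for r in records}
    if placement is None:
        return {g: default_by_role[role] for g, role in genes.items()}
    missing = sorted(set(genes) - set(placement))
    if missing:
        raise UnplacedGeneError(f"placement map does not cover genes: {missing}")
    return {g: placement[g] for g in genes}


def _layout_document(doc: PathwayDocument) -> None:
    """Deterministic schematic layout: routes on top, organ compartments in a
    middle band with their genes stacked inside, metabolites below their
    enzymes, excretion structures at the bottom."""
    layout = {}
    rows = {
        CompartmentLevel.ADMINISTRATION: 60.0,
        CompartmentLevel.ANATOMICAL: 280.0,
        CompartmentLevel.CELLULAR: 280.0,
        CompartmentLevel.TRANSPORT: 500.0,
    }
    col = {level: 0 for level in rows}
    comp_pos = {}
    for c in doc.compartments:
        x = 140.0 + 200.0 * col[c.level]
        col[c.level] += 1
        comp_pos[c.id] = (x, rows[c.level])
        layout[c.id] = _xy(x, rows[c.level])

    layout[node_id(doc.drug)] = _xy(140.0, 160.0)

    per_comp: dict = {}
    for g in doc.gene_nodes():
        k = per_comp.setdefault(g.compartment, 0)
        cx, cy = comp_pos.get(g.compartment, (140.0, 280.0))
        layout[g.symbol] = _xy(cx, cy - 28.0 + 30.0 * k)
        per_comp[g.compartment] = k + 1

    for i, m in enumerate(doc.metabolite_nodes()):
        layout[m.id] = _xy(140.0 + 120.0 * i, 400.0)

    doc.layout = layout


def build_pk_pathway(
    records,
    placement=None,
    route: str = "oral",
    drug_kind: DrugKind = DrugKind.ACTIVE_DRUG,
    clinical_info=None,
    excretion_overrides=None,
    extra_vocabulary=None,
) -> PathwayDocument:
    """Build a validated pharmacokinetic pathway from interaction records.

    Parameters
    ----------
    records : list of DrugGeneRecord
        All records must name the same drug.  Rows whose role resolves to
        ``target`` are ignored here (they belong to the PD pathway).
    placement : dict, optional
        gene symbol -> compartment name.  When omitted, role defaults apply
        (enzyme -> liver, transporter -> intestines, carrier -> artery).
        An explicit map must cover every gene.
    route : str
        Administration-route compartment name (default ``"oral"``).
    drug_kind : DrugKind
        Whether the drug is administered active or as a prodrug.
    excretion_overrides : dict, optional
        metabolite id -> compartment name, overriding the default routing
        (liver-produced metabolites -> bile duct, others -> urinary tract).
    """
    drug_id, drug_name = _single_drug(records)
    records = [r for r in records if r.resolved_role() is not GeneRole.TARGET]
    if not records:
        raise EmptyInputError("no PK-role (enzyme/transporter/carrier) records given")
    placement_names = _resolve_placement(records, placement, DEFAULT_PLACEMENT)

    drug = DrugNode(id=drug_id, name=drug_name, drug_kind=drug_kind, clinical_info=clinical_info)
    nodes: list = [drug]
    edges: list = []
    compartments: list = []
    comp_ids = set()

    def add_compartment(name):
        c = _compartment_for(name)
        if c.id not in comp_ids:
            comp_ids.add(c.id)
            compartments.append(c)
        return c.id

    route_id = add_compartment(route)
    for name in placement_names.values():
        add_compartment(name)

    seen_genes = set()
    metabolites = []
    for r in records:
        role = r.resolved_role()
        if r.gene_symbol in seen_genes:
            continue
        seen_genes.add(r.gene_symbol)
        gene = GeneNode(
            symbol=r.gene_symbol,
            gene_name=r.gene_symbol,
            role=role,
            major=bool(r.major) and role is GeneRole.ENZYME,
            compartment=slug(placement_names[r.gene_symbol]),
        )
        nodes.append(gene)
        if role is GeneRole.ENZYME:
            active = drug_kind is DrugKind.PRODRUG and gene.major
            met = MetaboliteNode(
                id=f"{drug_id}_met_{gene.symbol}",
                name=f"{drug_name} {'active ' if active else ''}metabolite ({gene.symbol})",
                active=active,
                parent_drug=drug_id,
            )
            metabolites.append((met, gene))
            edges.append(Edge(drug_id, gene.symbol, InteractionType.METABOLISM, r.action_type))
        elif role is GeneRole.TRANSPORTER:
            edges.append(Edge(drug_id, gene.symbol, InteractionType.TRANSPORTATION, r.action_type))
        else:  # carrier: plasma protein binds the drug
            edges.append(Edge(gene.symbol, drug_id, InteractionType.BINDING, r.action_type))

    overrides = excretion_overrides or {}
    for met, gene in metabolites:
        nodes.append(met)
        edges.append(Edge(gene.symbol, met.id, InteractionType.METABOLISM, None))
        if met.id in overrides:
            sink = overrides[met.id]
        elif placement_names[gene.symbol] == "liver":
            sink = "bile duct"
        else:
            sink = "urinary tract"
        edges.append(Edge(met.id, add_compartment(sink), InteractionType.EXCRETION, None))

    doc = PathwayDocument(
        pathway_kind=PathwayKind.PK,
        drug=drug,
        nodes=nodes,
        edges=edges,
        compartments=compartments,
        administration_route=route_id,
    )
    _layout_document(doc)
    violations = validate_pathway(doc, extra_vocabulary=extra_vocabulary)
    if violations:
        raise ValidationError(violations)
    return doc


def build_pd_pathway(
    records,
    description: str,
    cellular_placement=None,
    drug_kind: DrugKind = DrugKind.ACTIVE_DRUG,
    clinical_info=None,
    extra_vocabulary=None,
) -> PathwayDocument:
    """Build a validated pharmacodynamic pathway.

    ``records`` are the drug's target rows; each yields one edge from the
    actor (active metabolite for a prodrug, otherwise the drug) to the target
    gene, carrying the record's action type.  The full PD action vocabulary
    (agonist, antagonist, activator, ...) is allowed.
    """
    targets = [r for r in records if r.role is None or r.role is GeneRole.TARGET]
    if not targets:
        raise NoTargetError("PD pathway requires at least one target record")
    drug_id, drug_name = _single_drug(targets)
    placement_names = _resolve_placement(
        targets, cellular_placement, {role: "cell membrane" for role in GeneRole}
    )

    drug = DrugNode(id=drug_id, name=drug_name, drug_kind=drug_kind, clinical_info=clinical_info)
    nodes: list = [drug]
    edges: list = []
    compartments: list = []
    comp_ids = set()

    if drug_kind is DrugKind.PRODRUG:
        actor = f"{drug_id}_active_met"
        nodes.append(
            MetaboliteNode(id=actor, name=f"{drug_name} active metabolite", active=True, parent_drug=drug_id)
        )
    else:
        actor = drug_id

    seen = set()
    for r in targets:
        if r.gene_symbol in seen:
            continue
        seen.add(r.gene_symbol)
        name = placement_names[r.gene_symbol]
        level = compartment_level_for(name) or CompartmentLevel.CELLULAR
        cid = slug(name)
        if cid not in comp_ids:
            comp_ids.add(cid)
            compartments.append(Compartment(id=cid, name=name, level=level))
        nodes.append(
            GeneNode(
                symbol=r.gene_symbol,
                gene_name=r.gene_symbol,
                role=GeneRole.TARGET,
                major=False,
                compartment=cid,
            )
        )
        edges.append(
            Edge(actor, r.gene_symbol, r.interaction_type or InteractionType.BINDING, r.action_type)
        )

    doc = PathwayDocument(
        pathway_kind=PathwayKind.PD,
        drug=drug,
        nodes=nodes,
        edges=edges,
        compartments=compartments,
        description=description,
    )
    _layout_document(doc)
    violations = validate_pathway(doc, extra_vocabulary=extra_vocabulary)
    if violations:
        raise ValidationError(violations)
    return doc
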