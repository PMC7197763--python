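"""Synthetic inputs: SIFT-annotated VCFs, random pathways, worked example.

Everything here is generated data.  The VCF generator emulates the shape of
a germline call set annotated with per-variant SIFT scores, standing in for
a real individual's variant data; the clopidogrel fixture is an
illustrative, hand-curated interaction set mirroring the canonical
prodrug-activation story (CYP-mediated bioactivation, P2RY12 antagonism).
Clinical text fields are paraphrased placeholders, not database extracts.

All generators are pure functions of their spec and seed, and the VCF
generator returns a truth table computed by an *independent* oracle (plain
product and n-th root) so downstream scoring can be tested against it.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, replace

from .build import build_pd_pathway, build_pk_pathway
from .errors import SpecError
from .model import ClinicalInfo, Compartment, DrugNode, Edge, PathwayDocument
from .records import DrugGeneRecord
from .vocab import (
    ActionType,
    CompartmentLevel,
    DrugKind,
    GeneRole,
    InteractionType,
    PathwayKind,
)

_BASES = "ACGT"

#: Floor mirrored from the scoring convention (kept literal here so the
#: truth-table oracle stays independent of the gvb module).
_ORACLE_FLOOR = 1e-3


def oracle_gvb(values, floor: float = _ORACLE_FLOOR) -> float:
    """Independent burden oracle: product of floored scores, n-th root."""
    vals = list(values)
    if not vals:
        return 1.0
    prod = 1.0
    for v in vals:
        prod *= max(float(v), floor)
    return prod ** (1.0 / len(vals))


@dataclass
class SynthSpec:
    """Specification for a synthetic SIFT-annotated VCF.

    ``sift_distribution`` is a tuple: ``("uniform", lo, hi)``,
    ``("point_mass", v)`` or ``("mixture", [(weight, component), ...])``
    where each component is itself a uniform/point_mass tuple.
    """

    genes: list
    variants_per_gene: object = 3  # int or (lo, hi) inclusive range
    sift_distribution: tuple = ("uniform", 0.01, 1.0)
    fraction_noncoding: float = 0.0
    fraction_missing_sift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise SpecError("spec must name at least one gene")
        for name, frac in (
            ("fraction_noncoding", self.fraction_noncoding),
            ("fraction_missing_sift", self.fraction_missing_sift),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {frac}")
        if self.seed is None:
            raise SpecError("seed is mandatory: all generation must be reproducible")
        _validate_distribution(self.sift_distribution)


def _validate_distribution(dist):
    if not isinstance(dist, (tuple, list)) or not dist:
        raise SpecError(f"bad sift_distribution: {dist!r}")
    kind = dist[0]
    if kind == "uniform":
        _, lo, hi = dist
        if not (0.0 <= lo <= hi <= 1.0):
            raise SpecError(f"uniform bounds must satisfy 0 <= lo <= hi <= 1: {dist!r}")
    elif kind == "point_mass":
        _, v = dist
        if not 0.0 <= v <= 1.0:
            raise SpecError(f"point mass must be in [0, 1]: {dist!r}")
    elif kind == "mixture":
        _, components = dist
        if not components:
            raise SpecError("mixture needs at least one component")
        for weight, comp in components:
            if weight < 0:
                raise SpecError("mixture weights must be non-negative")
            _validate_distribution(comp)
    else:
        raise SpecError(f"unknown distribution kind {kind!r}")


def _sample_sift(rng: random.Random, dist) -> float:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2])
    if kind == "point_mass":
        return float(dist[1])
    weights = [w for w, _ in dist[1]]
    comp = rng.choices([c for _, c in dist[1]], weights=weights, k=1)[0]
    return _sample_sift(rng, comp)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pgpath-synth
##contig=<ID=chr1,length=248956422>
##INFO=<ID=GENE,Number=A,Type=String,Description="HGNC symbol per ALT allele">
##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT deleteriousness score per ALT allele">
##INFO=<ID=CONSEQ,Number=A,Type=String,Description="Consequence term per ALT allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def make_synthetic_vcf(spec: SynthSpec):
    """Generate a VCF 4.2 text plus a truth table of exact expected GVBs.

    Returns ``(vcf_text, truth)`` where ``truth`` maps each gene to the GVB
    computed by :func:`oracle_gvb` over its annotated *coding* variants only
    (records with a missing SIFT key or a non-coding consequence are written
    to the VCF but excluded from the truth, exactly as the scorer must drop
    them).
    """
    rng = random.Random(spec.seed)
    lines = [_VCF_HEADER.rstrip("\n")]
    truth = {}
    pos = 10_000
    for gene in spec.genes:
        if isinstance(spec.variants_per_gene, int):
            n = spec.variants_per_gene
        else:
            lo, hi = spec.variants_per_gene
            n = rng.randint(lo, hi)
        contributing = []
        for _ in range(n):
            pos += rng.randint(50, 500)
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            sift = _sample_sift(rng, spec.sift_distribution)
            missing = rng.random() < spec.fraction_missing_sift
            noncoding = rng.random() < spec.fraction_noncoding
            conseq = "intron_variant" if noncoding else "missense_variant"
            info = [f"GENE={gene}", f"CONSEQ={conseq}"]
            if not missing:
                info.insert(1, f"SIFT={sift:.6f}")
            gt = rng.choice(["0/1", "0/1", "1/1"])
            lines.append(
                f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}\tGT\t{gt}"
            )
            if not missing and not noncoding:
                contributing.append(float(f"{sift:.6f}"))
        truth[gene] = oracle_gvb(contributing)
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Worked example: a clopidogrel-like prodrug fixture


def clopidogrel_fixture():
    """Curated worked example: a clopidogrel-like prodrug interaction set.

    Returns ``(records, pk_doc, pd_doc, manifest)``.  The structure follows
    the canonical clopidogrel story — a prodrug bioactivated by CYP enzymes
    (CYP2C19 and CYP3A4 major), with CYP2C9/CYP1A2/CES1 as non-major
    enzymes, ABCB1 efflux transport, and antagonism of the P2RY12 receptor
    by the active metabolite.  Identifier strings and clinical text are
    illustrative placeholders (see the manifest), not database extracts.
    """
    drug_id, drug_name = "HMDB0014459", "clopidogrel"
    pk_records = [
        DrugGeneRecord(drug_id, drug_name, "CYP2C19", InteractionType.METABOLISM, ActionType.SUBSTRATE, major=True),
        DrugGeneRecord(drug_id, drug_name, "CYP3A4", InteractionType.METABOLISM, ActionType.SUBSTRATE, major=True),
        DrugGeneRecord(drug_id, drug_name, "CYP2C9", InteractionType.METABOLISM, ActionType.SUBSTRATE, major=False),
        DrugGeneRecord(drug_id, drug_name, "CYP1A2", InteractionType.METABOLISM, ActionType.SUBSTRATE, major=False),
        DrugGeneRecord(drug_id, drug_name, "CES1", InteractionType.METABOLISM, ActionType.SUBSTRATE, major=False),
        DrugGeneRecord(drug_id, drug_name, "ABCB1", InteractionType.TRANSPORTATION, ActionType.SUBSTRATE, major=False),
    ]
    pd_records = [
        DrugGeneRecord(
            drug_id, drug_name, "P2RY12", InteractionType.BINDING, ActionType.ANTAGONIST,
            major=False, role=GeneRole.TARGET,
        ),
    ]
    records = pk_records + pd_records
    clinical = ClinicalInfo(
        atc_class="B01AC04",
        indications="prevention of atherothrombotic events (illustrative summary)",
        adverse_effects="bleeding risk (illustrative summary)",
        interactions="reduced activation with CYP2C19 inhibitors (illustrative summary)",
        pk_notes="oral prodrug; hepatic CYP-mediated bioactivation (illustrative summary)",
    )
    pk_doc = build_pk_pathway(
        pk_records, route="oral", drug_kind=DrugKind.PRODRUG, clinical_info=clinical
    )
    pd_doc = build_pd_pathway(
        pd_records,
        description=(
            "The active metabolite irreversibly antagonizes the P2RY12 ADP receptor "
            "on the platelet membrane, suppressing ADP-mediated platelet activation "
            "and aggregation."
        ),
        drug_kind=DrugKind.PRODRUG,
        clinical_info=clinical,
    )
    manifest = {
        "drug_id": drug_id,
        "drug_name": drug_name,
        "provenance": "illustrative curated fixture (synthetic); not a database extract",
        "pk": {
            "n_nodes": 12,  # drug + 5 enzymes + 1 transporter + 5 metabolites
            "n_edges": 16,  # 5 substrate + 5 production + 1 transport + 5 excretion
            "n_compartments": 4,  # oral, liver, intestines, bile duct
            "n_active_metabolites": 2,  # downstream of the two major enzymes
            "major_enzymes": ["CYP2C19", "CYP3A4"],
        },
        "pd": {
            "n_nodes": 3,  # drug + active metabolite + P2RY12
            "n_edges": 1,  # antagonist edge on the target
            "n_compartments": 1,  # cell membrane
            "targets": ["P2RY12"],
        },
    }
    return records, pk_doc, pd_doc, manifest


# ---------------------------------------------------------------------------
# Random valid pathways for property tests


_GENE_POOL = [
    "CYP3A4", "CYP2D6", "CYP2C9", "CYP2C19", "CYP1A2", "CYP2B6", "CYP2E1",
    "UGT1A1", "ABCB1", "ABCG2", "SLCO1B1", "SLC22A1", "ALB", "ORM1",
    "VKORC1", "P2RY12", "ADRB1", "HMGCR", "DRD2", "EGFR",
]

_PK_PLACEMENT_BY_ROLE = {
    GeneRole.ENZYME: ["liver", "intestines", "kidney"],
    GeneRole.TRANSPORTER: ["intestines", "liver", "kidney", "blood-brain-barrier"],
    GeneRole.CARRIER: ["artery", "vein"],
}

_ROUTES = ["oral", "intravenous", "inhalation", "percutaneous"]

_PD_COMPARTMENTS = ["cell membrane", "nucleus", "endoplasmic reticulum", "mitochondria"]

_PK_INTERACTION_BY_ROLE = {
    GeneRole.ENZYME: InteractionType.METABOLISM,
    GeneRole.TRANSPORTER: InteractionType.TRANSPORTATION,
    GeneRole.CARRIER: InteractionType.BINDING,
}

_PD_ACTIONS = [
    ActionType.AGONIST, ActionType.ANTAGONIST, ActionType.ACTIVATOR,
    ActionType.MODULATOR, ActionType.COMPETITOR, ActionType.LIGAND,
    ActionType.STIMULATOR, ActionType.BINDER, ActionType.POTENTIATOR,
    ActionType.INHIBITOR,
]


def make_random_pathway(n_genes: int, kind: PathwayKind, seed: int) -> PathwayDocument:
    """Sample a valid pathway from the schema vocabularies, deterministically."""
    if n_genes < 1:
        raise SpecError("n_genes must be >= 1")
    rng = random.Random((seed, kind.value, n_genes).__repr__())
    drug_no = rng.randint(1000, 99999)
    drug_id = f"HMDB{drug_no:07d}"
    drug_name = f"drug{drug_no}"
    drug_kind = rng.choice([DrugKind.ACTIVE_DRUG, DrugKind.PRODRUG])
    genes = rng.sample(_GENE_POOL, min(n_genes, len(_GENE_POOL)))

    if kind is PathwayKind.PD:
        records = [
            DrugGeneRecord(
                drug_id, drug_name, g, InteractionType.BINDING,
                rng.choice(_PD_ACTIONS), role=GeneRole.TARGET,
            )
            for g in genes
        ]
        placement = {g: rng.choice(_PD_COMPARTMENTS) for g in genes}
        return build_pd_pathway(
            records,
            description=f"Synthetic mechanism description for {drug_name}.",
            cellular_placement=placement,
            drug_kind=drug_kind,
        )

    roles = [GeneRole.ENZYME] + [
        rng.choice([GeneRole.ENZYME, GeneRole.TRANSPORTER, GeneRole.CARRIER])
        for _ in genes[1:]
    ]
    records = []
    placement = {}
    for g, role in zip(genes, roles):
        action = rng.choice([ActionType.SUBSTRATE, ActionType.INHIBITOR, ActionType.INDUCER])
        records.append(
            DrugGeneRecord(
                drug_id, drug_name, g, _PK_INTERACTION_BY_ROLE[role], action,
                major=role is GeneRole.ENZYME and rng.random() < 0.4,
            )
        )
        placement[g] = rng.choice(_PK_PLACEMENT_BY_ROLE[role])
    return build_pk_pathway(
        records, placement=placement, route=rng.choice(_ROUTES), drug_kind=drug_kind
    )


# ---------------------------------------------------------------------------
# Seeded taxonomy violations (QA mutation suite for validate_pathway)


def seeded_violations():
    """One deliberately broken document per schema invariant.

    Returns a list of ``(label, mutated_document, expected_violation_code)``
    triples.  Each mutation starts from a fresh, valid worked-example
    document and breaks exactly one invariant; a validator with zero false
    negatives must flag every triple with the expected code.
    """
    mutations = []

    def fresh():
        _, pk_doc, pd_doc, _ = clopidogrel_fixture()
        return copy.deepcopy(pk_doc), copy.deepcopy(pd_doc)

    def add(label, doc, code):
        mutations.append((label, doc, code))

    pk, _ = fresh()
    pk.edges[0] = replace(pk.edges[0], action_type=ActionType.AGONIST)
    add("pk_edge_with_pd_action", pk, "PK_ACTION_FORBIDDEN")

    pk, _ = fresh()
    idx = next(i for i, n in enumerate(pk.nodes) if getattr(n, "symbol", "") == "ABCB1")
    pk.nodes[idx] = replace(pk.nodes[idx], major=True)
    add("major_marker_on_transporter", pk, "MAJOR_NOT_ENZYME")

    pk, _ = fresh()
    idx = next(i for i, n in enumerate(pk.nodes) if getattr(n, "parent_drug", None))
    pk.nodes[idx] = replace(pk.nodes[idx], parent_drug="DB_UNKNOWN")
    add("metabolite_orphaned", pk, "PARENT_DRUG_UNRESOLVED")

    pk, _ = fresh()
    idx = next(i for i, n in enumerate(pk.nodes) if getattr(n, "symbol", "") == "CYP2C9")
    pk.nodes[idx] = replace(pk.nodes[idx], compartment="nowhere")
    add("gene_compartment_unresolved", pk, "COMPARTMENT_UNRESOLVED")

    pk, _ = fresh()
    second = DrugNode(id="HMDB9999999", name="second drug", drug_kind=DrugKind.ACTIVE_DRUG)
    pk.nodes.append(second)
    pk.layout["HMDB9999999"] = (10.0, 10.0)
    add("two_principal_drugs", pk, "PRINCIPAL_DRUG")

    pk, _ = fresh()
    pk.edges.append(Edge("GHOST", pk.drug.id, InteractionType.BINDING, None))
    add("edge_endpoint_unresolved", pk, "EDGE_ENDPOINT_UNRESOLVED")

    pk, _ = fresh()
    pk.edges[0] = replace(pk.edges[0], interaction_type=None, action_type=None)
    add("edge_without_any_type", pk, "EDGE_TYPES_BOTH_NULL")

    pk, _ = fresh()
    pk.compartments[1] = replace(pk.compartments[1], name="spleen")
    add("compartment_outside_vocabulary", pk, "COMPARTMENT_NAME_UNKNOWN")

    pk, _ = fresh()
    pk.administration_route = None
    add("pk_without_route", pk, "ROUTE_MISSING")

    pk, _ = fresh()
    liver = next(c.id for c in pk.compartments if c.name == "liver")
    pk.administration_route = liver
    add("route_not_administration_level", pk, "ROUTE_NOT_ADMINISTRATION")

    _, pd = fresh()
    pd.description = None
    add("pd_without_description", pd, "DESCRIPTION_MISSING")

    pk, _ = fresh()
    pk.compartments.append(Compartment(id=pk.compartments[0].id, name="vein",
                                       level=CompartmentLevel.TRANSPORT))
    pk.layout.setdefault(pk.compartments[0].id, (0.0, 0.0))
    add("duplicate_compartment_id", pk, "DUPLICATE_COMPARTMENT_ID")

    pk, _ = fresh()
    i = next(j for j, e in enumerate(pk.edges)
             if e.interaction_type is InteractionType.TRANSPORTATION)
    pk.edges[i] = replace(pk.edges[i], interaction_type=InteractionType.METABOLISM)
    add("metabolism_edge_without_enzyme", pk, "METABOLISM_EDGE_NODES")

    pk, _ = fresh()
    pk.edges[0] = replace(pk.edges[0], interaction_type=InteractionType.TRANSPORTATION)
    add("transport_edge_without_mover", pk, "TRANSPORT_EDGE_NODES")

    pk, _ = fresh()
    old_id = pk.drug.id
    pk.drug = replace(pk.drug, id="")
    pk.nodes[0] = pk.drug
    pk.layout[""] = pk.layout[old_id]
    add("empty_drug_id", pk, "DRUG_ID_EMPTY")

    pk, _ = fresh()
    gene = next(n for n in pk.nodes if getattr(n, "symbol", "") == "CYP1A2")
    pk.nodes.append(gene)
    add("duplicate_node_id", pk, "DUPLICATE_NODE_ID")

    pk, _ = fresh()
    del pk.layout["CYP2C19"]
    add("node_without_layout", pk, "LAYOUT_MISSING")

    return mutations
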