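"""Personalization: gradient annotation and qualitative PK inference.

Given per-gene GVB scores, a pathway is personalized by recoloring each gene
node along a white-to-red gradient (score 1.0 = no predicted burden = the
neutral endpoint; the score floor = maximal predicted burden = the alert
endpoint).  Two qualitative rules then read predictions off the annotated
pathway:

* **Plasma concentration shift.**  The direction of the change in the
  plasma concentration of the *active ingredient* depends on the drug kind.
  For a prodrug, an impaired activating enzyme reduces bioactivation, so
  less active ingredient is formed (decreased).  For an active drug, an
  impaired metabolizing enzyme reduces clearance, so active ingredient
  accumulates (increased).  Impaired transporters/carriers are reported but
  flagged indeterminate: absorption-vs-elimination directionality depends on
  which membrane the transporter serves, which the schema does not encode.

* **Drug-gene-drug interaction.**  If drug A inhibits gene E and drug B is a
  substrate of E, the metabolism of B slows when the drugs are co-
  administered; an inducer accelerates it.  The scan is symmetric in the two
  drugs.

Predictions are strictly qualitative: a direction plus its mechanism, never
a numeric concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import logging

from .errors import KindError, SameDrugError, ScoreRangeError
from .gvb import DEFAULT_FLOOR, GvbTable
from .model import GeneNode, PathwayDocument
from .vocab import ActionType, GeneRole, PathwayKind

logger = logging.getLogger(__name__)

#: Default GVB threshold below which a gene is considered impaired.  The
#: underlying evidence is qualitative ("quite low" scores), so this cutoff is
#: an arbitrary default and should be tuned per deployment.
DEFAULT_IMPAIRED_THRESHOLD = 0.3


class Direction(str, Enum):
    DECREASED = "decreased_active_ingredient"
    INCREASED = "increased_active_ingredient"
    UNCHANGED = "unchanged"


class DdiMechanism(str, Enum):
    INHIBITION = "inhibition"
    INDUCTION = "induction"


class DdiEffect(str, Enum):
    SLOWED = "victim_metabolism_slowed"
    ACCELERATED = "victim_metabolism_accelerated"


@dataclass
class ColorScale:
    """Linear two-endpoint gradient over GVB scores."""

    neutral: str = "#FFFFFF"  # score 1.0: no burden
    alert: str = "#D7191C"  # score at the floor: maximal burden
    floor: float = DEFAULT_FLOOR


def _hex_to_rgb(color: str) -> tuple:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))


def gvb_to_color(score: float, scale: ColorScale | None = None) -> str:
    """Map a GVB score in (0, 1] to a 6-hex-digit gradient color.

    Deterministic and monotone: 1.0 maps to the neutral endpoint, the floor
    (and anything below it) to the alert endpoint, with channel-wise linear
    interpolation in between.
    """
    scale = scale or ColorScale()
    if not 0.0 < score <= 1.0:
        raise ScoreRangeError(f"GVB score {score} outside (0, 1]")
    t = (1.0 - score) / (1.0 - scale.floor)
    t = min(max(t, 0.0), 1.0)
    n = _hex_to_rgb(scale.neutral)
    a = _hex_to_rgb(scale.alert)
    rgb = tuple(round(nc + t * (ac - nc)) for nc, ac in zip(n, a))
    return "#{:02X}{:02X}{:02X}".format(*rgb)


@dataclass
class PersonalizedPathway:
    """A pathway document together with its GVB table and gene colors."""

    base: PathwayDocument
    gvb: GvbTable
    colors: dict = field(default_factory=dict)  # gene symbol -> hex color


@dataclass(frozen=True)
class ImplicatedGene:
    gene: str
    role: GeneRole
    gvb: float
    major: bool = False


@dataclass
class ConcentrationPrediction:
    drug_id: str
    direction: Direction
    mechanism: str
    implicated_genes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "direction": self.direction.value,
            "mechanism": self.mechanism,
            "implicated_genes": [
                {"gene": g.gene, "role": g.role.value, "gvb": g.gvb, "major": g.major}
                for g in self.implicated_genes
            ],
        }


@dataclass
class DdiPrediction:
    perpetrator_drug: str
    victim_drug: str
    gene: str
    mechanism: DdiMechanism
    expected_effect: DdiEffect

    def to_dict(self) -> dict:
        return {
            "perpetrator_drug": self.perpetrator_drug,
            "victim_drug": self.victim_drug,
            "gene": self.gene,
            "mechanism": self.mechanism.value,
            "expected_effect": self.expected_effect.value,
        }


def personalize(doc: PathwayDocument, gvb: GvbTable, scale: ColorScale | None = None) -> PersonalizedPathway:
    """Assign a gradient color to every gene node from its GVB score.

    Genes missing from the table default to a score of 1.0 (neutral color)
    and the default is logged.
    """
    scale = scale or ColorScale()
    colors = {}
    for gene in doc.gene_nodes():
        if gene.symbol not in gvb.entries:
            logger.info("gene %s missing from GVB table; defaulting to 1.0", gene.symbol)
        colors[gene.symbol] = gvb_to_color(gvb.score(gene.symbol), scale)
    return PersonalizedPathway(base=doc, gvb=gvb, colors=colors)


def predict_concentration_shift(
    p: PersonalizedPathway,
    impaired_threshold: float = DEFAULT_IMPAIRED_THRESHOLD,
) -> list:
    """Predict the qualitative shift in plasma active-ingredient concentration.

    Rule table (enzymes; ``impaired`` means GVB < threshold):

    ========== ======================= ====================================
    drug kind   impaired enzymes        direction
    ========== ======================= ====================================
    prodrug     any                     decreased_active_ingredient
                                        (reduced bioactivation)
    active      any                     increased_active_ingredient
                                        (reduced clearance)
    either      none                    unchanged
    ========== ======================= ====================================

    When only non-major enzymes are impaired the direction is kept but the
    mechanism text is hedged: the significance of a non-major enzyme's
    contribution is assumed, not established.  Impaired transporters and
    carriers are appended to ``implicated_genes`` with an indeterminate note;
    they never set the direction on their own.
    """
    doc = p.base
    if doc.pathway_kind is not PathwayKind.PK:
        raise KindError("concentration-shift prediction requires a PK pathway")

    impaired_enzymes = []
    impaired_transport = []
    for gene in doc.gene_nodes():
        score = p.gvb.score(gene.symbol)
        if score >= impaired_threshold:
            continue
        entry = ImplicatedGene(gene.symbol, gene.role, score, gene.major)
        if gene.role is GeneRole.ENZYME:
            impaired_enzymes.append(entry)
        else:
            impaired_transport.append(entry)

    from .vocab import DrugKind  # local import to keep module deps acyclic

    if impaired_enzymes:
        majors = [g for g in impaired_enzymes if g.major]
        genes = ", ".join(g.gene for g in impaired_enzymes)
        if doc.drug.drug_kind is DrugKind.PRODRUG:
            direction = Direction.DECREASED
            mechanism = (
                f"reduced bioactivation: impaired activating enzyme(s) {genes} are predicted "
                "to form the active metabolite at below-average levels"
            )
        else:
            direction = Direction.INCREASED
            mechanism = (
                f"reduced clearance: impaired metabolizing enzyme(s) {genes} are predicted "
                "to eliminate the active drug at below-average rates"
            )
        if not majors:
            mechanism += (
                "; note: only non-major enzyme(s) are impaired, so low metabolic capacity "
                "is assumed rather than established"
            )
        implicated = impaired_enzymes + impaired_transport
    elif impaired_transport:
        genes = ", ".join(g.gene for g in impaired_transport)
        direction = Direction.UNCHANGED
        mechanism = (
            f"indeterminate: impaired transporter/carrier(s) {genes} may alter absorption or "
            "elimination, but no directionality rule applies"
        )
        implicated = list(impaired_transport)
    else:
        direction = Direction.UNCHANGED
        mechanism = "no gene below the impairment threshold"
        implicated = []

    if impaired_transport and impaired_enzymes:
        mechanism += (
            "; impaired transporter/carrier(s) "
            + ", ".join(g.gene for g in impaired_transport)
            + " noted with indeterminate direction"
        )

    return [
        ConcentrationPrediction(
            drug_id=doc.drug.id,
            direction=direction,
            mechanism=mechanism,
            implicated_genes=implicated,
        )
    ]


def _actions_by_gene(doc: PathwayDocument) -> dict:
    """gene symbol -> set of PK action types on edges touching that gene."""
    symbols = {g.symbol for g in doc.gene_nodes()}
    actions: dict = {}
    for e in doc.edges:
        if e.action_type is None:
            continue
        for endpoint in (e.source, e.target):
            if endpoint in symbols:
                actions.setdefault(endpoint, set()).add(e.action_type)
    return actions


def infer_ddi(doc_a: PathwayDocument, doc_b: PathwayDocument) -> list:
    """Drug-gene-drug interaction scan over the genes shared by two PK pathways.

    For each shared gene E: if one drug has an inhibitor edge on E while the
    other is a substrate of E, the substrate drug's metabolism is predicted
    to slow; an inducer edge predicts accelerated metabolism.  Both
    perpetrator/victim orientations are scanned; output is ordered by gene
    symbol, then perpetrator.
    """
    for doc in (doc_a, doc_b):
        if doc.pathway_kind is not PathwayKind.PK:
            raise KindError("DDI inference requires two PK pathways")
    if doc_a.drug.id == doc_b.drug.id:
        raise SameDrugError(f"both pathways center on {doc_a.drug.id}")

    actions_a = _actions_by_gene(doc_a)
    actions_b = _actions_by_gene(doc_b)
    predictions = []
    for gene in sorted(set(actions_a) & set(actions_b)):
        for perp_doc, perp_actions, victim_doc, victim_actions in (
            (doc_a, actions_a[gene], doc_b, actions_b[gene]),
            (doc_b, actions_b[gene], doc_a, actions_a[gene]),
        ):
            if ActionType.SUBSTRATE not in victim_actions:
                continue
            if ActionType.INHIBITOR in perp_actions:
                predictions.append(
                    DdiPrediction(
                        perp_doc.drug.id, victim_doc.drug.id, gene,
                        DdiMechanism.INHIBITION, DdiEffect.SLOWED,
                    )
                )
            if ActionType.INDUCER in perp_actions:
                predictions.append(
                    DdiPrediction(
                        perp_doc.drug.id, victim_doc.drug.id, gene,
                        DdiMechanism.INDUCTION, DdiEffect.ACCELERATED,
                    )
                )
    return predictions
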