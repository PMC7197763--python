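"""Closed vocabularies of the standardized PK/PD pathway schema.

The schema restricts every node, edge and compartment to a small controlled
vocabulary so that pathways for different drugs stay interoperable:

* drugs are either *active drugs* or *prodrugs*;
* proteins act as enzymes, transporters, carriers (PK) or targets (PD);
* edges carry an *interaction type* (the protein's role in the reaction:
  metabolism, transportation, binding, excretion) and/or an *action type*
  (how drug and protein act on one another: inhibitor, inducer, substrate
  in PK; the wider agonist/antagonist/... vocabulary in PD);
* compartments are drawn from fixed anatomical, transport-structure,
  administration-route and cellular-component lists.
"""

from __future__ import annotations

import re
from enum import Enum


class PathwayKind(str, Enum):
    PK = "PK"
    PD = "PD"


class DrugKind(str, Enum):
    ACTIVE_DRUG = "active_drug"
    PRODRUG = "prodrug"


class GeneRole(str, Enum):
    ENZYME = "enzyme"
    TRANSPORTER = "transporter"
    CARRIER = "carrier"
    TARGET = "target"


class CompartmentLevel(str, Enum):
    ANATOMICAL = "anatomical"
    TRANSPORT = "transport"
    ADMINISTRATION = "administration"
    CELLULAR = "cellular"


class InteractionType(str, Enum):
    METABOLISM = "metabolism"
    TRANSPORTATION = "transportation"
    BINDING = "binding"
    EXCRETION = "excretion"


class ActionType(str, Enum):
    INHIBITOR = "inhibitor"
    INDUCER = "inducer"
    SUBSTRATE = "substrate"
    AGONIST = "agonist"
    ANTAGONIST = "antagonist"
    ACTIVATOR = "activator"
    MODULATOR = "modulator"
    COMPETITOR = "competitor"
    COFACTOR = "cofactor"
    LIGAND = "ligand"
    STIMULATOR = "stimulator"
    ANTIBODY = "antibody"
    BINDER = "binder"
    POTENTIATOR = "potentiator"
    NEUTRALIZER = "neutralizer"


class Genotype(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


#: Action types permitted on edges of a pharmacokinetic pathway.
PK_ACTION_TYPES = frozenset(
    {ActionType.INHIBITOR, ActionType.INDUCER, ActionType.SUBSTRATE}
)

ANATOMICAL_COMPARTMENTS = frozenset(
    {
        "eye",
        "nose",
        "mouth",
        "brain",
        "blood-brain-barrier",
        "lung",
        "heart",
        "muscle",
        "skin",
        "kidney",
        "liver",
        "adrenal gland",
        "testis",
        "intestines",
        "placenta",
    }
)

TRANSPORT_COMPARTMENTS = frozenset(
    {"artery", "vein", "bile duct", "urinary tract", "gut lumen"}
)

ADMINISTRATION_COMPARTMENTS = frozenset(
    {
        "eye drop",
        "inhalation",
        "sublingual/buccal",
        "oral",
        "intravenous",
        "intramuscular",
        "percutaneous",
    }
)

CELLULAR_COMPARTMENTS = frozenset(
    {
        "nucleus",
        "endoplasmic reticulum",
        "mitochondria",
        "Golgi apparatus",
        "lysosome",
        "peroxisome",
        "vesicle",
        "cell membrane",
        "ribosome",
    }
)

COMPARTMENT_VOCABULARY: dict[CompartmentLevel, frozenset[str]] = {
    CompartmentLevel.ANATOMICAL: ANATOMICAL_COMPARTMENTS,
    CompartmentLevel.TRANSPORT: TRANSPORT_COMPARTMENTS,
    CompartmentLevel.ADMINISTRATION: ADMINISTRATION_COMPARTMENTS,
    CompartmentLevel.CELLULAR: CELLULAR_COMPARTMENTS,
}

#: Role a gene plays, inferred from the interaction type of its record.
#: Target rows are identified explicitly (PD builders), not by interaction.
ROLE_BY_INTERACTION: dict[InteractionType, GeneRole] = {
    InteractionType.METABOLISM: GeneRole.ENZYME,
    InteractionType.TRANSPORTATION: GeneRole.TRANSPORTER,
    InteractionType.BINDING: GeneRole.CARRIER,
    InteractionType.EXCRETION: GeneRole.TRANSPORTER,
}


def compartment_level_for(name: str) -> CompartmentLevel | None:
    """Return the vocabulary level a compartment name belongs to, if any."""
    for level, names in COMPARTMENT_VOCABULARY.items():
        if name in names:
            return level
    return None


def slug(name: str) -> str:
    """Stable identifier for a compartment name ('bile duct' -> 'bile_duct')."""
    return re.sub(r"[^A-Za-z0-9]+", "_", name.strip()).strip("_").lower()
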