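# Methods

`pgpath` models the journey of a single drug through the human body as a
standardized, machine-readable diagram, and personalizes that diagram with a
per-gene summary of an individual's deleterious coding variation. This note
documents the model, the scoring statistic, the inference rules, the
synthetic-data generators, and the numerical and design choices behind them.

## The pathway model

A pathway document is *one-drug-centered*: it describes either the
pharmacokinetics (PK) of one drug — absorption, distribution, metabolism and
excretion (ADME) at the systemic level — or its pharmacodynamics (PD), the
mechanism of action in the target cell. It never represents a whole metabolic
or signaling network; personalized therapy reasons about the administered drug
only.

**Nodes.** Drugs are either *active drugs* (pharmacologically active as
administered) or *prodrugs* (requiring enzymatic bioactivation). Metabolites
are enzymatic products, marked *active* when they carry the therapeutic
effect. Genes play one of four roles: enzyme, transporter, carrier (PK) or
target (PD); enzymes may additionally carry the *major* marker for a
significant contribution to the drug's metabolism.

**Edges** carry an interaction type (metabolism, transportation, binding,
excretion — the protein's role in the reaction) and/or an action type (how
drug and protein act on each other). PK pathways restrict action types to
inhibitor/inducer/substrate; PD pathways admit the full pharmacological
vocabulary (agonist, antagonist, activator, modulator, competitor, cofactor,
ligand, stimulator, antibody, binder, potentiator, neutralizer).

**Compartments** are drawn from closed vocabularies: anatomical organs (liver,
intestines, kidney, ...), transport structures (artery, vein, bile duct,
urinary tract, gut lumen), administration routes (oral, intravenous, ...) and
cellular components (nucleus, cell membrane, ...). The vocabulary is
extensible through configuration — some drugs need extra compartments — but
every extension is logged, keeping the default schema strict.

`validate_pathway` enforces the whole taxonomy and returns ordered,
deterministic violation records rather than raising, so a document's problems
can be reported all at once. One deliberate widening: an excretion edge's
*target* may resolve to a transport compartment (bile duct, urinary tract, gut
lumen) rather than a node, because elimination terminates in a structure, not
a molecule.

### Construction rules

`build_pk_pathway` turns an interaction table into a validated document:

- each enzyme row yields drug → enzyme (metabolism, with the row's action) and
  enzyme → metabolite (metabolism) edges;
- on a prodrug, each *major* enzyme emits an **active** metabolite; non-major
  enzymes emit inactive metabolites. This is the minimal rule linking the
  'major' and 'active' markers: bioactivation is exactly what the major-enzyme
  marker asserts;
- transporter rows yield transportation edges, carrier rows binding edges
  (carrier → drug, plasma-protein binding);
- metabolites produced in the liver are excreted via the bile duct, all others
  via the urinary tract (overridable per metabolite);
- default placement when no map is given: enzymes → liver, transporters →
  intestines, carriers → artery, targets → cell membrane. This follows the
  standard oral-drug ADME narrative (portal-vein delivery to the liver,
  first-pass metabolism); expression-driven tissue placement is intentionally
  out of scope, so placement is always explicit or a documented default.

`build_pd_pathway` depicts mechanism of action: the *actor* (the active
metabolite for a prodrug, otherwise the drug) gets one edge per target with
the record's action type. The drug and active metabolite appear as nodes, but
no drug → metabolite conversion edge is drawn: a metabolism edge without an
enzyme endpoint would violate the edge taxonomy, and the PD diagram's subject
is the target interaction, not the conversion chemistry.

A gene interacting in two roles (say enzyme and transporter) is represented as
two role-specific records and would produce two nodes; the interaction table
is the ingestion boundary and keeps one row per role.

## Gene-wise variant burden (GVB)

The GVB score of a gene is the geometric mean of the SIFT scores of its coding
variants. SIFT scores lie in [0, 1], lower = more likely damaging, so a lower
GVB summarizes greater predicted impairment of the protein across all its
variants. A gene with no qualifying variants scores exactly 1.0.

Numerical choices:

- **Zero floor.** SIFT = 0 would annihilate the geometric mean; scores are
  floored at `1e-3` (configurable) before the log transform, so the result
  stays in (0, 1].
- **Log-space mean.** Computed as `exp(mean(log(s)))` for stability; the input
  is sorted first so the float summation order is canonical and the score is
  bitwise invariant under permutation of the variants.
- **Printed precision.** Annotation sources are consumed at 6-decimal
  precision, which also undoes the float32 widening of VCF INFO Float fields.
- **Zygosity.** Each qualifying variant contributes once regardless of
  het/hom-alt genotype (the definition aggregates the *set* of coding
  variants); a flag can double-count homozygous alts, off by default.
- **No deleteriousness cutoff by default.** All coding SIFT-scored variants
  contribute. An optional threshold (e.g. contribute only SIFT < 0.7) exists
  because parts of the burden-score literature use one; it is never applied
  silently.
- Variants annotated to several genes contribute to each independently; coding
  status is taken from the annotation source, never re-derived.

Three VCF annotation layouts are supported: a plain per-ALT INFO float, a
VEP/CSQ-style pipe-delimited field (where several transcripts annotate one
allele/gene pair, the minimum — most deleterious — SIFT is kept), and a
sidecar TSV. Records without SIFT and non-coding consequences are dropped and
counted in a parse report; multi-allelic records are decomposed per ALT.

## Personalization and qualitative inference

**Gradient.** Gene nodes are recolored along a linear two-endpoint gradient:
score 1.0 → neutral (`#FFFFFF`), the floor → alert (`#D7191C`), channel-wise
linear interpolation in between. The mapping is deterministic and monotone:
a lower score is always channel-wise closer to the alert endpoint.

**Concentration shift.** A gene is *impaired* when its GVB falls below a
threshold (default **0.3**, CLI-overridable). The underlying evidence for any
particular cutoff is qualitative, so this default is arbitrary and should be
tuned per deployment. The rule engine is a truth table over
{prodrug, active drug} × {impaired enzymes present or not}:

| drug kind | impaired enzyme(s) | prediction |
|---|---|---|
| prodrug | any | decreased active ingredient (reduced bioactivation) |
| active drug | any | increased active ingredient (reduced clearance) |
| either | none | unchanged |

When only non-major enzymes are impaired the direction is kept but the
mechanism text is hedged — low metabolic capacity of a non-major enzyme is
assumed, not established. Impaired transporters/carriers are reported among
the implicated genes with an *indeterminate* note and never set the direction:
whether impaired transport raises or lowers plasma exposure depends on which
membrane the transporter serves, which the schema does not encode.
Reabsorption is likewise excluded from the rule engine. Predictions are
strictly qualitative — a direction plus its mechanism, never a concentration.

**Drug-gene-drug interactions.** For each gene shared by two PK pathways: an
inhibitor edge from drug A plus a substrate edge from drug B predicts that
B's metabolism slows under co-administration; an inducer edge predicts
acceleration. The scan is symmetric in the two drugs and ordered by gene
symbol, so output is deterministic.

## Serialization and rendering

GPML is written natively in the 2013a dialect (the dialect PathVisio 3.x
writes). Fields the dialect has no slot for (drug kind, markers, roles,
compartment levels) ride in `Attribute` dynamic properties under `pgpath:`
keys, making write → read lossless; foreign files are read best-effort with
edge types inferred from arrowhead classes (unknown classes keep the edge
with null types and emit a warning). The arrowhead mapping:

| edge type | arrowhead class |
|---|---|
| metabolism | `mim-conversion` |
| transportation | `mim-translocation` |
| binding | `mim-binding` |
| excretion | plain `Arrow` |
| inhibitor | `mim-inhibition` |
| inducer | `mim-stimulation` |

Serialization is deterministic: element order follows document order and all
floats print with 6 decimals, so identical documents are byte-identical, and
layout coordinates (stored rounded to 6 decimals; abstract units, origin
top-left, y downward per SVG convention) round-trip exactly.

The SVG symbol standard (all hex values theme-overridable): prodrug amber and
active drug blue share the pill shape; inactive metabolite grey and active
metabolite blue likewise; enzyme green rounded rectangle, transporter purple
ellipse, carrier teal ellipse, target red rectangle; 'major'/'active' badges
as adjacent glyphs. Every node is one addressable element with a stable id
(`gene:<HGNC>`, `drug:<HMDB>`, `met:<id>`). A built-in schematic vector frame
(the compartment boxes) is always drawn so diagrams are complete without
raster artwork; a PNG background can be base64-embedded beneath everything,
and the final self-contained HTML attaches click hooks that open per-node
info windows (drug: name/ATC/indications/ADEs/interactions/PK notes, linked
to HMDB; gene: symbol/name/context fields, linked to HGNC; PD documents add a
pathway-description window). Empty fields render as "—".

## Synthetic data

The VCF generator emulates the *shape* of a SIFT-annotated germline call set:
configurable genes, variants per gene, SIFT distribution (uniform, point
mass, or mixture), and fractions of records with a missing SIFT key or a
non-coding consequence. It does not emulate linkage, allele frequencies, real
gene coordinates or genotype-quality structure — passing tests demonstrate
correct *aggregation and plumbing*, not calibration against any population.
Contig names are GRCh38-style and positions arbitrary, since no genomic logic
depends on them. Every generator is a pure function of its spec and seed, and
the generator returns a truth table computed by an independent oracle (plain
product, n-th root — no code shared with the scorer) so the scorer can be
tested against it.

The clopidogrel worked example is an illustrative curated fixture: a prodrug
bioactivated by CYP2C19/CYP3A4 (major) with CYP2C9/CYP1A2/CES1 non-major,
ABCB1 efflux, and P2RY12 antagonism by the active metabolite. Identifiers and
clinical strings are placeholders marked as such in its manifest; the
topology, not the text, is the tested substance.

## Problem sizes used in the checks

The automated checks run 1,000 random SIFT sets (sizes 1–50) against the
burden oracle, 1,000 randomized monotonicity/permutation cases, 200 random
pathways through the GPML round-trip, a 17-mutation taxonomy suite, a
100-point gradient sweep, and the full CLI chain twice for byte-level
determinism. These sizes make every property check complete in seconds while
exercising each code path many times over.

## Known limitations

- Predictions depend entirely on the correctness of the curated interaction
  table; there is no gold standard for the gene set, and the inference assumes
  it is right.
- Only genetic factors are modeled — no drug dosing, adherence, organ
  function, or quantitative PK (no compartment ODEs).
- SIFT is the only deleteriousness source; variants without SIFT annotations
  are invisible to the score.
- The impairment threshold and the prodrug-activation topology rule are
  defaults chosen for internal consistency, not clinically validated cutoffs.
- Tissue placement is schematic (role defaults or explicit maps), not
  expression-driven.
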