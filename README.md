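# pgpath

Standardized single-drug pharmacokinetic/pharmacodynamic pathway modeling
with gene-wise variant burden personalization.

## The problem

Pharmacogenomics-based pathway diagrams show the reactions between an
administered drug and the genes that move, metabolize, bind and respond to
it. Two things make most such diagrams hard to use for individualized
prescribing: they are not standardized (every resource draws nodes, edges and
body locations differently), and they are static (they show the reference
human, not the patient in front of you).

`pgpath` addresses both for researchers and clinical bioinformaticians. It
models each drug as a *one-drug-centered* pathway with a closed taxonomy:

- **PK pathway** — absorption, distribution, metabolism and excretion (ADME)
  at the systemic level: drug and metabolite nodes, gene nodes in the roles
  enzyme / transporter / carrier, placed in anatomical compartments (liver,
  intestines, bile duct, ...), with metabolism / transportation / binding /
  excretion edges and inhibitor / inducer / substrate actions.
- **PD pathway** — the mechanism of action in the target cell: the drug or
  its active metabolite acting on target genes with the full pharmacological
  action vocabulary (agonist, antagonist, activator, ...).

Prodrugs and active drugs are distinguished, major metabolizing enzymes carry
a `major` marker, and therapeutic metabolites an `active` marker. Documents
serialize to GPML (the PathVisio/WikiPathways XML dialect) and render to SVG
and self-contained HTML with per-node information windows.

## Personalization: the GVB score

The gene-wise variant burden of gene *g* with coding variants scored by SIFT
as s₁, …, sₙ ∈ [0, 1] is the geometric mean

GVB(g) = (∏ᵢ max(sᵢ, ε))^(1/n),  with floor ε = 10⁻³ and GVB = 1 for n = 0.

Lower SIFT means a more likely damaging substitution, so a lower GVB
summarizes greater predicted impairment of the protein. Scores computed from
a VCF recolor each gene node along a white→red gradient, and two qualitative
rules read predictions off the personalized diagram:

- **Plasma concentration shift** — for a *prodrug*, an impaired activating
  enzyme (GVB below a threshold, default 0.3) predicts *decreased* active
  ingredient (reduced bioactivation); for an *active drug*, an impaired
  metabolizing enzyme predicts *increased* active ingredient (reduced
  clearance); otherwise unchanged.
- **Drug-gene-drug interaction** — if drug A inhibits gene E and drug B is a
  substrate of E, B's metabolism slows under co-administration; an inducer
  accelerates it.

Predictions are strictly qualitative (a direction plus its mechanism), never
numeric concentrations. See `docs/methods.md` for the full model, defaults
and limitations.

## Worked example

The package ships a clopidogrel-like worked example: a prodrug bioactivated
by CYP2C19 and CYP3A4 (major enzymes), with CYP2C9/CYP1A2/CES1 non-major,
ABCB1 efflux transport and P2RY12 antagonism by the active metabolite (an
illustrative curated fixture — see its manifest). Score a synthetic
SIFT-annotated VCF carrying two damaging CYP2C19 variants (SIFT 0.05) and
predict the shift:

```python
from pgpath import (SiftSource, SynthSpec, clopidogrel_fixture,
                    make_synthetic_vcf, parse_variants, personalize,
                    predict_concentration_shift, score_genes)

records, pk_doc, pd_doc, manifest = clopidogrel_fixture()
vcf_text, truth = make_synthetic_vcf(SynthSpec(
    genes=["CYP2C19"], variants_per_gene=2,
    sift_distribution=("point_mass", 0.05), seed=1))
variants, report = parse_variants(vcf_text, SiftSource())
table = score_genes(variants, [g.symbol for g in pk_doc.gene_nodes()])
print(table.to_tsv())
pred = predict_concentration_shift(personalize(pk_doc, table))[0]
print(pred.direction.value)
print(pred.mechanism)
```

which prints

```
gene	gvb	n_variants
ABCB1	1.000000	0
CES1	1.000000	0
CYP1A2	1.000000	0
CYP2C19	0.050000	2
CYP2C9	1.000000	0
CYP3A4	1.000000	0

decreased_active_ingredient
reduced bioactivation: impaired activating enzyme(s) CYP2C19 are predicted to form the active metabolite at below-average levels
```

The GVB table says: two coding variants of SIFT 0.05 give CYP2C19 a burden
score of 0.05 (geometric mean of equal values), every other pathway gene is
variant-free and scores 1.0. Because clopidogrel is a prodrug and CYP2C19 is
an impaired *activating* enzyme, the engine predicts the active ingredient
will form at below-average levels — the drug may not reach its full
therapeutic effect. With an all-1.0 table the same call returns `unchanged`.

The same flow is available from the shell:

```sh
pgpath synth fixture --out fixtures/clopidogrel
pgpath build --records fixtures/clopidogrel/records.tsv --kind pk \
       --drug-kind prodrug --out pk.gpml
pgpath score --vcf sample.vcf --genes pk.gpml --out gvb.tsv
pgpath personalize pk.gpml --gvb gvb.tsv --threshold 0.3 \
       --out personalized.html --report predictions.json
pgpath ddi a.gpml b.gpml --out ddi.json
```

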