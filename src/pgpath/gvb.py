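"""Gene-wise variant burden (GVB) scoring from SIFT-annotated variants.

The GVB score of a gene is the geometric mean of the SIFT scores of its
coding variants.  SIFT scores lie in [0, 1] with lower values predicting a
more damaging amino-acid substitution, so a lower GVB score summarizes a
greater predicted functional impairment of the protein across all of its
variants.  A gene with no qualifying variants scores 1.0 (no predicted
burden).

A SIFT score of exactly 0 would annihilate the geometric mean, so scores are
floored at a small positive value (default 1e-3) before the log transform;
the floor is configurable.  The mean is computed in log space for numerical
stability.

Variants are read from VCF with three annotation layouts supported:

* a plain float INFO key (one value, or one per ALT allele),
* a VEP/CSQ-style pipe-delimited INFO field with named subfields,
* a sidecar TSV keyed on (chrom, pos, ref, alt).

Records without a SIFT value and non-coding consequences are dropped and
counted in a parse report; multi-allelic records are decomposed into one
variant per (record, alt allele, gene) triple.
"""

from __future__ import annotations

import csv
import io
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from cyvcf2 import VCF

from .errors import FormatError, MissingSourceError, ScoreRangeError
from .vocab import Genotype

#: Default floor applied to SIFT = 0 before the log transform.
DEFAULT_FLOOR = 1e-3

#: Sequence-ontology consequence terms treated as coding.
CODING_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "stop_retained_variant",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "coding_sequence_variant",
        "protein_altering_variant",
    }
)


@dataclass(frozen=True)
class Variant:
    """One coding variant with its SIFT deleteriousness score."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene_symbol: str
    sift: float
    coding: bool = True
    genotype: Genotype = Genotype.HET

    def __post_init__(self):
        if not 0.0 <= self.sift <= 1.0:
            raise ScoreRangeError(f"SIFT score {self.sift} outside [0, 1]")
        if self.pos < 1:
            raise FormatError(f"position {self.pos} is not 1-based")
        if self.alt == self.ref:
            raise FormatError(f"alt allele equals ref at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class SiftSource:
    """Where SIFT annotations live.

    kind='info'    — ``key`` is a float INFO field (one value or one per ALT);
                     ``gene_key`` names the gene-symbol INFO field and
                     ``consequence_key`` (optional) the consequence field.
    kind='csq'     — ``key`` is a VEP-style pipe-delimited INFO field;
                     subfield names give the positions of allele, gene,
                     consequence and SIFT inside each annotation block.
    kind='sidecar' — annotations come from a TSV with columns
                     chrom, pos, ref, alt, gene, sift [, coding].
    """

    kind: str = "info"
    key: str = "SIFT"
    gene_key: str = "GENE"
    consequence_key: Optional[str] = "CONSEQ"
    allele_field: str = "Allele"
    gene_field: str = "SYMBOL"
    consequence_field: str = "Consequence"
    sift_field: str = "SIFT"
    csq_format: Optional[str] = None  # e.g. "Allele|SYMBOL|Consequence|SIFT"
    sidecar_text: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("info", "csq", "sidecar"):
            raise FormatError(f"unknown SIFT source kind {self.kind!r}")


@dataclass
class ParseReport:
    """Bookkeeping for dropped records during VCF parsing."""

    n_records: int = 0
    n_variants: int = 0
    drops_no_sift: int = 0
    drops_noncoding: int = 0
    drops_no_gene: int = 0

    @property
    def drops(self) -> int:
        return self.drops_no_sift + self.drops_noncoding + self.drops_no_gene


@dataclass
class GvbEntry:
    score: float
    n_variants: int
    variant_ids: list = field(default_factory=list)


@dataclass
class GvbTable:
    """Per-gene burden scores with variant counts and provenance."""

    entries: dict = field(default_factory=dict)

    def score(self, gene: str, default: float = 1.0) -> float:
        e = self.entries.get(gene)
        return e.score if e is not None else default

    def to_tsv(self) -> str:
        out = io.StringIO()
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "gvb", "n_variants"])
        for gene in sorted(self.entries):
            e = self.entries[gene]
            w.writerow([gene, f"{e.score:.6f}", e.n_variants])
        return out.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "GvbTable":
        reader = csv.DictReader(io.StringIO(text), delimiter="\t")
        required = {"gene", "gvb", "n_variants"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"GVB TSV requires columns {sorted(required)}")
        table = cls()
        for row in reader:
            table.entries[row["gene"]] = GvbEntry(
                score=float(row["gvb"]), n_variants=int(row["n_variants"])
            )
        return table


def compute_gvb(sift_scores, floor: float = DEFAULT_FLOOR) -> float:
    """Geometric mean of SIFT scores, the gene-wise variant burden.

    An empty score set returns 1.0 (no variants, no predicted burden).
    Scores are floored at ``floor`` before the log transform so that a single
    SIFT of 0 cannot collapse the mean to 0; the result always lies in
    (0, 1].
    """
    scores = np.asarray(list(sift_scores), dtype=float)
    if scores.size == 0:
        return 1.0
    if np.any(scores < 0.0) or np.any(scores > 1.0):
        bad = scores[(scores < 0.0) | (scores > 1.0)]
        raise ScoreRangeError(f"SIFT scores outside [0, 1]: {bad.tolist()}")
    # sorting makes the float summation order canonical, so the score is
    # bitwise invariant under permutation of the variants
    scores = np.sort(scores)
    return min(float(np.exp(np.mean(np.log(np.maximum(scores, floor))))), 1.0)


def score_genes(
    variants,
    gene_universe,
    floor: float = DEFAULT_FLOOR,
    sift_threshold: Optional[float] = None,
    count_hom_alt_twice: bool = False,
) -> GvbTable:
    """Score every gene in ``gene_universe`` from a variant list.

    Genes without qualifying variants score 1.0 with a variant count of 0.
    ``sift_threshold``, when set, restricts contribution to variants with
    SIFT below the threshold (off by default: every coding SIFT-scored
    variant contributes).  ``count_hom_alt_twice`` optionally weights
    homozygous-alt variants twice (off by default: each qualifying variant
    contributes once regardless of zygosity).
    """
    gene_universe = list(gene_universe)
    if not gene_universe:
        raise FormatError("gene universe must be non-empty")
    by_gene: dict = {g: [] for g in gene_universe}
    ids: dict = {g: [] for g in gene_universe}
    for var in variants:
        if var.gene_symbol not in by_gene:
            continue
        if not var.coding:
            continue
        if sift_threshold is not None and var.sift >= sift_threshold:
            continue
        copies = 2 if (count_hom_alt_twice and var.genotype is Genotype.HOM_ALT) else 1
        by_gene[var.gene_symbol].extend([var.sift] * copies)
        ids[var.gene_symbol].append(var.variant_id)
    table = GvbTable()
    for g in gene_universe:
        table.entries[g] = GvbEntry(
            score=compute_gvb(by_gene[g], floor=floor),
            n_variants=len(ids[g]),
            variant_ids=ids[g],
        )
    return table


# ---------------------------------------------------------------------------
# VCF parsing


def _header_has_info(vcf: VCF, key: str) -> bool:
    return re.search(rf"##INFO=<ID={re.escape(key)},", vcf.raw_header) is not None


def _as_float(value) -> Optional[float]:
    # scores are consumed at the annotation's printed precision (6 decimals);
    # this also undoes the float32 widening of VCF INFO Float fields
    try:
        return round(float(value), 6)
    except (TypeError, ValueError):
        # VEP renders SIFT as e.g. "deleterious(0.03)"
        m = re.search(r"\(([0-9.eE+-]+)\)", str(value))
        return round(float(m.group(1)), 6) if m else None


def _per_alt_values(raw, n_alts: int) -> list:
    if raw is None:
        return [None] * n_alts
    if isinstance(raw, (tuple, list, np.ndarray)):
        vals = list(raw)
    else:
        vals = str(raw).split(",") if isinstance(raw, str) and "," in str(raw) else [raw]
    if len(vals) == 1:
        vals = vals * n_alts
    if len(vals) != n_alts:
        vals = (vals + [None] * n_alts)[:n_alts]
    return vals


def _load_sidecar(text: str) -> dict:
    lookup: dict = {}
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"chrom", "pos", "ref", "alt", "gene", "sift"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise FormatError(f"sidecar TSV requires columns {sorted(required)}")
    for row in reader:
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        coding = str(row.get("coding", "true")).strip().lower() not in ("false", "0", "no")
        lookup.setdefault(key, []).append((row["gene"], float(row["sift"]), coding))
    return lookup


def _genotype_of(record) -> Genotype:
    try:
        gt = record.gt_types
    except Exception:
        return Genotype.HET
    if gt is not None and len(gt) > 0 and int(gt[0]) == 3:  # cyvcf2: 3 = HOM_ALT
        return Genotype.HOM_ALT
    return Genotype.HET


def parse_variants(vcf_source, sift_source: SiftSource):
    """Extract SIFT-annotated coding variants from a VCF.

    ``vcf_source`` is a path to a VCF 4.x file (plain or bgzipped) or a
    file-like/str containing VCF text.  Returns ``(variants, report)`` where
    the report counts dropped records (missing SIFT, non-coding, no gene).
    """
    tmp_path = None
    if hasattr(vcf_source, "read"):
        vcf_source = vcf_source.read()
    if isinstance(vcf_source, str) and "\n" in vcf_source:
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(vcf_source)
        path = tmp_path
    else:
        path = str(vcf_source)
        if not os.path.exists(path):
            raise FormatError(f"VCF not found: {path}")
    try:
        try:
            vcf = VCF(path)
        except Exception as exc:
            raise FormatError(f"unparseable VCF: {exc}") from exc
        try:
            return _parse_open_vcf(vcf, sift_source)
        finally:
            vcf.close()
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


def _parse_open_vcf(vcf: VCF, src: SiftSource):
    if src.kind in ("info", "csq") and not _header_has_info(vcf, src.key):
        raise MissingSourceError(f"INFO key {src.key!r} not declared in the VCF header")
    if src.kind == "csq":
        fmt = src.csq_format or _csq_format_from_header(vcf, src.key)
        fields = fmt.split("|")
        idx = {}
        for name in (src.allele_field, src.gene_field, src.consequence_field, src.sift_field):
            if name not in fields:
                raise MissingSourceError(f"subfield {name!r} not in {src.key} format {fmt!r}")
            idx[name] = fields.index(name)
    sidecar = _load_sidecar(src.sidecar_text) if src.kind == "sidecar" else None

    report = ParseReport()
    variants: list = []
    for rec in vcf:
        report.n_records += 1
        genotype = _genotype_of(rec)
        alts = list(rec.ALT or [])
        if src.kind == "sidecar":
            for alt in alts:
                rows = sidecar.get((rec.CHROM, rec.POS, rec.REF, alt))
                if not rows:
                    report.drops_no_sift += 1
                    continue
                for gene, sift, coding in rows:
                    if not coding:
                        report.drops_noncoding += 1
                        continue
                    variants.append(
                        Variant(rec.CHROM, rec.POS, rec.REF, alt, gene, sift, True, genotype)
                    )
                    report.n_variants += 1
        elif src.kind == "csq":
            raw = rec.INFO.get(src.key)
            blocks = str(raw).split(",") if raw is not None else []
            per_triple: dict = {}
            for block in blocks:
                parts = block.split("|")
                if len(parts) <= max(idx.values()):
                    continue
                allele = parts[idx[src.allele_field]]
                gene = parts[idx[src.gene_field]]
                conseq = parts[idx[src.consequence_field]]
                sift = _as_float(parts[idx[src.sift_field]])
                if allele not in alts or not gene:
                    continue
                coding = bool(set(re.split("[&,]", conseq)) & CODING_CONSEQUENCES)
                key = (allele, gene)
                # several transcripts may annotate one (alt, gene): keep the
                # most deleterious (minimum) SIFT
                prev = per_triple.get(key)
                if sift is not None:
                    if prev is None or prev[0] is None or sift < prev[0]:
                        per_triple[key] = (sift, coding or (prev[1] if prev else False))
                    elif coding and not prev[1]:
                        per_triple[key] = (prev[0], True)
                elif prev is None:
                    per_triple[key] = (None, coding)
            annotated = {a for a, _ in per_triple}
            for alt in alts:
                if alt not in annotated:
                    report.drops_no_sift += 1
            for (allele, gene), (sift, coding) in sorted(per_triple.items()):
                if sift is None:
                    report.drops_no_sift += 1
                elif not coding:
                    report.drops_noncoding += 1
                else:
                    variants.append(
                        Variant(rec.CHROM, rec.POS, rec.REF, allele, gene, sift, True, genotype)
                    )
                    report.n_variants += 1
        else:  # plain INFO key
            sifts = _per_alt_values(rec.INFO.get(src.key), len(alts))
            genes = _per_alt_values(rec.INFO.get(src.gene_key), len(alts))
            conseqs = _per_alt_values(
                rec.INFO.get(src.consequence_key) if src.consequence_key else None, len(alts)
            )
            for alt, sift_raw, gene, conseq in zip(alts, sifts, genes, conseqs):
                sift = _as_float(sift_raw)
                if sift is None:
                    report.drops_no_sift += 1
                    continue
                if gene is None or str(gene) == "":
                    report.drops_no_gene += 1
                    continue
                if src.consequence_key is not None and conseq is not None:
                    coding = bool(set(re.split("[&,]", str(conseq))) & CODING_CONSEQUENCES)
                else:
                    coding = True
                if not coding:
                    report.drops_noncoding += 1
                    continue
                for g in str(gene).split("&"):  # a variant may map to several genes
                    variants.append(
                        Variant(rec.CHROM, rec.POS, rec.REF, alt, g, sift, True, genotype)
                    )
                    report.n_variants += 1
    return variants, report


def _csq_format_from_header(vcf: VCF, key: str) -> str:
    m = re.search(
        rf'##INFO=<ID={re.escape(key)},[^>]*Format: ([^">]+)', vcf.raw_header
    )
    if m is None:
        raise MissingSourceError(
            f"INFO key {key!r} has no 'Format:' description and no csq_format was configured"
        )
    return m.group(1).strip()
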