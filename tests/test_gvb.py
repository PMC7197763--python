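"""GVB scoring: geometric-mean properties and VCF annotation parsing."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgpath import SiftSource, compute_gvb, parse_variants, score_genes
from pgpath.errors import FormatError, MissingSourceError, ScoreRangeError
from pgpath.gvb import DEFAULT_FLOOR, GvbTable, Variant
from pgpath.vocab import Genotype


def product_root_oracle(values, floor=DEFAULT_FLOOR):
    """Independent brute-force oracle: plain product, then the n-th root."""
    if not values:
        return 1.0
    prod = 1.0
    for v in values:
        prod *= max(v, floor)
    return prod ** (1.0 / len(values))


sift_scores = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestComputeGvb:
    def test_closed_form_pair(self):
        assert compute_gvb([0.2, 0.8]) == 0.4  # sqrt(0.2 * 0.8)

    def test_no_variants_scores_one(self):
        assert compute_gvb([]) == 1.0

    def test_equal_values_score_themselves(self):
        assert compute_gvb([0.05, 0.05]) == pytest.approx(0.05, abs=1e-12)

    def test_zero_sift_is_floored_not_annihilating(self):
        assert compute_gvb([0.0]) == pytest.approx(DEFAULT_FLOOR, abs=1e-15)
        assert compute_gvb([0.0, 1.0]) == pytest.approx(
            math.sqrt(DEFAULT_FLOOR), abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoreRangeError):
            compute_gvb([0.5, 1.2])
        with pytest.raises(ScoreRangeError):
            compute_gvb([-0.1])

    def test_matches_oracle_on_seeded_uniform_draws(self):
        rng = random.Random(42)
        values = [rng.uniform(0.01, 1.0) for _ in range(10)]
        assert compute_gvb(values) == pytest.approx(product_root_oracle(values), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(sift_scores, min_size=1, max_size=50))
    def test_matches_oracle_on_random_sets(self, values):
        assert compute_gvb(values) == pytest.approx(product_root_oracle(values), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(sift_scores, min_size=1, max_size=30))
    def test_bounds_and_permutation_invariance(self, values):
        score = compute_gvb(values)
        assert DEFAULT_FLOOR - 1e-15 < score <= 1.0
        shuffled = list(values)
        random.Random(0).shuffle(shuffled)
        assert compute_gvb(shuffled) == score

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=DEFAULT_FLOOR, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=DEFAULT_FLOOR, max_value=1.0),
    )
    def test_monotone_burden(self, values, s):
        """Appending a score below the current mean strictly lowers it, above raises it."""
        before = compute_gvb(values)
        after = compute_gvb(values + [s])
        if math.isclose(s, before, rel_tol=1e-9):
            assert after == pytest.approx(before, abs=1e-9)
        elif s < before:
            assert after < before
        else:
            assert after > before

    def test_smaller_sift_scores_lower(self):
        # two genes identical except one value: the more deleterious scores lower
        assert compute_gvb([0.5, 0.1]) < compute_gvb([0.5, 0.4])


def _variant(gene, sift, **kw):
    return Variant("chr1", 100, "A", "G", gene, sift, **kw)


class TestScoreGenes:
    def test_genes_without_variants_default_to_one(self):
        table = score_genes(
            [_variant("CYP2C9", 0.2)], ["CYP2C9", "CYP2C19", "ABCB1"]
        )
        assert table.entries["CYP2C19"].score == 1.0
        assert table.entries["CYP2C19"].n_variants == 0
        assert table.entries["ABCB1"].score == 1.0
        assert table.entries["CYP2C9"].score == pytest.approx(0.2, abs=1e-12)

    def test_per_gene_agreement_with_oracle_on_synthetic_set(self):
        rng = random.Random(3)
        genes = [f"G{i}" for i in range(5)]
        variants, expected = [], {}
        for g in genes:
            vals = [rng.uniform(0.01, 1.0) for _ in range(8)]
            expected[g] = product_root_oracle(vals)
            variants += [Variant("chr1", 10 + i, "A", "C", g, v) for i, v in enumerate(vals)]
        rng.shuffle(variants)
        table = score_genes(variants, genes)
        for g in genes:
            assert table.entries[g].score == pytest.approx(expected[g], abs=1e-12)
            assert table.entries[g].n_variants == 8

    def test_noncoding_variants_do_not_contribute(self):
        table = score_genes(
            [_variant("G", 0.1), _variant("G", 0.5, coding=False)], ["G"]
        )
        assert table.entries["G"].score == pytest.approx(0.1, abs=1e-12)
        assert table.entries["G"].n_variants == 1

    def test_optional_sift_threshold_filters_tolerated_variants(self):
        variants = [_variant("G", 0.05), _variant("G", 0.9)]
        assert score_genes(variants, ["G"]).entries["G"].n_variants == 2
        filtered = score_genes(variants, ["G"], sift_threshold=0.7)
        assert filtered.entries["G"].n_variants == 1
        assert filtered.entries["G"].score == pytest.approx(0.05, abs=1e-12)

    def test_optional_homozygous_double_counting(self):
        variants = [
            _variant("G", 0.1, genotype=Genotype.HOM_ALT),
            _variant("G", 0.9, genotype=Genotype.HET),
        ]
        default = score_genes(variants, ["G"]).entries["G"].score
        weighted = score_genes(variants, ["G"], count_hom_alt_twice=True).entries["G"].score
        assert default == pytest.approx((0.1 * 0.9) ** 0.5, abs=1e-12)
        assert weighted == pytest.approx((0.1 * 0.1 * 0.9) ** (1 / 3), abs=1e-12)

    def test_tsv_roundtrip(self):
        table = score_genes([_variant("G", 0.25)], ["G", "H"])
        text = table.to_tsv()
        back = GvbTable.from_tsv(text)
        assert back.entries["G"].score == pytest.approx(0.25, abs=1e-6)
        assert back.entries["H"].n_variants == 0


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=248956422>\n'
    '##INFO=<ID=GENE,Number=A,Type=String,Description="gene">\n'
    '##INFO=<ID=SIFT,Number=A,Type=Float,Description="sift">\n'
    '##INFO=<ID=CONSEQ,Number=A,Type=String,Description="consequence">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


class TestParseVariants:
    def test_coding_annotated_snvs_are_kept(self):
        vcf = VCF_HEADER + (
            "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=CYP2C9;SIFT=0.05;CONSEQ=missense_variant\tGT\t0/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\tGENE=CYP2C9;SIFT=0.3;CONSEQ=stop_gained\tGT\t1/1\n"
            "chr1\t300\t.\tG\tA\t.\tPASS\tGENE=CYP2C9;SIFT=0.9;CONSEQ=missense_variant\tGT\t0/1\n"
        )
        variants, report = parse_variants(vcf, SiftSource())
        assert len(variants) == 3 and report.drops == 0
        assert variants[1].genotype is Genotype.HOM_ALT
        assert variants[0].sift == 0.05

    def test_missing_sift_is_dropped_and_counted(self):
        vcf = VCF_HEADER + (
            "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=CYP2C9;SIFT=0.05;CONSEQ=missense_variant\tGT\t0/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\tGENE=CYP2C9;CONSEQ=missense_variant\tGT\t0/1\n"
        )
        variants, report = parse_variants(vcf, SiftSource())
        assert len(variants) == 1
        assert report.drops_no_sift == 1

    def test_noncoding_is_dropped_and_counted(self):
        vcf = VCF_HEADER + (
            "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=CYP2C9;SIFT=0.4;CONSEQ=intron_variant\tGT\t0/1\n"
        )
        variants, report = parse_variants(vcf, SiftSource())
        assert variants == [] and report.drops_noncoding == 1

    def test_multiallelic_records_are_decomposed(self):
        vcf = VCF_HEADER + (
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t"
            "GENE=CYP2C9,CYP2C9;SIFT=0.1,0.2;CONSEQ=missense_variant,missense_variant\tGT\t0/1\n"
        )
        variants, report = parse_variants(vcf, SiftSource())
        assert [(v.alt, v.sift) for v in variants] == [("G", 0.1), ("T", 0.2)]

    def test_missing_info_key_raises(self):
        vcf = VCF_HEADER.replace('##INFO=<ID=SIFT,Number=A,Type=Float,Description="sift">\n', "")
        vcf += "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=X;CONSEQ=missense_variant\tGT\t0/1\n"
        with pytest.raises(MissingSourceError):
            parse_variants(vcf, SiftSource())

    def test_garbage_input_raises_format_error(self):
        with pytest.raises(FormatError):
            parse_variants("this is\nnot a vcf\n", SiftSource())

    def test_csq_style_annotation(self):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=248956422>\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
            'Format: Allele|SYMBOL|Consequence|SIFT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        vcf = header + (
            "chr1\t100\t.\tA\tG\t.\tPASS\t"
            "CSQ=G|CYP2C19|missense_variant|deleterious(0.03),"
            "G|CYP2C19|missense_variant|tolerated(0.44),"
            "G|ABCB1|intron_variant|\tGT\n"
        )
        variants, report = parse_variants(vcf, SiftSource(kind="csq", key="CSQ"))
        assert len(variants) == 1  # most deleterious transcript wins; intron annotation dropped
        assert variants[0].gene_symbol == "CYP2C19"
        assert variants[0].sift == 0.03

    def test_sidecar_annotation(self):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=248956422>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        vcf = header + "chr1\t100\t.\tA\tG\t.\tPASS\t.\n" + "chr1\t200\t.\tC\tT\t.\tPASS\t.\n"
        sidecar = (
            "chrom\tpos\tref\talt\tgene\tsift\n"
            "chr1\t100\tA\tG\tCYP2C9\t0.12\n"
        )
        variants, report = parse_variants(
            vcf, SiftSource(kind="sidecar", sidecar_text=sidecar)
        )
        assert len(variants) == 1 and variants[0].sift == 0.12
        assert report.drops_no_sift == 1  # the un-annotated record
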