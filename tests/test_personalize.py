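"""Gradient coloring and the qualitative prediction rule engines."""

import logging

import pytest

from pgpath import (
    ActionType,
    ColorScale,
    Direction,
    DrugGeneRecord,
    DrugKind,
    GvbTable,
    InteractionType,
    build_pk_pathway,
    gvb_to_color,
    infer_ddi,
    personalize,
    predict_concentration_shift,
)
from pgpath.errors import KindError, SameDrugError, ScoreRangeError
from pgpath.gvb import GvbEntry
from pgpath.personalize import DdiEffect, DdiMechanism
from pgpath.vocab import GeneRole, PathwayKind
from pgpath.synthetic import make_random_pathway


def _table(**scores):
    t = GvbTable()
    for gene, s in scores.items():
        t.entries[gene] = GvbEntry(score=s, n_variants=1)
    return t


def _hex_channels(color):
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))


class TestColorGradient:
    def test_endpoints(self):
        scale = ColorScale()
        assert gvb_to_color(1.0, scale) == "#FFFFFF"
        assert gvb_to_color(scale.floor, scale) == "#D7191C"

    def test_midpoint_matches_channelwise_arithmetic(self):
        scale = ColorScale()
        t = (1.0 - 0.5) / (1.0 - scale.floor)
        expected = tuple(
            round(n + t * (a - n))
            for n, a in zip(_hex_channels(scale.neutral), _hex_channels(scale.alert))
        )
        assert _hex_channels(gvb_to_color(0.5, scale)) == expected

    def test_monotone_towards_alert_on_sweep(self):
        scale = ColorScale()
        alert = _hex_channels(scale.alert)
        scores = [scale.floor + i * (1.0 - scale.floor) / 99 for i in range(100)]
        prev = None
        for s in scores:  # increasing score moves away from the alert endpoint
            channels = _hex_channels(gvb_to_color(s, scale))
            dist = [abs(c - a) for c, a in zip(channels, alert)]
            if prev is not None:
                assert all(d2 >= d1 for d1, d2 in zip(prev, dist))
            prev = dist

    def test_out_of_range_scores_rejected(self):
        for bad in (0.0, -0.2, 1.0001):
            with pytest.raises(ScoreRangeError):
                gvb_to_color(bad)


class TestPersonalize:
    def test_all_neutral_when_no_burden(self, pk_doc):
        table = _table(**{g.symbol: 1.0 for g in pk_doc.gene_nodes()})
        p = personalize(pk_doc, table)
        assert set(p.colors.values()) == {"#FFFFFF"}
        assert set(p.colors) == {g.symbol for g in pk_doc.gene_nodes()}

    def test_impaired_gene_shifts_toward_alert(self, pk_doc):
        p = personalize(pk_doc, _table(CYP2C9=0.05))
        assert p.colors["CYP2C9"] == gvb_to_color(0.05)
        assert p.colors["CYP2C19"] == "#FFFFFF"

    def test_missing_gene_defaults_neutral_and_logs(self, pk_doc, caplog):
        with caplog.at_level(logging.INFO, logger="pgpath.personalize"):
            p = personalize(pk_doc, _table(CYP2C9=0.5))
        assert p.colors["ABCB1"] == "#FFFFFF"
        assert any("ABCB1" in r.message for r in caplog.records)


def _pk_doc(drug_kind, major_impaired=True, drug=("HMDB0000010", "drugA")):
    records = [
        DrugGeneRecord(drug[0], drug[1], "ENZMAJ", InteractionType.METABOLISM,
                       ActionType.SUBSTRATE, major=True),
        DrugGeneRecord(drug[0], drug[1], "ENZMIN", InteractionType.METABOLISM,
                       ActionType.SUBSTRATE, major=False),
        DrugGeneRecord(drug[0], drug[1], "TRANS1", InteractionType.TRANSPORTATION,
                       ActionType.SUBSTRATE),
    ]
    placement = {"ENZMAJ": "liver", "ENZMIN": "liver", "TRANS1": "intestines"}
    return build_pk_pathway(records, placement=placement, drug_kind=drug_kind)


class TestConcentrationShift:
    @pytest.mark.parametrize(
        "drug_kind, impaired, expected",
        [
            (DrugKind.PRODRUG, {"ENZMAJ": 0.05}, Direction.DECREASED),
            (DrugKind.PRODRUG, {"ENZMIN": 0.05}, Direction.DECREASED),
            (DrugKind.PRODRUG, {}, Direction.UNCHANGED),
            (DrugKind.ACTIVE_DRUG, {"ENZMAJ": 0.05}, Direction.INCREASED),
            (DrugKind.ACTIVE_DRUG, {"ENZMIN": 0.05}, Direction.INCREASED),
            (DrugKind.ACTIVE_DRUG, {}, Direction.UNCHANGED),
            # threshold not crossed: scores above the cutoff leave the drug unchanged
            (DrugKind.PRODRUG, {"ENZMAJ": 0.5}, Direction.UNCHANGED),
            (DrugKind.ACTIVE_DRUG, {"ENZMAJ": 0.5}, Direction.UNCHANGED),
        ],
    )
    def test_rule_table(self, drug_kind, impaired, expected):
        doc = _pk_doc(drug_kind)
        scores = {"ENZMAJ": 1.0, "ENZMIN": 1.0, "TRANS1": 1.0, **impaired}
        preds = predict_concentration_shift(personalize(doc, _table(**scores)), 0.3)
        assert len(preds) == 1  # exactly one direction per drug
        assert preds[0].direction is expected
        if expected is Direction.UNCHANGED:
            assert preds[0].implicated_genes == []
        else:
            assert [g.gene for g in preds[0].implicated_genes] == list(impaired)

    def test_nonmajor_only_impairment_is_hedged(self):
        doc = _pk_doc(DrugKind.PRODRUG)
        preds = predict_concentration_shift(
            personalize(doc, _table(ENZMIN=0.05)), 0.3
        )
        assert preds[0].direction is Direction.DECREASED
        assert "non-major" in preds[0].mechanism
        assert "reduced bioactivation" in preds[0].mechanism

    def test_transporter_only_impairment_is_indeterminate(self):
        doc = _pk_doc(DrugKind.ACTIVE_DRUG)
        preds = predict_concentration_shift(
            personalize(doc, _table(TRANS1=0.05)), 0.3
        )
        assert preds[0].direction is Direction.UNCHANGED
        assert "indeterminate" in preds[0].mechanism
        assert [g.gene for g in preds[0].implicated_genes] == ["TRANS1"]
        assert preds[0].implicated_genes[0].role is GeneRole.TRANSPORTER

    def test_pd_document_rejected(self):
        pd = make_random_pathway(2, PathwayKind.PD, seed=5)
        with pytest.raises(KindError):
            predict_concentration_shift(personalize(pd, GvbTable()))


def _ddi_doc(drug, gene_actions):
    records = [
        DrugGeneRecord(drug[0], drug[1], gene, InteractionType.METABOLISM, action)
        for gene, action in gene_actions
    ]
    return build_pk_pathway(records, drug_kind=DrugKind.ACTIVE_DRUG)


class TestDdi:
    def test_inhibitor_on_shared_substrate_slows_victim(self):
        a = _ddi_doc(("DRA", "drugA"), [("CYP3A4", ActionType.INHIBITOR)])
        b = _ddi_doc(("DRB", "drugB"), [("CYP3A4", ActionType.SUBSTRATE)])
        preds = infer_ddi(a, b)
        assert len(preds) == 1
        p = preds[0]
        assert (p.perpetrator_drug, p.victim_drug, p.gene) == ("DRA", "DRB", "CYP3A4")
        assert p.mechanism is DdiMechanism.INHIBITION
        assert p.expected_effect is DdiEffect.SLOWED

    def test_inducer_on_shared_substrate_accelerates_victim(self):
        a = _ddi_doc(("DRA", "drugA"), [("CYP3A4", ActionType.INDUCER)])
        b = _ddi_doc(("DRB", "drugB"), [("CYP3A4", ActionType.SUBSTRATE)])
        preds = infer_ddi(a, b)
        assert len(preds) == 1
        assert preds[0].expected_effect is DdiEffect.ACCELERATED

    def test_no_prediction_without_substrate_or_shared_gene(self):
        a = _ddi_doc(("DRA", "drugA"), [("CYP3A4", ActionType.INHIBITOR)])
        b = _ddi_doc(("DRB", "drugB"), [("CYP3A4", ActionType.INHIBITOR)])
        assert infer_ddi(a, b) == []
        c = _ddi_doc(("DRC", "drugC"), [("CYP2D6", ActionType.SUBSTRATE)])
        assert infer_ddi(a, c) == []

    def test_symmetry_up_to_labeling(self):
        a = _ddi_doc(("DRA", "drugA"),
                     [("CYP3A4", ActionType.INHIBITOR), ("CYP2D6", ActionType.SUBSTRATE)])
        b = _ddi_doc(("DRB", "drugB"),
                     [("CYP3A4", ActionType.SUBSTRATE), ("CYP2D6", ActionType.INDUCER)])
        ab = {(p.perpetrator_drug, p.victim_drug, p.gene, p.mechanism) for p in infer_ddi(a, b)}
        ba = {(p.perpetrator_drug, p.victim_drug, p.gene, p.mechanism) for p in infer_ddi(b, a)}
        assert ab == ba
        assert len(ab) == 2

    def test_same_drug_and_pd_rejected(self):
        a = _ddi_doc(("DRA", "drugA"), [("CYP3A4", ActionType.SUBSTRATE)])
        with pytest.raises(SameDrugError):
            infer_ddi(a, a)
        pd = make_random_pathway(1, PathwayKind.PD, seed=1)
        with pytest.raises(KindError):
            infer_ddi(a, pd)
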