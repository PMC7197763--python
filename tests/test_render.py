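"""Rendering contract: symbol standard, GVB recoloring, HTML assembly."""

from dataclasses import replace

import pytest
from lxml import etree

from pgpath import (
    GvbTable,
    gvb_to_color,
    make_info_window,
    merge_with_background,
    render_svg,
)
from pgpath.errors import ImageDecodeError, TypeMismatchError, ValidationError
from pgpath.gvb import GvbEntry
from pgpath.render import Theme, element_id
from pgpath.model import node_id
from pgpath.vocab import ActionType

SVG_NS = "http://www.w3.org/2000/svg"


def _shape_elements(svg_text):
    root = etree.fromstring(svg_text.encode())
    out = {}
    for tag in ("rect", "ellipse"):
        for el in root.iter(f"{{{SVG_NS}}}{tag}"):
            eid = el.get("id") or ""
            if eid.startswith(("gene:", "drug:", "met:")) and not eid.endswith((":major", ":active")):
                out[eid] = el
    return out


def _table(**scores):
    t = GvbTable()
    for g, s in scores.items():
        t.entries[g] = GvbEntry(score=s, n_variants=1)
    return t


class TestRenderSvg:
    def test_one_addressable_element_per_node(self, pk_doc):
        diagram = render_svg(pk_doc)
        shapes = _shape_elements(diagram.svg_text)
        assert len(shapes) == len(pk_doc.nodes)
        assert set(diagram.node_anchor_index) == {node_id(n) for n in pk_doc.nodes}
        assert set(diagram.node_anchor_index.values()) == set(shapes)

    def test_prodrug_and_active_metabolite_share_shape_differ_in_fill(self, pk_doc):
        theme = Theme()
        shapes = _shape_elements(render_svg(pk_doc).svg_text)
        drug_el = shapes[element_id(pk_doc.drug)]
        active_met = next(m for m in pk_doc.metabolite_nodes() if m.active)
        met_el = shapes[element_id(active_met)]
        assert etree.QName(drug_el).localname == etree.QName(met_el).localname == "rect"
        assert drug_el.get("fill") == theme.prodrug
        assert met_el.get("fill") == theme.active_metabolite
        assert drug_el.get("fill") != met_el.get("fill")

    def test_gene_roles_differ_in_shape_and_color(self, pk_doc):
        theme = Theme()
        shapes = _shape_elements(render_svg(pk_doc).svg_text)
        enzyme = shapes["gene:CYP2C19"]
        transporter = shapes["gene:ABCB1"]
        assert etree.QName(enzyme).localname == "rect"
        assert etree.QName(transporter).localname == "ellipse"
        assert enzyme.get("fill") == theme.enzyme
        assert transporter.get("fill") == theme.transporter

    def test_major_and_active_badges_present(self, pk_doc):
        svg = render_svg(pk_doc).svg_text
        assert 'id="gene:CYP2C19:major"' in svg
        assert 'id="gene:CYP3A4:major"' in svg
        assert 'id="gene:CYP2C9:major"' not in svg
        active_met = next(m for m in pk_doc.metabolite_nodes() if m.active)
        assert f'id="met:{active_met.id}:active"' in svg

    def test_gvb_overrides_gene_fills(self, pk_doc):
        table = _table(CYP2C9=0.05)
        shapes = _shape_elements(render_svg(pk_doc, gvb=table).svg_text)
        assert shapes["gene:CYP2C9"].get("fill") == gvb_to_color(0.05)
        for symbol in ("CYP2C19", "CYP3A4", "ABCB1"):
            assert shapes[f"gene:{symbol}"].get("fill") == gvb_to_color(1.0)
        # drug/metabolite fills stay on the symbol standard
        assert shapes[element_id(pk_doc.drug)].get("fill") == Theme().prodrug

    def test_all_neutral_table_gives_no_burden_color(self, pk_doc):
        table = _table(**{g.symbol: 1.0 for g in pk_doc.gene_nodes()})
        shapes = _shape_elements(render_svg(pk_doc, gvb=table).svg_text)
        for g in pk_doc.gene_nodes():
            assert shapes[f"gene:{g.symbol}"].get("fill") == "#FFFFFF"

    def test_out_of_range_gvb_rejected(self, pk_doc):
        with pytest.raises(Exception) as exc_info:
            render_svg(pk_doc, gvb=_table(CYP2C9=1.5))
        assert "outside" in str(exc_info.value)

    def test_invalid_document_rejected(self, pk_doc):
        pk_doc.edges[0] = replace(pk_doc.edges[0], action_type=ActionType.AGONIST)
        with pytest.raises(ValidationError):
            render_svg(pk_doc)

    def test_background_png_embedded_beneath_nodes(self, pk_doc, white_png):
        svg = render_svg(pk_doc, background=white_png).svg_text
        assert "data:image/png;base64," in svg
        assert svg.index('id="background"') < svg.index('id="nodes"')

    def test_identical_inputs_yield_identical_bytes(self, pk_doc):
        assert render_svg(pk_doc).svg_text == render_svg(pk_doc).svg_text


class TestMergeWithBackground:
    def test_single_embedded_image_and_full_node_set(self, pk_doc, white_png):
        html = merge_with_background(render_svg(pk_doc), white_png)
        assert html.count("<img") == 1
        assert html.count("data:image/png;base64,") == 1
        for n in pk_doc.nodes:
            assert f'id="{element_id(n)}"' in html

    def test_info_window_hooks_attached_to_anchors(self, pk_doc, white_png):
        html = merge_with_background(render_svg(pk_doc), white_png)
        assert f'data-window="win:{element_id(pk_doc.drug)}"' in html
        assert 'data-window="win:gene:CYP2C19"' in html
        assert "addEventListener" in html

    def test_pd_description_window_included(self, pd_doc, white_png):
        html = merge_with_background(render_svg(pd_doc), white_png)
        assert 'id="win:description"' in html
        assert "P2RY12" in html

    def test_corrupt_bytes_rejected(self, pk_doc):
        with pytest.raises(ImageDecodeError):
            merge_with_background(render_svg(pk_doc), b"\x89PNG not really")


class TestInfoWindows:
    def test_drug_window_lists_clinical_fields(self, pk_doc):
        frag = make_info_window(pk_doc.drug)
        assert "B01AC04" in frag  # ATC class from the fixture
        assert "hmdb.ca" in frag
        assert pk_doc.drug.name in frag

    def test_empty_fields_render_as_dash(self):
        from pgpath.model import DrugNode
        from pgpath.vocab import DrugKind

        frag = make_info_window(DrugNode("HMDB0000001", "bare drug", DrugKind.ACTIVE_DRUG))
        assert frag.count("—") == 5  # ATC, indications, ADEs, interactions, PK

    def test_gene_window_links_to_hgnc(self, pk_doc):
        gene = next(g for g in pk_doc.gene_nodes() if g.symbol == "CYP2C19")
        frag = make_info_window(gene, extra={"expression_tissue": "liver"})
        assert "CYP2C19" in frag
        assert "genenames.org" in frag
        assert "liver" in frag

    def test_metabolite_has_no_window(self, pk_doc):
        met = pk_doc.metabolite_nodes()[0]
        with pytest.raises(TypeMismatchError):
            make_info_window(met)
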