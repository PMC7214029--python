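"""Markdown rendering, page assembly, and the offline/determinism
contracts."""

import json
import re

import lxml.etree as etree
import pytest
from bs4 import BeautifulSoup

from molpage import fixtures as fx
from molpage.page_builder import (PageDocument, PageError,
                                  embedded_structures, load_page_document,
                                  page_state, prolink_anchors,
                                  render_markdown, render_page)
from molpage.prolinks import ProlinkAction, parse_prolink, render_prolink
from molpage.selection_lang import All
from molpage.structure_io import write_pdb
from molpage.variants import build_variant_page, parse_variant
from molpage.view_model import Representation, ViewSpec


@pytest.fixture()
def minimal_doc(helix12):
    spec = ViewSpec(structures=((helix12, True),),
                    representations=(Representation(
                        kind="cartoon", selection=All(),
                        object_id=helix12.id),))
    return PageDocument(title="helix", body_markdown="",
                        viewspecs=(("main", spec),), initial_view="main")


class TestMarkdown:
    def test_basic_formatting(self):
        assert "<strong>bold</strong>" in render_markdown("**bold**")
        assert "<h2>" in render_markdown("## heading")

    def test_prolink_anchor_passes_through_byte_identical(self):
        anchor = render_prolink(
            ProlinkAction(focus=All(), label="x & y"), "see <view>")
        out = render_markdown(f"Look at {anchor} now.")
        assert anchor in out

    def test_script_stripped_and_raw_html_escaped(self):
        out = render_markdown(
            "hello <script>alert('x')</script> <b>bold?</b>")
        assert "<script" not in out
        assert "alert" not in out
        assert "<b>" not in out  # raw HTML escaped, not interpreted


class TestRenderPage:
    def test_minimal_page_contract(self, minimal_doc, helix12):
        page = render_page(minimal_doc)
        soup = BeautifulSoup(page, "html.parser")
        assert len(soup.select("#molpage-viewport")) == 1
        assert soup.select("a.prolink") == []
        back = embedded_structures(page)["helix"]
        assert back == helix12

    def test_offline_page_has_no_external_urls(self, minimal_doc):
        page = render_page(minimal_doc)
        assert "http://" not in page and "https://" not in page

    def test_online_page_references_pinned_viewer(self, minimal_doc):
        doc = PageDocument(title=minimal_doc.title,
                           body_markdown=minimal_doc.body_markdown,
                           viewspecs=minimal_doc.viewspecs,
                           initial_view="main",
                           options={"offline": False,
                                    "background": "FFFFFF", "spin": False})
        page = render_page(doc)
        assert "https://unpkg.com/ngl@" in page

    def test_byte_determinism(self, helix12):
        doc = build_variant_page(
            helix12, [parse_variant(v) for v in ("A3T", "A5V")], chain="A")
        assert render_page(doc) == render_page(doc)

    def test_wellformed_and_unique_ids(self, helix12):
        doc = build_variant_page(
            helix12, [parse_variant(v) for v in ("A3T", "A5V", "A9G")],
            chain="A")
        page = render_page(doc)
        root = etree.fromstring(page.encode())
        ids = root.xpath("//@id")
        assert len(ids) == len(set(ids))

    def test_variant_page_anchor_targets(self, helix12):
        doc = build_variant_page(
            helix12, [parse_variant(v) for v in ("A3T", "A5V", "A9G")],
            chain="A")
        page = render_page(doc)
        soup = BeautifulSoup(page, "html.parser")
        anchors = soup.select("a.prolink")
        assert [a["data-load"] for a in anchors] == [
            "variant-1", "variant-2", "variant-3"]
        for a in anchors:
            parse_prolink({k: v for k, v in a.attrs.items()
                           if k.startswith("data-")})

    def test_dangling_load_target_rejected_before_output(self, helix12):
        spec = ViewSpec(structures=((helix12, True),))
        anchor = render_prolink(ProlinkAction(load="ghost"), "go")
        doc = PageDocument(title="t", body_markdown=f"see {anchor}",
                           viewspecs=(("main", spec),),
                           initial_view="main")
        with pytest.raises(PageError, match="ghost"):
            render_page(doc)

    def test_front_image_swap_element(self, minimal_doc):
        doc = PageDocument(title="t", body_markdown="",
                           viewspecs=minimal_doc.viewspecs,
                           initial_view="main", front_image="figure1.png")
        page = render_page(doc)
        soup = BeautifulSoup(page, "html.parser")
        img = soup.select("#molpage-front-image")
        assert len(img) == 1 and img[0]["src"] == "figure1.png"

    def test_state_island_carries_views_and_clash_payload(self, clash_pair):
        doc = build_variant_page(clash_pair, [parse_variant("A2T")],
                                 chain="A")
        page = render_page(doc)
        m = re.search(r'id="molpage-state">(.*?)</script>', page, re.DOTALL)
        state = json.loads(m.group(1))
        assert state["viewOrder"] == ["overview", "variant-1"]
        reps = state["views"]["variant-1"]["representations"]
        spiky = [r for r in reps if r["kind"] == "spiky-ball"]
        assert len(spiky) == 1
        assert len(spiky[0]["atom_radii"]) == 2
        for _idx, radius in spiky[0]["atom_radii"]:
            assert radius == pytest.approx(1.0, abs=1e-6)


class TestPageDocumentJSON:
    def test_loads_and_renders(self, helix12):
        data = {
            "title": "doc",
            "body_markdown": "plain **text**",
            "initial_view": "main",
            "viewspecs": [{
                "id": "main",
                "structures": [{"id": "helix",
                                "pdb_text": write_pdb(helix12)}],
                "representations": [{"kind": "cartoon",
                                     "selection": "all",
                                     "color": "red"}],
            }],
        }
        doc = load_page_document(data)
        page = render_page(doc)
        assert embedded_structures(page)["helix"] == helix12

    def test_schema_rejects_bad_document(self):
        import jsonschema
        with pytest.raises(jsonschema.ValidationError):
            load_page_document({"title": "x"})
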