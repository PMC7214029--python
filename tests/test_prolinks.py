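"""Prolink parsing, canonical serialization, and pure application."""

import math
import random

import pytest

from molpage.page_builder import prolink_anchors
from molpage.prolinks import (PROLINK_KEYS, ProlinkAction, ProlinkError,
                              apply_prolink, parse_prolink,
                              prolink_attributes, render_prolink)
from molpage.selection_lang import (And, Chain, Resi, parse_selection,
                                    print_selection)
from molpage.session_import import import_manifest
from molpage.view_model import Representation, ViewSpec, ColorScheme
from molpage import fixtures as fx
from oracles import oracle_clashes, random_ast


def random_action(rng, structure) -> ProlinkAction:
    kwargs = {}
    if rng.random() < 0.3:
        kwargs["load"] = rng.choice(["main", "variant-1", "overview"])
    if rng.random() < 0.3:
        # a valid view: z-axis rotation, camera on the axis
        theta = rng.uniform(0, 6.28)
        c, s = round(math.cos(theta), 6), round(math.sin(theta), 6)
        zoom = round(rng.uniform(5, 100), 3)
        kwargs["view"] = (c, s, 0.0, -s, c, 0.0, 0.0, 0.0, 1.0,
                          0.0, 0.0, -zoom,
                          round(rng.uniform(-20, 20), 3),
                          round(rng.uniform(-20, 20), 3),
                          round(rng.uniform(-20, 20), 3),
                          zoom - 10, zoom + 10, 1.0)
    if rng.random() < 0.5:
        kwargs["focus"] = random_ast(rng, structure, depth=2)
    if rng.random() < 0.3:
        kwargs["focus_radius"] = round(rng.uniform(2, 10), 2)
    if rng.random() < 0.4:
        kwargs["show"] = tuple(
            (rng.choice(["cartoon", "ball+stick", "surface", "line"]),
             random_ast(rng, structure, depth=1))
            for _ in range(rng.randint(1, 2)))
    if rng.random() < 0.3:
        kwargs["hide"] = (random_ast(rng, structure, depth=1),)
    if rng.random() < 0.3:
        kwargs["color_ops"] = ((random_ast(rng, structure, depth=1),
                                f"{rng.randrange(16**6):06X}"),)
    if rng.random() < 0.3:
        kwargs["chains_visible"] = tuple(
            sorted(set(rng.choices(["A", "B"], k=rng.randint(1, 2)))))
    if rng.random() < 0.2:
        kwargs["clash"] = random_ast(rng, structure, depth=1)
    if rng.random() < 0.5 or not kwargs:
        kwargs["label"] = rng.choice(["wt", "R45C <mark>", "see & zoom"])
    return ProlinkAction(**kwargs)


class TestParse:
    def test_focus_with_radius(self):
        a = parse_prolink({"data-focus": "chain A and resi 123",
                           "data-radius": "5"})
        assert a.focus == And(Chain(("A",)), Resi(((123, 123),)))
        assert a.focus_radius == 5.0

    def test_chains_and_clash_vocabulary(self):
        a = parse_prolink({"data-chains": "A,B"})
        assert a.chains_visible == ("A", "B")
        a = parse_prolink({"data-clash": "resi 45"})
        assert a.clash == Resi(((45, 45),))

    def test_empty_and_unknown_keys(self):
        with pytest.raises(ProlinkError, match="empty prolink"):
            parse_prolink({})
        with pytest.raises(ProlinkError, match="data-zoom"):
            parse_prolink({"data-zoom": "5", "data-wiggle": "yes"})

    def test_malformed_float_list(self):
        with pytest.raises(ProlinkError, match="float"):
            parse_prolink({"data-view": "1,2,three"})
        with pytest.raises(ProlinkError, match="18"):
            parse_prolink({"data-view": "1,2,3"})


class TestRender:
    def test_label_only_anchor(self):
        out = render_prolink(ProlinkAction(label="x"), "text")
        assert out == ('<a href="#" class="prolink" data-label="x">'
                       "text</a>")

    def test_text_is_entity_escaped(self):
        out = render_prolink(ProlinkAction(label="x"), "a < b & c")
        assert "a &lt; b &amp; c" in out

    def test_canonical_attribute_order(self, dimer):
        rng = random.Random(8)
        for _ in range(20):
            a = random_action(rng, dimer)
            keys = list(prolink_attributes(a))
            assert keys == [k for k in PROLINK_KEYS if k in keys]

    def test_parse_render_round_trip_200_seeded(self, dimer):
        rng = random.Random(314159)
        for _ in range(200):
            action = random_action(rng, dimer)
            anchor = render_prolink(action, "link")
            attrs_list = prolink_anchors(anchor)
            assert len(attrs_list) == 1
            assert parse_prolink(attrs_list[0]) == action


@pytest.fixture()
def two_chain_spec(dimer):
    reps = (Representation(kind="cartoon",
                           selection=parse_selection("chain A"),
                           object_id="dimer"),
            Representation(kind="cartoon",
                           selection=parse_selection("chain B"),
                           object_id="dimer"))
    return ViewSpec(structures=((dimer, True),), representations=reps)


def spec_fingerprint(spec):
    from molpage.page_builder import _serialize_viewspec
    import json
    return json.dumps(_serialize_viewspec(spec), sort_keys=True)


class TestApply:
    def test_label_only_is_identity(self, two_chain_spec):
        out = apply_prolink(ProlinkAction(label="x"), two_chain_spec)
        assert spec_fingerprint(out) == spec_fingerprint(two_chain_spec)

    def test_chains_visible_hides_other_chain(self, two_chain_spec):
        out = apply_prolink(ProlinkAction(chains_visible=("A",)),
                            two_chain_spec)
        reps = out.representations
        assert reps[0].visible and not reps[1].visible

    def test_load_switches_visible_structure(self, manifest):
        spec = import_manifest(manifest)
        out = apply_prolink(ProlinkAction(load="pocket"), spec)
        visible = {s.id: vis for s, vis in out.structures}
        assert visible == {"helix": False, "pocket": True}
        with pytest.raises(ProlinkError, match="ghost"):
            apply_prolink(ProlinkAction(load="ghost"), spec)

    def test_clash_action_appends_spiky_ball_with_oracle_atoms(
            self, clash_pair):
        spec = ViewSpec(structures=((clash_pair, True),))
        action = ProlinkAction(clash=parse_selection("all"))
        out = apply_prolink(action, spec)
        spiky = [r for r in out.representations if r.kind == "spiky-ball"]
        assert len(spiky) == 1
        oracle = oracle_clashes(clash_pair,
                                set(range(len(clash_pair.atoms))))
        oracle_atoms = {i for pair in oracle for i in pair}
        from molpage.selection_lang import evaluate_selection
        assert evaluate_selection(spiky[0].selection, clash_pair) == \
            oracle_atoms
        assert len(oracle_atoms) == 2

    def test_apply_never_mutates_input(self, two_chain_spec, dimer):
        before = spec_fingerprint(two_chain_spec)
        rng = random.Random(2718)
        for _ in range(30):
            action = random_action(rng, dimer)
            try:
                apply_prolink(action, two_chain_spec)
            except ProlinkError:
                pass  # random load ids may not resolve
            assert spec_fingerprint(two_chain_spec) == before

    def test_visibility_actions_idempotent(self, two_chain_spec):
        for action in (ProlinkAction(chains_visible=("A",)),
                       ProlinkAction(hide=(parse_selection("chain B"),)),
                       ProlinkAction(show=(("surface",
                                            parse_selection("all")),))):
            once = apply_prolink(action, two_chain_spec)
            twice = apply_prolink(action, once)
            assert spec_fingerprint(once) == spec_fingerprint(twice)
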