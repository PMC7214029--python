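"""Steric-clash detection vs the all-pairs oracle."""

import math
import random

import numpy as np
import pytest

from molpage.clash_detect import clash_representation, find_clashes
from molpage.config import Config
from molpage.selection_lang import All, NoneSel, evaluate_selection
from molpage.structure_io import Atom, Structure, infer_bonds
from oracles import oracle_clashes


def two_carbons(d):
    return Structure(atoms=(
        Atom(1, "C1", "C", "", "AAA", "A", 1, "", 0, 0, 0),
        Atom(2, "C2", "C", "", "BBB", "A", 2, "", d, 0, 0)))


def random_structure(rng, n):
    elements = ["C", "C", "C", "N", "O", "S", "P", "H"]
    box = max(8.0, (n ** (1 / 3)) * 3.0)
    atoms = []
    for i in range(n):
        res = i // 4 + 1
        atoms.append(Atom(i + 1, f"X{i % 4}{res}", rng.choice(elements), "",
                          "UNK", rng.choice("AB"), res, "",
                          round(rng.uniform(0, box), 3),
                          round(rng.uniform(0, box), 3),
                          round(rng.uniform(0, box), 3)))
    return Structure(atoms=tuple(atoms))


def as_pairs(clashes):
    return {(c.i, c.j): c.overlap for c in clashes}


def test_nonbonded_pair_arithmetic():
    clashes = find_clashes(two_carbons(2.4), All(), 0.4)
    assert len(clashes) == 1
    assert clashes[0].overlap == pytest.approx(1.70 + 1.70 - 2.4)
    assert find_clashes(two_carbons(3.5), All(), 0.4) == []


def test_clash_pair_fixture_exact(clash_pair):
    clashes = find_clashes(clash_pair, All(), 0.4)
    assert len(clashes) == 1
    assert clashes[0].overlap == pytest.approx(1.0, abs=1e-6)
    assert find_clashes(clash_pair, All(), 1.5) == []


def test_helix_self_clash_free(helix12):
    assert find_clashes(helix12, All(), 0.4) == []


def test_removing_probe_removes_clash(clash_pair):
    trimmed = Structure(atoms=tuple(a for a in clash_pair.atoms
                                    if a.resname != "PRB"))
    assert find_clashes(trimmed, All(), 0.4) == []
    oracle = oracle_clashes(trimmed, set(range(len(trimmed.atoms))))
    assert oracle == {}


def test_grid_equals_oracle_on_50_random_structures():
    rng = random.Random(987654)
    for _ in range(50):
        n = rng.randint(20, 500)
        s = random_structure(rng, n)
        got = as_pairs(find_clashes(s, All(), 0.4))
        want = oracle_clashes(s, set(range(n)))
        assert set(got) == set(want)
        for pair, overlap in want.items():
            assert got[pair] == pytest.approx(overlap, abs=1e-9)


def test_selection_restricts_pairs():
    rng = random.Random(5150)
    from molpage.selection_lang import Chain
    for _ in range(10):
        s = random_structure(rng, 120)
        sel = Chain(("A",))
        selected = evaluate_selection(sel, s)
        got = as_pairs(find_clashes(s, sel, 0.4))
        want = oracle_clashes(s, selected)
        assert set(got) == set(want)


def test_each_unordered_pair_reported_once():
    rng = random.Random(31)
    s = random_structure(rng, 200)
    clashes = find_clashes(s, All(), 0.4)
    pairs = [(c.i, c.j) for c in clashes]
    assert len(pairs) == len(set(pairs))
    assert all(i < j for i, j in pairs)


def test_sorted_by_descending_overlap():
    rng = random.Random(42)
    s = random_structure(rng, 300)
    overlaps = [c.overlap for c in find_clashes(s, All(), 0.4)]
    assert overlaps == sorted(overlaps, reverse=True)


def test_cutoff_monotonicity():
    rng = random.Random(1001)
    s = random_structure(rng, 250)
    low = {(c.i, c.j) for c in find_clashes(s, All(), 0.2)}
    mid = {(c.i, c.j) for c in find_clashes(s, All(), 0.4)}
    high = {(c.i, c.j) for c in find_clashes(s, All(), 0.8)}
    assert high <= mid <= low


def test_rigid_motion_invariance():
    rng = random.Random(777)
    s = random_structure(rng, 150)
    theta = math.radians(37.0)
    R = np.array([[math.cos(theta), -math.sin(theta), 0],
                  [math.sin(theta), math.cos(theta), 0],
                  [0, 0, 1]])
    shift = np.array([11.0, -7.0, 3.0])
    moved_atoms = []
    for a, xyz in zip(s.atoms, (s.coords() @ R.T) + shift):
        moved_atoms.append(Atom(a.serial, a.name, a.element, a.altloc,
                                a.resname, a.chain, a.resseq, a.icode,
                                float(xyz[0]), float(xyz[1]), float(xyz[2]),
                                a.occupancy, a.bfactor, a.hetero))
    moved = Structure(atoms=tuple(moved_atoms))
    orig = as_pairs(find_clashes(s, All(), 0.4))
    after = as_pairs(find_clashes(moved, All(), 0.4))
    assert set(orig) == set(after)
    for pair in orig:
        assert after[pair] == pytest.approx(orig[pair], abs=1e-9)


def test_hydrogen_pairs_flag():
    s = Structure(atoms=(
        Atom(1, "H1", "H", "", "AAA", "A", 1, "", 0, 0, 0),
        Atom(2, "C2", "C", "", "BBB", "A", 2, "", 2.0, 0, 0)))
    assert find_clashes(s, All(), 0.4) == []
    cfg = Config(include_hydrogen_clashes=True)
    clashes = find_clashes(s, All(), 0.4, config=cfg)
    assert len(clashes) == 1
    assert clashes[0].overlap == pytest.approx(1.20 + 1.70 - 2.0)


def test_bonded_and_one_three_pairs_excluded():
    # linear chain a-b-c with a..c close enough to overlap
    atoms = (Atom(1, "C1", "C", "", "AAA", "A", 1, "", 0.0, 0, 0),
             Atom(2, "C2", "C", "", "BBB", "A", 2, "", 1.5, 0, 0),
             Atom(3, "C3", "C", "", "CCC", "A", 3, "", 3.0, 0, 0))
    s = Structure(atoms=atoms)
    bonds = infer_bonds(s)
    assert (0, 1) in bonds and (1, 2) in bonds
    assert find_clashes(s, All(), 0.1, bonds) == []


class TestClashRepresentation:
    def test_empty_list_gives_none_selection(self, helix12):
        rep = clash_representation([], helix12)
        assert rep.kind == "spiky-ball"
        assert rep.selection == NoneSel()
        assert evaluate_selection(rep.selection, helix12) == set()

    def test_single_clash_selects_two_atoms(self, clash_pair):
        clashes = find_clashes(clash_pair, All(), 0.4)
        rep = clash_representation(clashes, clash_pair)
        selected = evaluate_selection(rep.selection, clash_pair)
        assert selected == {clashes[0].i, clashes[0].j}
        radii = dict(rep.atom_radii)
        assert radii[clashes[0].i] == pytest.approx(1.0, abs=1e-6)
        assert radii[clashes[0].j] == pytest.approx(1.0, abs=1e-6)
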