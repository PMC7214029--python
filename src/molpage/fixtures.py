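"""Deterministic synthetic structures and manifests for tests and docs.

Everything here is closed-form, idealized geometry — no downloads, no
randomness — so every numeric check against these structures can be
derived on paper.  The helix follows ideal α-helical parameters (1.5 Å
rise and 100° twist per residue, CA on a 2.3 Å-radius cylinder); the
remaining atoms sit at fixed offsets in each residue's local cylindrical
frame (radial u, tangential t, axial k), chosen so that the distance
rule of :func:`~molpage.structure_io.infer_bonds` recovers the expected
connectivity (N–CA, CA–C, C–O, CA–CB within each residue plus the
peptide C(i)–N(i+1) link) and the helix is free of steric clashes at
the default cutoff.  The geometry is a test substrate with correct
topology, not a chemically exact backbone.
"""

from __future__ import annotations

import math

from .structure_io import Atom, Structure

RISE = 1.5          # Å per residue
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3     # Å

# Per-atom offsets in the residue's local frame: (radial, tangential, axial).
BACKBONE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "N": (-0.35, -1.25, -0.65),
    "CA": (0.0, 0.0, 0.0),
    "C": (-0.30, 1.25, 0.70),
    "O": (0.75, 1.25, 1.35),    # relative to CA; radially out from C
    "CB": (1.35, 0.0, -0.70),
}
ATOM_ORDER = ("N", "CA", "C", "O", "CB")
ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _helix_atom_xyz(res_index: int, atom: str) -> tuple[float, float, float]:
    """Coordinates of one helix atom; res_index is 0-based."""
    theta = math.radians(res_index * TWIST)
    u = (math.cos(theta), math.sin(theta), 0.0)
    t = (-math.sin(theta), math.cos(theta), 0.0)
    du, dt, dk = BACKBONE_OFFSETS[atom]
    x = (CA_RADIUS + du) * u[0] + dt * t[0]
    y = (CA_RADIUS + du) * u[1] + dt * t[1]
    z = res_index * RISE + dk
    return (round(x, 3), round(y, 3), round(z, 3))


def make_helix(n_res: int, chain: str = "A", id: str = "helix",
               start_resseq: int = 1) -> Structure:
    """Ideal polyalanine α-helix: N/CA/C/O/CB per residue, chain A."""
    if n_res < 2:
        raise ValueError("a helix needs at least 2 residues")
    atoms = []
    serial = 1
    for i in range(n_res):
        for name in ATOM_ORDER:
            x, y, z = _helix_atom_xyz(i, name)
            atoms.append(Atom(serial=serial, name=name,
                              element=ELEMENTS[name], altloc="",
                              resname="ALA", chain=chain,
                              resseq=start_resseq + i, icode="",
                              x=x, y=y, z=z, occupancy=1.0, bfactor=0.0,
                              hetero=False))
            serial += 1
    return Structure(atoms=tuple(atoms), id=id)


def make_dimer(id: str = "dimer") -> Structure:
    """Two 8-residue helices as chains A and B, B translated 20 Å in x."""
    a = make_helix(8, chain="A")
    atoms = list(a.atoms)
    serial = len(atoms) + 1
    for atom in a.atoms:
        atoms.append(Atom(serial=serial, name=atom.name,
                          element=atom.element, altloc="",
                          resname=atom.resname, chain="B",
                          resseq=atom.resseq, icode="",
                          x=round(atom.x + 20.0, 3), y=atom.y, z=atom.z,
                          occupancy=1.0, bfactor=0.0, hetero=False))
        serial += 1
    return Structure(atoms=tuple(atoms), id=id)


def make_clash_pair(id: str = "clashpair") -> Structure:
    """4-residue helix plus one hetero carbon 2.4 Å from residue 2's CB.

    The probe sits roughly radially outward from the CB, ≥3.6 Å from
    every other atom, so default settings yield exactly one clash of
    overlap 1.70 + 1.70 − 2.40 = 1.00 Å.  The offset (−0.672, 2.304, 0)
    is a scaled 7-24-25 Pythagorean pair: its norm is exactly 2.4 even
    in 3-decimal PDB coordinates, so the overlap is exact too.
    """
    helix = make_helix(4)
    cb = next(a for a in helix.atoms if a.resseq == 2 and a.name == "CB")
    probe = Atom(serial=len(helix.atoms) + 1, name="C1", element="C",
                 altloc="", resname="PRB", chain="A", resseq=90, icode="",
                 x=round(cb.x - 0.672, 3),
                 y=round(cb.y + 2.304, 3),
                 z=cb.z, occupancy=1.0, bfactor=0.0, hetero=True)
    return Structure(atoms=helix.atoms + (probe,), id=id)


def make_pocket(id: str = "pocket") -> Structure:
    """12-residue helix plus a 3-atom LIG hetero group near residues 5–7.

    Each LIG atom lies 4 Å radially outward from one of the CB atoms of
    residues 5, 6 and 7 and more than 5 Å from every atom of every other
    residue, so a 5 Å by-residue neighborhood of LIG is exactly {5,6,7}.
    """
    helix = make_helix(12)
    atoms = list(helix.atoms)
    serial = len(atoms) + 1
    for k, res in enumerate((5, 6, 7), start=1):
        cb = next(a for a in helix.atoms
                  if a.resseq == res and a.name == "CB")
        theta = math.radians((res - 1) * TWIST)
        u = (math.cos(theta), math.sin(theta), 0.0)
        atoms.append(Atom(serial=serial, name=f"C{k}", element="C",
                          altloc="", resname="LIG", chain="A", resseq=100,
                          icode="",
                          x=round(cb.x + 4.0 * u[0], 3),
                          y=round(cb.y + 4.0 * u[1], 3),
                          z=cb.z, occupancy=1.0, bfactor=0.0, hetero=True))
        serial += 1
    return Structure(atoms=tuple(atoms), id=id)


def make_session_manifest() -> dict:
    """Two-object, four-representation manifest with a non-identity view."""
    from .structure_io import write_pdb

    helix = make_helix(12)
    pocket = make_pocket()
    c, s = math.cos(math.radians(30)), math.sin(math.radians(30))
    view = [c, s, 0.0, -s, c, 0.0, 0.0, 0.0, 1.0,   # rotation (about z)
            0.0, 0.0, -40.0,                        # camera position
            0.0, 0.0, 8.0,                          # rotation origin
            30.0, 50.0, 1.0]                        # slabs, orthoscopic
    return {
        "schema": 1,
        "objects": [
            {"id": "helix", "pdb_text": write_pdb(helix), "visible": True},
            {"id": "pocket", "pdb_text": write_pdb(pocket), "visible": True},
        ],
        "reps": [
            {"object_id": "helix", "kind": "cartoon", "selection": "all",
             "color": "red", "opacity": 1.0},
            {"object_id": "helix", "kind": "ball+stick",
             "selection": "resi 2-4",
             "color": [{"selection": "name CA", "color": "yellow"},
                       {"selection": "not name CA", "color": "cyan"}],
             "opacity": 1.0},
            {"object_id": "pocket", "kind": "surface",
             "selection": "polymer", "color": "wheat", "opacity": 0.5},
            {"object_id": "pocket", "kind": "line", "selection": "hetatm",
             "color": 4, "opacity": 1.0},
        ],
        "view": view,
        "background": "white",
    }
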