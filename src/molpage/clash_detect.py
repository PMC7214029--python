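"""Steric-clash detection for spiky-ball visualization.

A clash is an atom pair whose van der Waals spheres overlap by more
than a cutoff: ``overlap = r_vdw(i) + r_vdw(j) − d > cutoff`` (default
0.4 Å, a common steric-clash convention).  Pairs that are covalently
bonded (1-2), share a bonded neighbor (1-3) or belong to the same
residue are excluded — those contacts are chemistry, not strain.  Pairs
involving hydrogen are reported only when the config flag asks for
them.

The search runs on a KD-tree capped at the largest possible clashing
distance, which is exactly equivalent to the quadratic all-pairs rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULT_CONFIG
from .selection_lang import (And, Chain, Name, NoneSel, Resi, SelectionAST,
                             evaluate_selection, _or_fold)
from .structure_io import BondSet, Structure
from .view_model import ColorScheme, Representation

log = logging.getLogger("molpage")

# van der Waals radii (Å), Bondi-style.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.capitalize(), DEFAULT_VDW_RADIUS)


@dataclass(frozen=True)
class Clash:
    """One overlapping pair; ``overlap = r_i + r_j − distance``."""

    i: int
    j: int
    distance: float
    overlap: float

    def to_json(self) -> dict:
        return {"i": self.i, "j": self.j,
                "distance": round(self.distance, 3),
                "overlap": round(self.overlap, 3)}


def find_clashes(s: Structure, sel: SelectionAST, cutoff: float | None = None,
                 bonds: BondSet | None = None,
                 config: Config = DEFAULT_CONFIG) -> list[Clash]:
    """All clashes between atoms of ``sel`` and any atom of ``s``.

    Each unordered pair is reported once with ``i < j``, sorted by
    descending overlap (ties by index).  ``bonds`` should come from
    :func:`~molpage.structure_io.infer_bonds`; it drives the 1-2 and
    1-3 exclusions.
    """
    if cutoff is None:
        cutoff = config.clash_cutoff
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if bonds is None:
        from .structure_io import infer_bonds
        bonds = infer_bonds(s, config=config)
    selected = evaluate_selection(sel, s)
    if not selected:
        return []
    n = len(s.atoms)
    adj = bonds.neighbors(n)
    radii = np.array([vdw_radius(a.element) for a in s.atoms])
    coords = s.coords()
    # overlap > cutoff requires d < r_i + r_j - cutoff <= 2*max_r - cutoff;
    # epsilon keeps the tree prefilter from dropping boundary-exact pairs
    max_d = 2 * float(radii.max()) - cutoff + 1e-9
    clashes: list[Clash] = []
    if max_d > 0 and n >= 2:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(max_d):
            if i not in selected and j not in selected:
                continue
            a, b = s.atoms[i], s.atoms[j]
            if not config.include_hydrogen_clashes and (
                    a.element.upper() == "H" or b.element.upper() == "H"):
                continue
            if a.residue_key() == b.residue_key():
                continue
            if (i, j) in bonds:
                continue
            if adj[i] & adj[j]:  # 1-3: shared bonded neighbor
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            overlap = float(radii[i] + radii[j] - d)
            if overlap > cutoff:
                clashes.append(Clash(min(i, j), max(i, j), d, overlap))
    clashes.sort(key=lambda c: (-c.overlap, c.i, c.j))
    return clashes


def clash_representation(clashes: list[Clash],
                         s: Structure) -> Representation:
    """Spiky-ball representation covering exactly the clashing atoms.

    Per-atom radius metadata carries each atom's largest overlap, which
    drives the spike size in the page runtime.  An empty clash list
    yields a renderable no-op (``none`` selection).
    """
    if not clashes:
        return Representation(kind="spiky-ball", selection=NoneSel(),
                              color=ColorScheme(uniform="FF0000"))
    worst: dict[int, float] = {}
    for c in clashes:
        worst[c.i] = max(worst.get(c.i, 0.0), c.overlap)
        worst[c.j] = max(worst.get(c.j, 0.0), c.overlap)
    parts: list[SelectionAST] = []
    for i in sorted(worst):
        a = s.atoms[i]
        parts.append(And(Chain((a.chain,)),
                         And(Resi(((a.resseq, a.resseq),)),
                             Name((a.name.upper(),)))))
    return Representation(
        kind="spiky-ball",
        selection=_or_fold(parts),
        color=ColorScheme(uniform="FF0000"),
        atom_radii=tuple((i, round(worst[i], 6)) for i in sorted(worst)),
    )
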