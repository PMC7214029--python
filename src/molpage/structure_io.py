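"""Fixed-column PDB parsing/writing and covalent-bond inference.

The in-memory model is deliberately flat: a :class:`Structure` is an
ordered list of :class:`Atom` records exactly as they appeared in the
file (first MODEL only, one altloc per atom name).  No renumbering is
ever performed — residue numbers are the author's numbering, which is
what variant positions are matched against.

Bond inference uses a distance rule over a fixed covalent-radius table;
bonds feed the 1-2/1-3 exclusions of clash detection, so plain PDB files
without CONECT records work everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULT_CONFIG

log = logging.getLogger("molpage")

# Covalent radii (Å) used by the bond-distance rule.
COVALENT_RADII = {
    "C": 0.77,
    "N": 0.75,
    "O": 0.73,
    "S": 1.02,
    "H": 0.37,
    "P": 1.06,
}
DEFAULT_COVALENT_RADIUS = 0.77

# 20 standard amino acids — used for element inference ("CA" is carbon in
# a standard residue, calcium in a monoatomic HETATM).
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class PDBError(ValueError):
    """Raised for malformed or empty PDB input and unwritable structures."""


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record.  Coordinates in Å, resseq as printed."""

    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    hetero: bool = False

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


@dataclass(frozen=True)
class Structure:
    """Ordered atom list plus a model identifier."""

    atoms: tuple[Atom, ...]
    id: str = "model"

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue keys (chain, resseq, icode) in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key())
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int, str], list[int]]:
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key(), []).append(i)
        return out


@dataclass(frozen=True)
class BondSet:
    """Unordered bonded atom-index pairs, stored as (i, j) with i < j."""

    pairs: frozenset[tuple[int, int]]

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def neighbors(self, n_atoms: int) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(n_atoms)]
        for i, j in self.pairs:
            adj[i].add(j)
            adj[j].add(i)
        return adj


# ---------------------------------------------------------------------------
# hybrid-36 residue numbers (used only beyond 9999 when enabled)

_H36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _hy36_encode_resseq(num: int) -> str:
    if num < 10000:
        return f"{num:4d}"
    if num < 10000 + 26 * 36**3:
        n = num - 10000 + 10 * 36**3  # leading digit runs A..Z
        digits = ""
        for _ in range(4):
            n, r = divmod(n, 36)
            digits = _H36[r] + digits
        return digits
    raise PDBError(f"residue number {num} exceeds hybrid-36 range")


def _hy36_decode_resseq(text: str) -> int:
    s = text.strip()
    if not s:
        raise ValueError("empty residue number")
    if s.lstrip("-").isdigit():
        return int(s)
    if len(s) == 4 and s[0].isalpha() and s[0].isupper():
        val = 0
        for ch in s:
            val = val * 36 + _H36.index(ch.upper())
        return val - 10 * 36**3 + 10000
    raise ValueError(f"unparseable residue number {text!r}")


# ---------------------------------------------------------------------------
# parsing

def _infer_element(name: str, resname: str, hetero: bool) -> str:
    """Element from the atom name when columns 77-78 are blank.

    Standard-residue names start with the element's one-letter symbol once
    digits are stripped ("1HG1" → H, "CA" → C).  In a HETATM outside the
    standard residues, a two-letter name like "CA" or "FE" is taken as the
    two-letter element (calcium, iron).
    """
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return ""
    if hetero and resname not in STANDARD_AA and len(stripped) >= 2:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise PDBError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None
    if not math.isfinite(value):
        raise PDBError(f"line {lineno}: non-finite {what}")
    return value


def parse_pdb(text: str, id: str = "model") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Only the first MODEL is read (later conformers are dropped with a
    warning); per atom name the highest-occupancy altloc is kept, first
    seen winning ties.  Raises :class:`PDBError` on zero coordinate
    records or malformed numeric fields (naming the line).
    """
    atoms: list[Atom] = []
    seen_endmdl = False
    dropped_models = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n ")
        record = line[:6].strip().upper()
        if record == "ENDMDL":
            seen_endmdl = True
            continue
        if record not in ("ATOM", "HETATM"):
            continue
        if seen_endmdl:
            dropped_models = True
            continue
        line = line.ljust(80)
        serial = int(line[6:11]) if line[6:11].strip() else len(atoms) + 1
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        try:
            resseq = _hy36_decode_resseq(line[22:26])
        except ValueError as exc:
            raise PDBError(f"line {lineno}: {exc}") from None
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        occ = line[54:60].strip()
        occupancy = _parse_float(occ, "occupancy", lineno) if occ else 1.0
        bf = line[60:66].strip()
        bfactor = _parse_float(bf, "B-factor", lineno) if bf else 0.0
        hetero = record == "HETATM"
        element = line[76:78].strip().capitalize()
        if not element:
            element = _infer_element(name, resname, hetero)
        atoms.append(Atom(serial, name, element, altloc, resname, chain,
                          resseq, icode, x, y, z, occupancy, bfactor, hetero))
    if dropped_models:
        log.warning("multi-model input: keeping first MODEL only")
    if not atoms:
        raise PDBError("empty structure: no ATOM/HETATM records found")
    return Structure(atoms=tuple(_prune_altlocs(atoms)), id=id)


def _prune_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom site (ties: first seen)."""
    best: dict[tuple, int] = {}
    for idx, a in enumerate(atoms):
        key = (a.chain, a.resseq, a.icode, a.resname, a.name)
        if key not in best:
            best[key] = idx
        elif a.occupancy > atoms[best[key]].occupancy:
            best[key] = idx
    keep = sorted(best.values())
    kept = [atoms[i] for i in keep]
    # A surviving lone altloc label is preserved as read.
    return kept


# ---------------------------------------------------------------------------
# writing

def _format_name(name: str, element: str) -> str:
    # Columns 13-16: one/two-letter elements align differently by convention.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(s: Structure, config: Config = DEFAULT_CONFIG) -> str:
    """Write fixed-column PDB text; ``parse_pdb(write_pdb(s))`` is identity.

    Residue numbers above 9999 raise unless ``config.hybrid36`` is set,
    in which case they are encoded in hybrid-36.  Chain ids longer than
    one character do not fit the dialect and raise.
    """
    lines = []
    for a in s.atoms:
        if len(a.chain) > 1:
            raise PDBError(f"chain id {a.chain!r} longer than one character")
        if a.resseq > 9999 or a.resseq < -999:
            if not config.hybrid36:
                raise PDBError(
                    f"residue number {a.resseq} overflows 4 columns "
                    "(enable hybrid36 to encode it)"
                )
            resseq = _hy36_encode_resseq(a.resseq)
        else:
            resseq = f"{a.resseq:4d}"
        record = "HETATM" if a.hetero else "ATOM  "
        lines.append(
            f"{record}{a.serial:5d} {_format_name(a.name, a.element)}"
            f"{a.altloc or ' '}{a.resname:>3s} {a.chain or ' '}{resseq}"
            f"{a.icode or ' '}   {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bond inference

def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.capitalize()]
    except KeyError:
        log.warning("unknown element %r: using default covalent radius",
                    element)
        return DEFAULT_COVALENT_RADIUS


def infer_bonds(s: Structure, slack: float | None = None,
                config: Config = DEFAULT_CONFIG) -> BondSet:
    """Distance-rule bonds: d(i,j) ≤ r_cov(i) + r_cov(j) + slack.

    Implemented with a KD-tree neighbor query capped at the largest
    possible bonded distance, then filtered per pair by the element
    radii; exactly equivalent to the all-pairs rule.
    """
    if slack is None:
        slack = config.bond_slack
    if slack < 0:
        raise ValueError("slack must be >= 0")
    n = len(s.atoms)
    if n < 2:
        return BondSet(frozenset())
    radii = np.array([covalent_radius(a.element) for a in s.atoms])
    tree = cKDTree(s.coords())
    # tiny epsilon: the tree prefilter must never drop a boundary-exact
    # pair that the per-pair rule below would accept
    max_d = 2 * radii.max() + slack + 1e-9
    pairs = set()
    coords = s.coords()
    for i, j in tree.query_pairs(max_d):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= radii[i] + radii[j] + slack:
            pairs.add((min(i, j), max(i, j)))
    return BondSet(frozenset(pairs))
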