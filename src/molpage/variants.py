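"""Point-mutation parsing, structure mapping, and the combined
variant page.

Variants arrive as ``A123T`` (one-letter) or ``p.Ala123Thr``
(three-letter) strings, one per line in list files (``#`` comments
allowed).  Positions are matched directly against the author numbering
of the PDB file — no alignment-based renumbering — so the wild-type
residue check is the safety net: a variant whose stated reference amino
acid disagrees with the residue found at that position fails loudly,
which is how numbering offsets are caught.

:func:`build_variant_page` produces one focused view per mappable
variant (residue highlighted, 5 Å neighborhood in ball+stick, steric
clashes of the residue as spiky balls) plus an overview with all variant
positions colored on the cartoon, joined into a single page whose
narrative carries one model-switching prolink per variant.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .clash_detect import clash_representation, find_clashes
from .config import Config, DEFAULT_CONFIG
from .prolinks import ProlinkAction, render_prolink
from .selection_lang import (All, And, Around, Chain, Or, Resi,
                             SelectionAST, evaluate_selection)
from .structure_io import Structure, infer_bonds
from .view_model import (CameraState18, ColorScheme, Representation,
                         ViewSpec, camera_to_orientation)

log = logging.getLogger("molpage")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


class VariantError(ValueError):
    """Unparseable variant, wild-type mismatch, or zero mappable variants."""


@dataclass(frozen=True)
class VariantSpec:
    """One point mutation in three-letter normalized form."""

    from_aa: str
    position: int
    to_aa: str
    chain: str | None = None

    @property
    def short(self) -> str:
        return (f"{AA_3TO1[self.from_aa]}{self.position}"
                f"{AA_3TO1[self.to_aa]}")

    def __str__(self) -> str:
        return self.short


_VARIANT_RE = re.compile(
    r"^\s*(?:p\.)?\s*([A-Za-z]{1,3})\s*(\d+)\s*([A-Za-z]{1,3})\s*$")


def _normalize_aa(code: str) -> str:
    if len(code) == 1:
        try:
            return AA_1TO3[code.upper()]
        except KeyError:
            raise VariantError(
                f"unknown amino-acid letter {code!r}") from None
    code3 = code.upper()
    if code3 not in AA_3TO1:
        raise VariantError(f"unknown amino-acid code {code!r}")
    return code3


def parse_variant(text: str) -> VariantSpec:
    """Parse ``X123Y`` / ``p.Xaa123Yaa`` into a :class:`VariantSpec`."""
    m = _VARIANT_RE.match(text)
    if not m:
        raise VariantError(f"unparseable variant {text!r} "
                           "(expected e.g. A123T or p.Ala123Thr)")
    from_aa = _normalize_aa(m.group(1))
    to_aa = _normalize_aa(m.group(3))
    position = int(m.group(2))
    if position < 1:
        raise VariantError(f"variant position must be >= 1 in {text!r}")
    if from_aa == to_aa:
        raise VariantError(f"synonymous variant {text!r}: reference and "
                           "alternate residues are identical")
    return VariantSpec(from_aa=from_aa, position=position, to_aa=to_aa)


def parse_variant_file(path: str | Path) -> list[VariantSpec]:
    """One mutation per line; blank lines and ``#`` comments skipped."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(parse_variant(line))
    return out


def map_variant(v: VariantSpec, s: Structure, chain: str) -> list[int]:
    """Locate the variant residue; returns its atom indices.

    Raises :class:`VariantError` when the position is absent from the
    chain ("not in structure") or when the residue found there is not
    the stated wild type — the guard against numbering offsets.
    """
    if chain not in s.chains():
        raise VariantError(f"chain {chain!r} not present in structure "
                           f"{s.id!r}")
    indices = [i for i, a in enumerate(s.atoms)
               if a.chain == chain and a.resseq == v.position
               and not a.hetero]
    if not indices:
        raise VariantError(
            f"variant {v.short}: position {v.position} not in structure "
            f"(chain {chain})")
    found = s.atoms[indices[0]].resname.upper()
    if found != v.from_aa:
        raise VariantError(
            f"variant {v.short}: wild-type mismatch at {chain}{v.position}: "
            f"found {found} expected {v.from_aa}")
    return indices


def _residue_selection(chain: str, position: int) -> SelectionAST:
    return And(Chain((chain,)), Resi(((position, position),)))


def _frame_residue(s: Structure, sel: SelectionAST,
                   radius: float) -> CameraState18:
    import numpy as np

    atoms = evaluate_selection(sel, s) | evaluate_selection(
        Around(sel, radius, byres=True), s)
    coords = s.coords()[sorted(atoms)]
    centroid = coords.mean(axis=0)
    extent = float(np.linalg.norm(coords - centroid, axis=1).max())
    zoom = max(extent + radius, 5.0)
    return CameraState18(
        rotation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        camera_position=(0.0, 0.0, -zoom),
        rotation_origin=tuple(float(x) for x in centroid),
        slab_near=zoom - 10.0, slab_far=zoom + 10.0, orthoscopic=True)


def build_variant_page(s: Structure, variants: list[VariantSpec],
                       chain: str, title: str | None = None,
                       config: Config = DEFAULT_CONFIG):
    """Combine per-variant views and an overview into one PageDocument.

    Input order is preserved: variant *k* in the list is prolink *k* in
    the page body.  Unmappable variants (absent position or wild-type
    mismatch) do not get views; they are listed in a "Not in structure"
    section with the reason.
    """
    from .page_builder import PageDocument

    if not variants:
        raise VariantError("no variants given")
    bonds = infer_bonds(s, config=config)
    mapped: list[tuple[VariantSpec, SelectionAST]] = []
    unmappable: list[tuple[VariantSpec, str]] = []
    for v in variants:
        try:
            map_variant(v, s, chain)
        except VariantError as exc:
            log.warning("variant %s not mapped: %s", v.short, exc)
            unmappable.append((v, str(exc)))
            continue
        mapped.append((v, _residue_selection(chain, v.position)))
    if not mapped:
        raise VariantError("zero mappable variants: nothing to show")

    viewspecs: list[tuple[str, ViewSpec]] = []
    body_lines: list[str] = []
    overview_sel = None
    for v, sel in mapped:
        overview_sel = sel if overview_sel is None else Or(overview_sel, sel)

    cartoon = Representation(
        kind="cartoon", selection=All(),
        color=ColorScheme(mode="segmented", segments=(
            (All(), "BFBFBF"),
            (overview_sel, config.highlight_color))),
        object_id=s.id)
    overview = ViewSpec(
        structures=((s, True),),
        representations=(cartoon,),
        camera=camera_to_orientation(_frame_overview(s)),
        background=config.background)
    viewspecs.append(("overview", overview))

    for k, (v, sel) in enumerate(mapped, start=1):
        view_id = f"variant-{k}"
        neighborhood = Around(sel, config.focus_radius, byres=True)
        clashes = find_clashes(s, sel, bonds=bonds, config=config)
        reps = [
            Representation(kind="cartoon",
                           selection=cartoon.selection,
                           color=ColorScheme(uniform="BFBFBF"),
                           object_id=s.id),
            Representation(kind="ball+stick", selection=neighborhood,
                           color=ColorScheme(uniform="99CCFF"),
                           object_id=s.id),
            Representation(kind="ball+stick", selection=sel,
                           color=ColorScheme(
                               uniform=config.highlight_color),
                           object_id=s.id),
        ]
        spiky = clash_representation(clashes, s)
        if clashes:
            reps.append(Representation(
                kind="spiky-ball", selection=spiky.selection,
                color=spiky.color, atom_radii=spiky.atom_radii,
                object_id=s.id))
        vs = ViewSpec(structures=((s, True),),
                      representations=tuple(reps),
                      camera=camera_to_orientation(
                          _frame_residue(s, sel, config.focus_radius)),
                      background=config.background)
        viewspecs.append((view_id, vs))
        action = ProlinkAction(load=view_id, focus=sel,
                               focus_radius=config.focus_radius,
                               label=v.short)
        clash_note = (f" — {len(clashes)} steric clash(es)"
                      if clashes else "")
        link_text = f"{v.from_aa}{v.position}{v.to_aa}"
        body_lines.append(
            f"- {render_prolink(action, link_text)}{clash_note}")

    body = [f"# {title or 'Variant views: ' + s.id}", "",
            "Click a variant to focus its residue and 5 Å neighborhood; "
            "spiky balls mark van der Waals overlaps of the wild-type "
            "side chain.", ""]
    body += body_lines
    if unmappable:
        body += ["", "## Not in structure", ""]
        for v, reason in unmappable:
            body.append(f"- {v.short}: {reason}")

    return PageDocument(
        title=title or f"Variants on {s.id}",
        body_markdown="\n".join(body),
        viewspecs=tuple(viewspecs),
        initial_view="overview",
        options={"offline": True, "background": config.background,
                 "spin": False})


def _frame_overview(s: Structure) -> CameraState18:
    import numpy as np

    coords = s.coords()
    centroid = coords.mean(axis=0)
    extent = float(np.linalg.norm(coords - centroid, axis=1).max())
    zoom = max(extent * 2.0, 10.0)
    return CameraState18(
        rotation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        camera_position=(0.0, 0.0, -zoom),
        rotation_origin=tuple(float(x) for x in centroid),
        slab_near=zoom - 10.0, slab_far=zoom + 10.0, orthoscopic=True)
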