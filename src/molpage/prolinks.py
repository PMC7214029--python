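"""Prolinks: hyperlinks that steer the 3D view.

A prolink is an ``<a class="prolink">`` element whose ``data-*``
attributes encode one view-changing action.  The ten-key vocabulary is
this package's normative definition (documented with examples in the
README):

=============  =====================================================
attribute      meaning
=============  =====================================================
data-load      switch the visible model to this structure id
data-view      18 comma-separated floats, desktop ``get_view`` order
data-focus     selection to center and frame
data-radius    focus neighborhood radius in Å (default 5)
data-show      ``kind:selection`` pairs, ``;``-separated, to add
data-hide      selections (``;``-separated) whose reps are retired
data-color     ``#RRGGBB:selection`` pairs, ``;``-separated
data-chains    comma-separated chain ids to leave visible
data-clash     selection around which steric clashes are detected
               and drawn as spiky balls
data-label     free-text note carried on the link
=============  =====================================================

:func:`apply_prolink` implements the same semantics server-side that the
emitted page's runtime performs client-side, as a pure function over
ViewSpecs, so behavior is testable without a browser.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .clash_detect import clash_representation, find_clashes
from .config import Config, DEFAULT_CONFIG
from .selection_lang import (Around, SelectionAST, evaluate_selection,
                             parse_selection, print_selection)
from .structure_io import infer_bonds
from .view_model import (CameraState18, ColorScheme, Representation,
                         ViewSpec, camera_to_orientation, _check_hex,
                         REP_KINDS)

log = logging.getLogger("molpage")

# Canonical attribute order: fixed so rendered pages are byte-stable.
PROLINK_KEYS = ("data-load", "data-view", "data-focus", "data-radius",
                "data-show", "data-hide", "data-color", "data-chains",
                "data-clash", "data-label")


class ProlinkError(ValueError):
    """Malformed prolink attributes or an unresolvable action."""


@dataclass(frozen=True)
class ProlinkAction:
    """Parsed form of one prolink's data-attributes."""

    load: str | None = None
    view: tuple[float, ...] | None = None
    focus: SelectionAST | None = None
    focus_radius: float | None = None
    show: tuple[tuple[str, SelectionAST], ...] = ()
    hide: tuple[SelectionAST, ...] = ()
    color_ops: tuple[tuple[SelectionAST, str], ...] = ()
    chains_visible: tuple[str, ...] | None = None
    clash: SelectionAST | None = None
    label: str | None = None

    def __post_init__(self):
        if not any((self.load, self.view, self.focus,
                    self.focus_radius is not None, self.show, self.hide,
                    self.color_ops, self.chains_visible is not None,
                    self.clash, self.label)):
            raise ProlinkError("empty prolink: no action fields set")
        if self.view is not None and len(self.view) != 18:
            raise ProlinkError(
                f"data-view needs 18 floats, got {len(self.view)}")
        for kind, _sel in self.show:
            if kind not in REP_KINDS:
                raise ProlinkError(f"unknown representation kind {kind!r}")
        for _sel, hexval in self.color_ops:
            _check_hex(hexval)


def _parse_floats(text: str, what: str) -> tuple[float, ...]:
    try:
        return tuple(float(v) for v in text.split(","))
    except ValueError as exc:
        raise ProlinkError(f"malformed float list in {what}: {exc}") from None


def parse_prolink(attrs: dict[str, str]) -> ProlinkAction:
    """Parse a mapping of ``data-*`` attribute → string into an action.

    Unknown ``data-*`` keys raise, listing them; an empty mapping raises
    "empty prolink".
    """
    unknown = sorted(k for k in attrs if k not in PROLINK_KEYS)
    if unknown:
        raise ProlinkError(
            f"unknown prolink attributes: {', '.join(unknown)}")
    if not attrs:
        raise ProlinkError("empty prolink: no data attributes")
    kwargs: dict = {}
    if "data-load" in attrs:
        kwargs["load"] = attrs["data-load"]
    if "data-view" in attrs:
        kwargs["view"] = _parse_floats(attrs["data-view"], "data-view")
    if "data-focus" in attrs:
        kwargs["focus"] = parse_selection(attrs["data-focus"])
    if "data-radius" in attrs:
        try:
            kwargs["focus_radius"] = float(attrs["data-radius"])
        except ValueError:
            raise ProlinkError(
                f"malformed data-radius {attrs['data-radius']!r}") from None
    if "data-show" in attrs:
        show = []
        for item in attrs["data-show"].split(";"):
            kind, _, sel = item.partition(":")
            if not sel:
                raise ProlinkError(f"malformed data-show item {item!r}")
            show.append((kind.strip(), parse_selection(sel)))
        kwargs["show"] = tuple(show)
    if "data-hide" in attrs:
        kwargs["hide"] = tuple(parse_selection(item)
                               for item in attrs["data-hide"].split(";"))
    if "data-color" in attrs:
        ops = []
        for item in attrs["data-color"].split(";"):
            hexval, _, sel = item.partition(":")
            if not sel:
                raise ProlinkError(f"malformed data-color item {item!r}")
            ops.append((parse_selection(sel), _check_hex(hexval.strip())))
        kwargs["color_ops"] = tuple(ops)
    if "data-chains" in attrs:
        kwargs["chains_visible"] = tuple(
            c.strip() for c in attrs["data-chains"].split(",") if c.strip())
    if "data-clash" in attrs:
        kwargs["clash"] = parse_selection(attrs["data-clash"])
    if "data-label" in attrs:
        kwargs["label"] = attrs["data-label"]
    return ProlinkAction(**kwargs)


def prolink_attributes(a: ProlinkAction) -> dict[str, str]:
    """Serialize an action to its data-attributes in canonical key order."""
    out: dict[str, str] = {}
    if a.load is not None:
        out["data-load"] = a.load
    if a.view is not None:
        out["data-view"] = ",".join(repr(v) for v in a.view)
    if a.focus is not None:
        out["data-focus"] = print_selection(a.focus)
    if a.focus_radius is not None:
        out["data-radius"] = repr(float(a.focus_radius))
    if a.show:
        out["data-show"] = ";".join(
            f"{kind}:{print_selection(sel)}" for kind, sel in a.show)
    if a.hide:
        out["data-hide"] = ";".join(print_selection(sel) for sel in a.hide)
    if a.color_ops:
        out["data-color"] = ";".join(
            f"#{hexval}:{print_selection(sel)}" for sel, hexval in a.color_ops)
    if a.chains_visible is not None:
        out["data-chains"] = ",".join(a.chains_visible)
    if a.clash is not None:
        out["data-clash"] = print_selection(a.clash)
    if a.label is not None:
        out["data-label"] = a.label
    return {k: out[k] for k in PROLINK_KEYS if k in out}


def render_prolink(a: ProlinkAction, text: str) -> str:
    """Render the canonical HTML anchor; ``parse_prolink`` inverts it."""
    attrs = prolink_attributes(a)
    attr_text = "".join(
        f' {key}="{html.escape(value, quote=True)}"'
        for key, value in attrs.items())
    return (f'<a href="#" class="prolink"{attr_text}>'
            f"{html.escape(text)}</a>")


# ---------------------------------------------------------------------------
# applying an action to a ViewSpec (the server-side twin of the page runtime)

def _focus_camera(v: ViewSpec, sel: SelectionAST, radius: float,
                  config: Config) -> ViewSpec:
    target = _active_structure(v)
    context = Around(sel, radius, byres=True)
    atoms = evaluate_selection(sel, target) | evaluate_selection(
        context, target)
    if not atoms:
        log.warning("focus selection matches no atoms; camera unchanged")
        return v
    coords = target.coords()[sorted(atoms)]
    centroid = coords.mean(axis=0)
    extent = float(np.linalg.norm(coords - centroid, axis=1).max())
    zoom = max(extent + radius, 5.0)
    if v.camera is not None:
        from .view_model import orientation_to_camera
        rotation = orientation_to_camera(v.camera).rotation
    else:
        rotation = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    cam = CameraState18(rotation=rotation,
                        camera_position=(0.0, 0.0, -zoom),
                        rotation_origin=tuple(float(x) for x in centroid),
                        slab_near=zoom - 10.0, slab_far=zoom + 10.0,
                        orthoscopic=True)
    return replace(v, camera=camera_to_orientation(cam))


def _active_structure(v: ViewSpec):
    for s, visible in v.structures:
        if visible:
            return s
    return v.structures[0][0]


def apply_prolink(a: ProlinkAction, v: ViewSpec,
                  config: Config = DEFAULT_CONFIG) -> ViewSpec:
    """Apply an action to a ViewSpec, returning a new ViewSpec.

    Pure: the input is never mutated.  Visibility-only actions are
    idempotent.  This is exactly the semantics the emitted page's
    runtime script performs client-side.
    """
    if a.load is not None:
        ids = [s.id for s, _vis in v.structures]
        if a.load not in ids:
            raise ProlinkError(f"unknown model id {a.load!r} "
                               f"(known: {', '.join(ids)})")
        v = replace(v, structures=tuple(
            (s, s.id == a.load) for s, _vis in v.structures))
    if a.view is not None:
        v = replace(v, camera=camera_to_orientation(
            CameraState18.from_floats(a.view)))
    if a.chains_visible is not None:
        wanted = set(a.chains_visible)
        structures = tuple(
            (s, vis and bool(set(s.chains()) & wanted))
            for s, vis in v.structures)
        reps = []
        for rep in v.representations:
            target = (v.structure_by_id(rep.object_id)
                      if rep.object_id else v.structures[0][0])
            atoms = evaluate_selection(rep.selection, target)
            visible_atoms = {i for i in atoms
                             if target.atoms[i].chain in wanted}
            reps.append(replace(rep, visible=bool(visible_atoms)))
        v = replace(v, structures=structures, representations=tuple(reps))
    if a.hide:
        hidden = set(map(print_selection, a.hide))
        v = replace(v, representations=tuple(
            rep for rep in v.representations
            if print_selection(rep.selection) not in hidden))
    if a.show:
        existing = {(rep.kind, print_selection(rep.selection))
                    for rep in v.representations}
        added = tuple(Representation(kind=kind, selection=sel,
                                     color=ColorScheme())
                      for kind, sel in a.show
                      if (kind, print_selection(sel)) not in existing)
        v = replace(v, representations=v.representations + added)
    if a.color_ops:
        reps = []
        for rep in v.representations:
            scheme = rep.color
            base = (scheme.segments if scheme.mode == "segmented"
                    else ((parse_selection("all"), scheme.uniform),))
            reps.append(replace(rep, color=ColorScheme(
                mode="segmented",
                segments=tuple(base) + tuple(a.color_ops))))
        v = replace(v, representations=tuple(reps))
    if a.clash is not None:
        target = _active_structure(v)
        bonds = infer_bonds(target, config=config)
        clashes = find_clashes(target, a.clash, bonds=bonds, config=config)
        spiky = replace(clash_representation(clashes, target),
                        object_id=target.id)
        v = replace(v, representations=v.representations + (spiky,))
        radius = (a.focus_radius if a.focus_radius is not None
                  else config.focus_radius)
        if a.focus is None:
            v = _focus_camera(v, a.clash, radius, config)
    if a.focus is not None:
        radius = (a.focus_radius if a.focus_radius is not None
                  else config.focus_radius)
        v = _focus_camera(v, a.focus, radius, config)
    return v
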