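"""Session import: manifest JSON (always) and live PSE (optional backend).

The desktop viewer's binary session format is an undocumented serialized
blob, so it is never re-parsed from bytes.  Instead a stable JSON
*session manifest* (schema shipped as ``schemas/session-manifest.
schema.json``) captures what a session contributes — objects, per-
selection representations, colors, the 18-float view — and the optional
PSE route merely walks a live session through the viewer's own Python
module and emits that same manifest, so the entire downstream path is
shared and testable without the binary format.

Representation kinds outside the supported set degrade through an
explicit mapping table (ribbon→cartoon, mesh→surface, …); anything
unmapped falls back to ``line`` with a warning.  Degradation never
raises: every warning path still yields a renderable ViewSpec.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import jsonschema

from .config import Config, DEFAULT_CONFIG
from .selection_lang import parse_selection, SelectionSyntaxError
from .structure_io import parse_pdb
from .view_model import (CameraState18, ColorScheme, Representation,
                         ViewSpec, camera_to_orientation, color_to_hex,
                         REP_KINDS)

log = logging.getLogger("molpage")

# Source representation kind → supported kind.  Explicit data; unmapped
# kinds degrade to "line" with a warning.
REP_KIND_MAP: dict[str, str] = {
    "cartoon": "cartoon",
    "ribbon": "cartoon",
    "cartoon_fancy": "cartoon",
    "sticks": "licorice",
    "stick": "licorice",
    "licorice": "licorice",
    "ball+stick": "ball+stick",
    "ball_and_stick": "ball+stick",
    "spheres": "spacefill",
    "sphere": "spacefill",
    "spacefill": "spacefill",
    "vdw": "spacefill",
    "surface": "surface",
    "mesh": "surface",
    "dots": "surface",
    "lines": "line",
    "line": "line",
    "wire": "line",
    "nonbonded": "line",
    "nb_spheres": "ball+stick",
}


class ManifestError(ValueError):
    """Schema violation or unresolvable manifest content."""


class BackendMissingError(RuntimeError):
    """The optional PSE scripting backend is not installed."""


@dataclass(frozen=True)
class SessionObject:
    id: str
    pdb_text: str
    visible: bool = True


@dataclass(frozen=True)
class SessionRep:
    object_id: str
    kind: str
    selection: str
    color: object = "grey"
    opacity: float = 1.0


@dataclass(frozen=True)
class SessionManifest:
    """Validated in-memory form of the session-manifest JSON."""

    objects: tuple[SessionObject, ...]
    reps: tuple[SessionRep, ...]
    view: tuple[float, ...]
    background: object = "white"

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "objects": [{"id": o.id, "pdb_text": o.pdb_text,
                         "visible": o.visible} for o in self.objects],
            "reps": [{"object_id": r.object_id, "kind": r.kind,
                      "selection": r.selection, "color": r.color,
                      "opacity": r.opacity} for r in self.reps],
            "view": list(self.view),
            "background": self.background,
        }


def manifest_schema() -> dict:
    text = (resources.files("molpage") / "schemas" /
            "session-manifest.schema.json").read_text()
    return json.loads(text)


def validate_manifest(data: dict) -> None:
    """Validate against the shipped schema; errors list JSON pointers."""
    validator = jsonschema.Draft202012Validator(manifest_schema())
    errors = sorted(validator.iter_errors(data), key=lambda e: e.json_path)
    if errors:
        pointers = "; ".join(
            "/" + "/".join(str(p) for p in err.absolute_path) +
            f": {err.message}" for err in errors)
        raise ManifestError(f"manifest schema violation at {pointers}")


def load_manifest(source: dict | str | Path) -> SessionManifest:
    """Build a validated :class:`SessionManifest` from JSON data or a file."""
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
        base = Path(source).parent
    else:
        data = source
        base = Path(".")
    validate_manifest(data)
    objects = []
    ids = set()
    for i, obj in enumerate(data["objects"]):
        if obj["id"] in ids:
            raise ManifestError(f"duplicate object id {obj['id']!r} "
                                f"at /objects/{i}")
        ids.add(obj["id"])
        if "pdb_text" in obj:
            pdb_text = obj["pdb_text"]
        elif "pdb_path" in obj:
            pdb_text = (base / obj["pdb_path"]).read_text()
        else:
            raise ManifestError(
                f"object {obj['id']!r} has neither pdb_text nor pdb_path "
                f"(at /objects/{i})")
        objects.append(SessionObject(id=obj["id"], pdb_text=pdb_text,
                                     visible=obj.get("visible", True)))
    reps = []
    for i, rep in enumerate(data["reps"]):
        if rep["object_id"] not in ids:
            raise ManifestError(
                f"rep at /reps/{i} references missing object id "
                f"{rep['object_id']!r}")
        reps.append(SessionRep(object_id=rep["object_id"], kind=rep["kind"],
                               selection=rep["selection"],
                               color=rep.get("color", "grey"),
                               opacity=float(rep.get("opacity", 1.0))))
    return SessionManifest(objects=tuple(objects), reps=tuple(reps),
                           view=tuple(float(v) for v in data["view"]),
                           background=data.get("background", "white"))


def _resolve_color(color: object, config: Config) -> ColorScheme:
    if isinstance(color, list):
        segments = []
        for seg in color:
            sel = parse_selection(seg["selection"])
            segments.append((sel, color_to_hex(seg["color"], config)))
        return ColorScheme(mode="segmented", segments=tuple(segments))
    if color == "by-element":
        return ColorScheme(mode="by-element")
    return ColorScheme(mode="uniform",
                       uniform=color_to_hex(color, config))


def import_manifest(m: SessionManifest | dict | str | Path,
                    config: Config = DEFAULT_CONFIG) -> ViewSpec:
    """Convert a session manifest into a validated :class:`ViewSpec`.

    Selections go through the selection parser, colors through the
    palette, the 18-float view through the camera conversion.
    Unsupported representation kinds degrade per :data:`REP_KIND_MAP`.
    Deterministic: identical manifest bytes give an identical ViewSpec.
    """
    if not isinstance(m, SessionManifest):
        m = load_manifest(m)
    structures = tuple(
        (parse_pdb(o.pdb_text, id=o.id), o.visible) for o in m.objects)
    reps = []
    for rep in m.reps:
        kind = REP_KIND_MAP.get(rep.kind.lower())
        if kind is None:
            log.warning("unsupported representation kind %r: degrading "
                        "to line", rep.kind)
            kind = "line"
        try:
            sel = parse_selection(rep.selection)
        except SelectionSyntaxError as exc:
            raise ManifestError(
                f"unparseable selection in rep for object "
                f"{rep.object_id!r}: {exc}") from exc
        reps.append(Representation(kind=kind, selection=sel,
                                   color=_resolve_color(rep.color, config),
                                   opacity=rep.opacity,
                                   object_id=rep.object_id))
    camera = camera_to_orientation(CameraState18.from_floats(m.view))
    spec = ViewSpec(structures=structures, representations=tuple(reps),
                    camera=camera,
                    background=color_to_hex(m.background, config))
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# optional live-PSE route

# Rep names queryable with the desktop viewer's "rep" selection operator.
_PSE_REP_NAMES = ("cartoon", "ribbon", "sticks", "spheres", "surface",
                  "mesh", "lines", "dots", "nb_spheres", "nonbonded")


def import_pse(path: str | Path) -> SessionManifest:
    """Load a binary PSE session through the optional scripting backend.

    Requires the desktop viewer's Python module (``pymol2``); without it
    a :class:`BackendMissingError` explains how to get it.  The session
    is walked object by object and emitted as a
    :class:`SessionManifest`, so everything downstream of this function
    is identical to the manifest route.
    """
    try:
        import pymol2  # type: ignore
    except ImportError:
        raise BackendMissingError(
            "the PSE route needs the desktop viewer's Python module: "
            "install PyMOL (e.g. conda install -c conda-forge "
            "pymol-open-source) to enable it; the manifest route works "
            "without it") from None
    path = Path(path)
    with pymol2.PyMOL() as p:
        cmd = p.cmd
        cmd.load(str(path))
        names = [n for n in cmd.get_names("objects")
                 if cmd.get_type(n) == "object:molecule"]
        if not names:
            raise ManifestError(f"empty session: no molecular objects "
                                f"in {path}")
        enabled = set(cmd.get_names("objects", enabled_only=1))
        objects = []
        reps = []
        for name in names:
            pdb_text = cmd.get_pdbstr(name)
            objects.append({"id": name, "pdb_text": pdb_text,
                            "visible": name in enabled})
            colors: set[int] = set()
            cmd.iterate(name, "colors.add(color)", space={"colors": colors})
            color = (int(next(iter(colors)))
                     if len(colors) == 1 else "by-element")
            for kind in _PSE_REP_NAMES:
                if cmd.count_atoms(f"({name}) and rep {kind}"):
                    reps.append({"object_id": name, "kind": kind,
                                 "selection": "all", "color": color,
                                 "opacity": 1.0})
        view = [float(v) for v in cmd.get_view()]
        data = {"schema": 1, "objects": objects, "reps": reps,
                "view": view, "background": "white"}
    return load_manifest(data)


def fetch_pdb(code: str) -> str:
    """Download PDB text for a 4-character entry code (network required).

    Thin convenience for the PDB-code input route; everything else in
    the package is offline.
    """
    import urllib.request

    code = code.strip().lower()
    if len(code) != 4 or not code.isalnum():
        raise ValueError(f"not a PDB entry code: {code!r}")
    url = f"https://files.rcsb.org/download/{code}.pdb"
    with urllib.request.urlopen(url) as fh:  # pragma: no cover - network
        return fh.read().decode()
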