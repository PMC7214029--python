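"""Final assembly of the self-contained HTML page.

A page is one HTML file: a viewer viewport, the markdown narrative with
its prolinks wired to a small bundled runtime, a radio model switcher,
an optional front image that is swapped for the live view on click, and
a single ``<script type="application/json">`` state island carrying
every view (structures as embedded PDB text, representations with
transpiled viewer-dialect selections, orientation matrices, clash
payloads).  State-as-data rather than generated imperative code keeps
the output testable without executing a browser.

Offline pages (the default) contain zero external URL references: the
runtime is inlined from the packaged asset and structures are embedded.
Non-offline pages additionally reference the pinned viewer-library URL
from the config.  Output is byte-deterministic: no timestamps, fixed
key order everywhere.
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass, field
from importlib import resources

from markdown_it import MarkdownIt

from .config import Config, DEFAULT_CONFIG
from .selection_lang import resolve_around, to_viewer_selection
from .structure_io import parse_pdb
from .view_model import ViewSpec

__all__ = ["PageDocument", "PageError", "render_markdown", "render_page"]


class PageError(ValueError):
    """Invalid page document (dangling targets, duplicate ids, …)."""


@dataclass(frozen=True)
class PageDocument:
    """Everything needed to emit one page."""

    title: str
    body_markdown: str
    viewspecs: tuple[tuple[str, ViewSpec], ...]
    initial_view: str
    front_image: str | None = None
    options: dict = field(default_factory=lambda: {
        "offline": True, "background": "FFFFFF", "spin": False})

    def view_ids(self) -> list[str]:
        return [vid for vid, _ in self.viewspecs]

    def validate(self) -> None:
        ids = self.view_ids()
        if len(set(ids)) != len(ids):
            raise PageError(f"duplicate viewspec ids: {ids}")
        if self.initial_view not in ids:
            raise PageError(
                f"initial view {self.initial_view!r} is not among "
                f"viewspec ids {ids}")
        for target in _prolink_load_targets(self.body_markdown):
            if target not in ids:
                raise PageError(
                    f"prolink data-load target {target!r} does not "
                    f"resolve to any viewspec id")


# ---------------------------------------------------------------------------
# markdown with prolink passthrough

_PROLINK_RE = re.compile(
    r"<a\s[^>]*class=\"prolink\"[^>]*>.*?</a>", re.DOTALL)
_SCRIPTISH_RE = re.compile(
    r"<\s*(script|style)\b.*?(?:</\s*\1\s*>|$)", re.DOTALL | re.IGNORECASE)
_ATTR_RE = re.compile(r"(data-[a-z]+)=\"([^\"]*)\"")


def _prolink_load_targets(markdown_body: str) -> list[str]:
    targets = []
    for anchor in _PROLINK_RE.findall(markdown_body):
        for key, value in _ATTR_RE.findall(anchor):
            if key == "data-load":
                targets.append(html.unescape(value))
    return targets


def prolink_anchors(text: str) -> list[dict[str, str]]:
    """Extract each prolink anchor's data-attributes from HTML/markdown."""
    out = []
    for anchor in _PROLINK_RE.findall(text):
        out.append({k: html.unescape(v)
                    for k, v in _ATTR_RE.findall(anchor)})
    return out


def render_markdown(body: str) -> str:
    """CommonMark rendering with an HTML allowlist of exactly one item.

    Prolink anchors pass through byte-for-byte; ``<script>``/``<style>``
    elements are stripped wholesale; any other raw HTML is escaped to
    visible text.
    """
    body = _SCRIPTISH_RE.sub("", body)
    anchors: list[str] = []

    def stash(match: re.Match) -> str:
        anchors.append(match.group(0))
        return f"MOLPAGEPROLINK{len(anchors) - 1}TOKEN"

    stashed = _PROLINK_RE.sub(stash, body)
    md = MarkdownIt("commonmark", {"html": False})
    rendered = md.render(stashed)
    for i, anchor in enumerate(anchors):
        rendered = rendered.replace(f"MOLPAGEPROLINK{i}TOKEN", anchor)
    return rendered


# ---------------------------------------------------------------------------
# state serialization

def _serialize_color(scheme, structure) -> dict:
    data: dict = {"mode": scheme.mode}
    if scheme.mode == "uniform":
        data["uniform"] = scheme.uniform
    elif scheme.mode == "segmented":
        data["segments"] = [
            {"selection": to_viewer_selection(resolve_around(sel, structure)),
             "color": hexval}
            for sel, hexval in scheme.segments]
    return data


def _serialize_viewspec(spec: ViewSpec) -> dict:
    reps = []
    for rep in spec.representations:
        structure = (spec.structure_by_id(rep.object_id)
                     if rep.object_id else spec.structures[0][0])
        reps.append({
            "kind": rep.kind,
            "selection": to_viewer_selection(
                resolve_around(rep.selection, structure)),
            "color": _serialize_color(rep.color, structure),
            "opacity": rep.opacity,
            "visible": rep.visible,
            "object_id": rep.object_id,
            "atom_radii": [[i, r] for i, r in rep.atom_radii],
        })
    return {
        "structures": [{"id": s.id, "visible": visible}
                       for s, visible in spec.structures],
        "representations": reps,
        "camera": list(spec.camera.matrix) if spec.camera else None,
        "background": spec.background,
    }


def page_state(doc: PageDocument) -> dict:
    """The JSON state island: views, deduplicated structure payloads."""
    from .structure_io import write_pdb

    structures: dict[str, dict] = {}
    views: dict[str, dict] = {}
    for vid, spec in doc.viewspecs:
        views[vid] = _serialize_viewspec(spec)
        for s, _visible in spec.structures:
            structures.setdefault(s.id, {"pdb": write_pdb(s)})
    return {
        "initialView": doc.initial_view,
        "viewOrder": doc.view_ids(),
        "options": doc.options,
        "structures": structures,
        "views": views,
    }


def _json_island(data: dict) -> str:
    text = json.dumps(data, sort_keys=True, separators=(",", ":"))
    # XML/script-safe: escape markup characters inside JSON strings
    return (text.replace("&", "\\u0026").replace("<", "\\u003c")
            .replace(">", "\\u003e"))


def _asset(name: str) -> str:
    return (resources.files("molpage") / "assets" / name).read_text()


# ---------------------------------------------------------------------------
# page assembly

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<meta name="viewport" content="width=device-width, initial-scale=1"/>
<title>{title}</title>
<style>
{css}
</style>
</head>
<body style="background-color:#{background}">
<h1>{title}</h1>
{front_image}
<div id="molpage-viewport"></div>
{switcher}
<div id="molpage-body">
{body}
</div>
<script type="application/json" id="molpage-state">{state}</script>
{viewer_script}
<script id="molpage-runtime">/*<![CDATA[*/
{runtime}
/*]]>*/</script>
</body>
</html>
"""


def _switcher(doc: PageDocument) -> str:
    if len(doc.viewspecs) < 2:
        return '<div class="molpage-switcher"></div>'
    inputs = []
    for vid in doc.view_ids():
        checked = ' checked="checked"' if vid == doc.initial_view else ""
        esc = html.escape(vid, quote=True)
        inputs.append(
            f'<label><input type="radio" name="molpage-model" '
            f'value="{esc}" id="molpage-model-{esc}"{checked}/>'
            f"{html.escape(vid)}</label>")
    return ('<div class="molpage-switcher">' + "".join(inputs) + "</div>")


def render_page(doc: PageDocument, config: Config = DEFAULT_CONFIG) -> str:
    """Emit the complete single-file HTML page for ``doc``.

    Raises :class:`PageError` before writing anything if a prolink
    ``data-load`` target does not resolve.  Identical documents produce
    byte-identical pages.
    """
    doc.validate()
    offline = bool(doc.options.get("offline", True))
    state = _json_island(page_state(doc))
    if doc.front_image:
        src = html.escape(doc.front_image, quote=True)
        front = (f'<img id="molpage-front-image" src="{src}" '
                 f'alt="static preview: click for the interactive view"/>')
    else:
        front = ""
    viewer_script = ""
    if not offline:
        url = html.escape(config.viewer_js_url, quote=True)
        viewer_script = f'<script src="{url}"></script>'
    return _PAGE_TEMPLATE.format(
        title=html.escape(doc.title),
        css=_asset("page.css"),
        background=doc.options.get("background", "FFFFFF"),
        front_image=front,
        switcher=_switcher(doc),
        body=render_markdown(doc.body_markdown).rstrip("\n"),
        state=state,
        viewer_script=viewer_script,
        runtime=_asset("runtime.js").rstrip("\n"),
    )


def load_page_document(source: str | dict, config=DEFAULT_CONFIG
                       ) -> PageDocument:
    """Build a PageDocument from its JSON form (schema shipped under
    ``schemas/page-document.schema.json``) for scripted use."""
    import jsonschema
    from pathlib import Path

    from .selection_lang import parse_selection
    from .session_import import _resolve_color
    from .view_model import Orientation4x4, Representation

    if not isinstance(source, dict):
        data = json.loads(Path(source).read_text())
    else:
        data = source
    schema = json.loads((resources.files("molpage") / "schemas" /
                         "page-document.schema.json").read_text())
    jsonschema.validate(data, schema)
    viewspecs = []
    for vs in data["viewspecs"]:
        structures = tuple(
            (parse_pdb(obj["pdb_text"], id=obj["id"]),
             obj.get("visible", True))
            for obj in vs["structures"])
        reps = tuple(
            Representation(kind=rep["kind"],
                           selection=parse_selection(rep["selection"]),
                           color=_resolve_color(rep.get("color", "grey"),
                                                config),
                           opacity=rep.get("opacity", 1.0),
                           object_id=rep.get("object_id"),
                           visible=rep.get("visible", True))
            for rep in vs.get("representations", []))
        camera = (Orientation4x4(matrix=tuple(vs["camera"]))
                  if vs.get("camera") else None)
        viewspecs.append((vs["id"], ViewSpec(
            structures=structures, representations=reps, camera=camera,
            background=vs.get("background", "FFFFFF"))))
    options = {"offline": True, "background": "FFFFFF", "spin": False}
    options.update(data.get("options", {}))
    doc = PageDocument(title=data["title"],
                       body_markdown=data["body_markdown"],
                       viewspecs=tuple(viewspecs),
                       initial_view=data["initial_view"],
                       front_image=data.get("front_image"),
                       options=options)
    doc.validate()
    return doc


def embedded_structures(page_html: str) -> dict[str, "object"]:
    """Re-parse the PDB payloads embedded in a rendered page.

    Convenience for round-trip checks: returns ``{id: Structure}``.
    """
    m = re.search(r'<script type="application/json" id="molpage-state">'
                  r"(.*?)</script>", page_html, re.DOTALL)
    if not m:
        raise PageError("no state island found in page")
    state = json.loads(m.group(1))
    return {sid: parse_pdb(entry["pdb"], id=sid)
            for sid, entry in state["structures"].items()}
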