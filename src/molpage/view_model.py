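"""Renderable state: representations, color schemes, camera conversion.

The camera bridge is the heart of the session route.  The desktop
viewer's ``get_view`` state is 18 numbers — a row-major 3×3 rotation, a
camera position in the camera frame, a rotation origin in the model
frame, two slab depths and an orthoscopic flag.  The browser viewer
instead takes a single homogeneous 4×4 orientation matrix.  The forward
conversion here is pinned by three decomposition properties rather than
any particular formula:

(a) the 3×3 block of the result is ``scale · Rᵀ``;
(b) the result maps the rotation origin onto the view axis at a depth
    equal to ``|camera z|`` from the camera plane;
(c) the uniform scale equals ``|camera z|``, preserving zoom.

Slab values cannot be expressed in the 4×4 and are re-synthesized as
``(|z|−10, |z|+10)`` on the inverse; the orthoscopic flag travels as a
separate page parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .selection_lang import SelectionAST, Chain, evaluate_selection
from .structure_io import Structure

log = logging.getLogger("molpage")

REP_KINDS = ("cartoon", "ball+stick", "licorice", "spacefill", "surface",
             "line", "spiky-ball")

# Classic molecular-viewer palette: name → RRGGBB, plus small-integer
# indices in conventional order.  Data, not code: override via
# Config.color_overrides.
COLOR_TABLE: dict[str, str] = {
    "white": "FFFFFF",
    "black": "000000",
    "blue": "0000FF",
    "green": "00FF00",
    "red": "FF0000",
    "cyan": "00FFFF",
    "yellow": "FFFF00",
    "magenta": "FF00FF",
    "orange": "FF8000",
    "wheat": "F0D9B3",
    "salmon": "FA8072",
    "grey": "808080",
    "gray": "808080",
    "grey50": "808080",
    "gray50": "808080",
    "grey80": "CCCCCC",
    "gray80": "CCCCCC",
    "grey30": "4D4D4D",
    "gray30": "4D4D4D",
    "slate": "8080FF",
    "marine": "0080FF",
    "olive": "C0C000",
    "purple": "BF00BF",
    "teal": "00BFBF",
    "pink": "FFB3B3",
    "hotpink": "FF0080",
    "firebrick": "B22222",
    "chocolate": "D2691E",
    "brown": "A52A2A",
    "lime": "80FF00",
    "limegreen": "00FF80",
    "smudge": "86A67C",
    "deepteal": "1F9999",
    "violet": "BF80BF",
    "skyblue": "54A8FC",
    "forest": "228022",
    "deepblue": "0000B3",
    "lightblue": "BFBFFF",
    "palegreen": "A5E6A5",
    "paleyellow": "FFFF80",
    "tv_red": "FF3333",
    "tv_green": "33FF33",
    "tv_blue": "4D4DFF",
}

COLOR_INDICES: tuple[str, ...] = (
    "white", "black", "blue", "green", "red", "cyan", "yellow", "magenta",
    "orange", "salmon", "grey", "wheat", "purple", "pink", "marine",
    "slate", "olive", "teal", "hotpink", "forest",
)


@dataclass(frozen=True)
class ColorScheme:
    """uniform / by-element / segmented coloring of one representation."""

    mode: str = "uniform"  # uniform | by-element | segmented
    uniform: str = "808080"
    segments: tuple[tuple[SelectionAST, str], ...] = ()

    def __post_init__(self):
        if self.mode not in ("uniform", "by-element", "segmented"):
            raise ValueError(f"unknown color mode {self.mode!r}")
        if self.mode == "segmented" and not self.segments:
            raise ValueError("segmented color scheme needs >= 1 segment")
        for hexval in [self.uniform] + [h for _, h in self.segments]:
            _check_hex(hexval)


def _check_hex(value: str) -> str:
    v = value.lstrip("#")
    if len(v) != 6 or any(c not in "0123456789abcdefABCDEF" for c in v):
        raise ValueError(f"not an RRGGBB hex triplet: {value!r}")
    return v.upper()


def color_to_hex(name_or_index: str | int,
                 config: Config = DEFAULT_CONFIG) -> str:
    """Resolve a viewer color name, small index, or hex to RRGGBB.

    Total by design: unknown input falls back to the configured grey
    with a logged warning, never an exception.
    """
    table = dict(COLOR_TABLE)
    table.update({k.lower(): _check_hex(v)
                  for k, v in config.color_overrides.items()})
    if isinstance(name_or_index, bool):
        name_or_index = int(name_or_index)
    if isinstance(name_or_index, int):
        if 0 <= name_or_index < len(COLOR_INDICES):
            return table[COLOR_INDICES[name_or_index]]
        log.warning("unknown color index %d: falling back to grey",
                    name_or_index)
        return config.fallback_color
    text = str(name_or_index).strip()
    if text.startswith("#") or (
            len(text) == 6 and all(c in "0123456789abcdefABCDEF"
                                   for c in text)):
        try:
            return _check_hex(text)
        except ValueError:
            pass
    if text.lstrip("-").isdigit():
        return color_to_hex(int(text), config)
    key = text.lower()
    if key in table:
        return table[key]
    log.warning("unknown color name %r: falling back to grey", text)
    return config.fallback_color


# ---------------------------------------------------------------------------
# camera state

class CameraError(ValueError):
    """Invalid camera state or orientation matrix."""


@dataclass(frozen=True)
class CameraState18:
    """The desktop viewer's 18-float view state (``get_view`` order)."""

    rotation: tuple[float, ...]         # 9 floats, row-major 3x3
    camera_position: tuple[float, float, float]
    rotation_origin: tuple[float, float, float]
    slab_near: float = 40.0
    slab_far: float = 60.0
    orthoscopic: bool = True

    @classmethod
    def from_floats(cls, values) -> "CameraState18":
        vals = [float(v) for v in values]
        if len(vals) != 18:
            raise CameraError(f"expected 18 view floats, got {len(vals)}")
        return cls(rotation=tuple(vals[0:9]),
                   camera_position=tuple(vals[9:12]),
                   rotation_origin=tuple(vals[12:15]),
                   slab_near=vals[15], slab_far=vals[16],
                   orthoscopic=bool(round(vals[17])))

    def to_floats(self) -> list[float]:
        return [*self.rotation, *self.camera_position,
                *self.rotation_origin, self.slab_near, self.slab_far,
                float(self.orthoscopic)]

    def rotation_matrix(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float).reshape(3, 3)

    def validate(self) -> None:
        R = self.rotation_matrix()
        if not np.all(np.isfinite(R)):
            raise CameraError("non-finite rotation matrix")
        dev = np.abs(R.T @ R - np.eye(3)).max()
        if dev >= 1e-4:
            raise CameraError(
                f"rotation not orthonormal (max |RtR - I| = {dev:.2e})")
        if np.linalg.det(R) < 0:
            raise CameraError("rotation has negative determinant")


@dataclass(frozen=True)
class Orientation4x4:
    """Row-major homogeneous orientation matrix for the browser viewer."""

    matrix: tuple[float, ...]  # 16 floats

    @classmethod
    def from_array(cls, m: np.ndarray) -> "Orientation4x4":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise CameraError(f"expected a 4x4 matrix, got {m.shape}")
        return cls(matrix=tuple(float(v) for v in m.ravel()))

    def array(self) -> np.ndarray:
        return np.array(self.matrix, dtype=float).reshape(4, 4)

    def validate(self) -> None:
        m = self.array()
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise CameraError("last row of orientation must be (0,0,0,1)")
        A = m[:3, :3]
        scale = float(np.linalg.norm(A[0]))
        if scale <= 0 or not np.isfinite(scale):
            raise CameraError("degenerate orientation scale")
        R = A / scale
        if np.linalg.det(R) < 0:
            raise CameraError("orientation contains a reflection (det < 0)")
        dev = np.abs(R.T @ R - np.eye(3)).max()
        if dev >= 1e-4:
            raise CameraError(
                f"orientation block is not scale*rotation "
                f"(max deviation {dev:.2e})")


def camera_to_orientation(v: CameraState18) -> Orientation4x4:
    """Convert the 18-float camera state to the 4×4 orientation.

    Built as ``T(0,0,−s) · s·Rᵀ · T(−origin)`` with ``s = |camera z|``,
    which realizes the three pinned decomposition properties: the linear
    block is s·Rᵀ, the rotation origin lands on the view axis at depth
    s, and zoom is carried by the uniform scale s.
    """
    v.validate()
    R = v.rotation_matrix()
    s = abs(v.camera_position[2])
    if s == 0:
        raise CameraError("camera z distance must be non-zero")
    A = s * R.T
    origin = np.array(v.rotation_origin, dtype=float)
    t = -A @ origin + np.array([0.0, 0.0, -s])
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t
    return Orientation4x4.from_array(m)


def orientation_to_camera(m: Orientation4x4) -> CameraState18:
    """Inverse of :func:`camera_to_orientation` up to slab values.

    Slabs are re-synthesized as ``(|z|−10, |z|+10)``; the orthoscopic
    flag defaults to true (it is carried outside the matrix).
    """
    m.validate()
    arr = m.array()
    A = arr[:3, :3]
    s = float(np.linalg.norm(A[0]))
    R = (A / s).T
    t = arr[:3, 3]
    origin = -np.linalg.solve(A, t - np.array([0.0, 0.0, -s]))
    return CameraState18(
        rotation=tuple(float(x) for x in R.ravel()),
        camera_position=(0.0, 0.0, -s),
        rotation_origin=tuple(float(x) for x in origin),
        slab_near=s - 10.0,
        slab_far=s + 10.0,
        orthoscopic=True,
    )


# ---------------------------------------------------------------------------
# representations and the renderable unit

@dataclass(frozen=True)
class Representation:
    """One drawing style over a selected atom subset of one structure."""

    kind: str
    selection: SelectionAST
    color: ColorScheme = field(default_factory=ColorScheme)
    opacity: float = 1.0
    object_id: str | None = None   # which ViewSpec structure it draws
    visible: bool = True
    atom_radii: tuple[tuple[int, float], ...] = ()  # spiky-ball spike sizes

    def __post_init__(self):
        if self.kind not in REP_KINDS:
            raise ValueError(f"unknown representation kind {self.kind!r}")
        if not (0.0 < self.opacity <= 1.0):
            raise ValueError("opacity must be in (0, 1]")


@dataclass(frozen=True)
class ViewSpec:
    """Structures + representations + camera + background: one view."""

    structures: tuple[tuple[Structure, bool], ...]
    representations: tuple[Representation, ...] = ()
    camera: Orientation4x4 | None = None
    background: str = "FFFFFF"

    def structure_by_id(self, object_id: str) -> Structure:
        for s, _visible in self.structures:
            if s.id == object_id:
                return s
        raise KeyError(f"no structure with id {object_id!r}")

    def validate(self) -> None:
        """Check selections evaluate; warn (never drop) on absent chains."""
        _check_hex(self.background)
        if self.camera is not None:
            self.camera.validate()
        for rep in self.representations:
            target = (self.structure_by_id(rep.object_id)
                      if rep.object_id else self.structures[0][0])
            evaluate_selection(rep.selection, target)
            for chain in _chains_in(rep.selection):
                if chain not in target.chains():
                    log.warning(
                        "representation %r selects chain %r absent from "
                        "structure %r", rep.kind, chain, target.id)


def _chains_in(ast: SelectionAST) -> set[str]:
    if isinstance(ast, Chain):
        return set(ast.ids)
    out: set[str] = set()
    for attr in ("left", "right", "child", "inner"):
        sub = getattr(ast, attr, None)
        if sub is not None:
            out |= _chains_in(sub)
    return out
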