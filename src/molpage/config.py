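"""Package-wide defaults and the optional TOML config file.

Every numeric convention the package relies on (bond-inference slack,
clash cutoff, focus radius, fallback/highlight colors) lives here so the
CLI can override it from a single ``[molpage]``-table TOML file and so
tests can construct explicit configs.  Flags always win over config-file
values, which win over these defaults.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

log = logging.getLogger("molpage")


@dataclass(frozen=True)
class Config:
    """Tunable defaults, all in Å unless noted.

    bond_slack          added to the covalent-radius sum when inferring bonds
    clash_cutoff        minimum van der Waals overlap reported as a clash
    include_hydrogen_clashes  report clash pairs involving hydrogen atoms
    focus_radius        neighborhood radius used by focus/highlight actions
    fallback_color      hex used for unknown color names (mid-grey)
    highlight_color     hex used to mark variant residues
    background          page background hex
    hybrid36            encode residue numbers >9999 in hybrid-36 on write
                        (default: error instead)
    viewer_js_url       pinned viewer-library URL used by non-offline pages
    """

    bond_slack: float = 0.45
    clash_cutoff: float = 0.4
    include_hydrogen_clashes: bool = False
    focus_radius: float = 5.0
    fallback_color: str = "808080"
    highlight_color: str = "FF8C00"
    background: str = "FFFFFF"
    hybrid36: bool = False
    viewer_js_url: str = "https://unpkg.com/ngl@2.0.0-dev.39/dist/ngl.js"
    color_overrides: dict[str, str] = field(default_factory=dict)


DEFAULT_CONFIG = Config()


def load_config(path: str | Path) -> Config:
    """Read a TOML config file; keys under [molpage] mirror Config fields."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("molpage", data)
    known = {f.name for f in fields(Config)}
    unknown = sorted(set(table) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return replace(DEFAULT_CONFIG, **table)
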