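# Methods

This note records the models, conventions and numerical choices behind
`molpage`, in the spirit of a package's own methods documentation. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and design stance

The package turns coordinates plus a description of a viewer session
into a single offline HTML page whose text controls the 3D view. Three
things are deliberately *not* attempted: re-parsing the desktop
viewer's binary session format from bytes (it is an undocumented
serialized blob — the live-backend route plus a stable JSON manifest
schema is the engineering answer, and it keeps the test suite
hermetic); alignment-based renumbering between variant coordinates and
PDB author numbering (the wild-type residue check fails loudly
instead); and mutant side-chain modelling (variant views show the
location and steric environment of the *existing* wild-type atoms —
pretending to place a mutant rotamer would be worse than not doing it).

## Structure model and PDB dialect

One `Atom` per ATOM/HETATM record, order preserved, author numbering
kept verbatim. Fixed tolerance rules, chosen where the fixed-column
format is ambiguous:

* first MODEL only; later conformers dropped with a warning (one
  conformer per renderable view);
* per atom site, the highest-occupancy altloc is kept, first seen
  winning ties — the usual viewer default;
* element inference when columns 77–78 are blank: first alphabetic
  character of the atom name ("CA" in a standard amino acid is carbon);
  in a non-standard HETATM a two-letter name is taken as a two-letter
  element ("CA" alone in a hetero group is calcium);
* residue numbers above 9999 error on write by default; a config flag
  enables hybrid-36 encoding instead. Insertion codes are carried but
  `resi` ranges match by integer, a documented limitation;
* parsing tolerates CR/LF and trailing whitespace; malformed numeric
  fields report the line number.

## Bond inference

`d(i,j) ≤ r_cov(i) + r_cov(j) + slack`, slack 0.45 Å, covalent radii
C 0.77, N 0.75, O 0.73, S 1.02, H 0.37, P 1.06, default 0.77 Å
(unknown elements warn and use the default). The KD-tree implementation
caps the query at the largest bondable distance plus a 1e-9 Å epsilon
so the prefilter can never drop a boundary-exact pair the rule would
accept; tests assert exact set equality with an all-pairs scan.

## Clash model

van der Waals overlap `r_i + r_j − d`, Bondi-style radii (C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, default 1.70 Å), reported when
overlap exceeds a 0.4 Å cutoff. The threshold and radii follow common
steric-clash conventions and are config-exposed; nothing in the source
application documents its own values. Exclusions: bonded pairs (1-2),
pairs sharing a bonded neighbor (1-3), intra-residue pairs, and pairs
involving hydrogen unless a config flag asks for them. Results are
sorted by descending overlap with index tie-breaks, each unordered pair
once. The spiky-ball representation enumerates exactly the clashing
atoms and carries each atom's largest overlap as per-atom radius
metadata (spike size in the page runtime).

## Selection language

The supported subset (README table) is this package's contract; the
source application never enumerates which constructs it preserves.
Three semantics decisions worth recording: `around` excludes the inner
selection itself (the desktop viewer's `around`, not `expand`); `byres`
is only meaningful attached to a distance selection and expands any
partially included residue to all its atoms; unknown and known-but-
unsupported keywords both raise with the keyword named and a character
offset. The transpiler's correctness criterion is behavioral: the
emitted NGL-dialect string, evaluated under an independent test-side
implementation of the dialect's published semantics, must select the
same atom set as the internal evaluator. Distance selections are
rewritten to explicit enumerations first — by-residue neighborhoods
become per-chain `chain C and resi …` unions (consecutive numbers
merged into ranges), atom-level neighborhoods become
`chain/resi/name` triples.

## Camera conversion

The 18-float view state is converted as
`M = T(0,0,−s) · s·Rᵀ · T(−origin)` with `s = |camera z|`. No formula
is documented for the original conversion; this one is pinned by three
decomposition properties any correct choice must satisfy (linear block
= `s·Rᵀ`; origin maps to the view axis at depth `s`; zoom carried as
uniform scale), so an alternative implementation is test-equivalent.
Rotations must be orthonormal within 1e-4 (max |RᵀR−I| entry) with
positive determinant; reflections are rejected. Slab depths are not
representable in the 4×4 and are re-synthesized as `(s−10, s+10)` on
inversion; the orthoscopic flag travels beside the matrix as a page
parameter. Round trips are fixed points on rotation/origin/zoom to
1e-6 (measured ~1e-13).

## Session manifests

The manifest JSON schema (`schemas/session-manifest.schema.json`,
versioned `schema: 1`) captures objects, per-selection representations,
colors (name, index, hex or segment list) and the 18-float view.
Unsupported representation kinds degrade through an explicit mapping
table (ribbon→cartoon, mesh/dots→surface, sticks→licorice,
spheres→spacefill, …); anything unmapped becomes `line` with a warning.
Degradation never raises: any color or kind problem still yields a
renderable ViewSpec. The color table ships the classic viewer palette
(40+ names, 20 small-integer indices, index 0 = white) as data,
overridable via config; unknown colors fall back to mid-grey `808080`
with a warning, so color resolution is total.

## Prolinks

The ten-key `data-*` vocabulary is this package's normative definition;
the wire format of the original service is not documented, and no
compatibility with it is attempted. `data-view` deliberately carries
the 18-float desktop convention (authorable by copy-paste from
`get_view`) rather than a raw 4×4. Serialization uses a fixed canonical
key order and `repr` floats, making parse∘render an identity and pages
byte-stable. `apply_prolink` is a pure function implementing the same
semantics the bundled page runtime performs client-side: `load`
switches the visible structure, `chains` flags structures and
representations whose selections fall entirely outside the kept chains
invisible, `hide` retires representations by structural selection
equality, `show` appends (skipping exact duplicates, so it is
idempotent), `color` appends painter-model segments (later segments
win), `clash` runs detection around the selection and appends the
spiky-ball representation, and `focus` frames the selection: camera
origin at the centroid of the selection plus its by-residue 5 Å
neighborhood, zoom = max radial extent + focus radius (min 5 Å),
rotation kept from the current camera.

## Variant pipeline

Defaults: 5 Å neighborhood radius, highlight color `FF8C00`, both
config-exposed. Views are `overview` then `variant-k` in input order;
the overview colors the union of mapped residues on a grey cartoon.
Per-variant prolinks carry `data-load`, `data-focus` and `data-radius`
and must round-trip through the prolink parser (tested).

## Page output

One HTML file, XML-well-formed (void elements self-closed, scripts
CDATA-wrapped), deterministic: state serialized with sorted keys, no
timestamps. All view state lives in a single
`<script type="application/json">` island — structures as embedded PDB
text (deduplicated by id), representations with transpiled dialect
selections, 4×4 cameras, clash payloads — never generated imperative
code, so pages are testable without a browser. Markup characters inside
the JSON are unicode-escaped, which keeps the island both valid JSON
and inert in HTML. Markdown is rendered as CommonMark with raw HTML
disabled; the sanitization allowlist has exactly one entry: prolink
anchors pass through byte-for-byte, `<script>`/`<style>` elements are
removed wholesale, and all other raw HTML is escaped to visible text.

Offline pages contain zero external URL references (the acceptance
scan is for `http://`/`https://` substrings anywhere, which is why even
an XHTML namespace declaration is omitted). The bundled runtime script
is viewer-agnostic: it drives a full NGL stage when a global `NGL`
object is present (online pages reference the pinned viewer URL from
config; embedding sites can inject their own copy) and otherwise
degrades to a textual description of the active view, so offline pages
remain self-contained and their interactive state machine (model
switching, prolink handling, front-image swap) is still exercised. The
runtime is a compact original implementation, pinned and vendored with
the package so emitted pages are reproducible.

## Synthetic structures

All tests run on closed-form generated structures; nothing is
downloaded. The helix uses ideal α-helical parameters (rise 1.5 Å,
twist 100°, CA radius 2.3 Å) with the remaining atoms at fixed offsets
in each residue's local cylindrical frame, tuned so the bond rule
recovers N–CA, CA–C, C–O, CA–CB and the peptide C(i)–N(i+1) link and
the helix is clash-free at the default cutoff. The clash-pair probe
offset is a scaled 7-24-25 Pythagorean pair, so its 2.40 Å distance —
and hence the 1.00 Å overlap — survives 3-decimal PDB rounding exactly.
The pocket's three LIG atoms sit 4 Å radially out from the CB atoms of
residues 5–7 and >5 Å from every other residue, making the 5 Å
by-residue neighborhood exactly {5, 6, 7} by construction.

What these fixtures do *not* emulate: real side-chain geometry beyond
CB, insertion codes, altloc disorder in anything but dedicated parser
tests, multi-copy crystallographic entries, or chemically sensible
ligands. Passing tests therefore demonstrate the correctness of the
geometry/set/serialization machinery on exact inputs, not robustness to
the full zoo of real PDB deposition quirks; the parser's tolerance
rules above are the intended entry point for real files.

## Problem sizes

Randomized suites use seeded generators throughout: 200 selection ASTs,
50 random structures of up to 500 atoms for the clash oracle, 100
camera states, 200 prolink actions — sizes at which the quadratic
oracles stay effectively instant while covering the combinatorial
space. `scripts/acceptance.py` re-runs the same computations from a
single `--seed`.

## Known limitations

* `resi` ignores insertion codes; icode-bearing residues match by
  integer part.
* `around`-free transpilation only; the atom-level rewrite identifies
  atoms by (chain, resseq, name), which assumes names are unique within
  a residue after altloc pruning.
* Perspective FOV, fog/depth cueing and lighting are out of scope; the
  orthoscopic flag is carried but not modelled.
* The PDB-code fetch helper is a network convenience and deliberately
  untested; the protein-name lookup route of the original service is
  out of scope entirely.
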