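# molpage

Self-contained interactive molecular-structure web pages, with
hyperlinks that drive the 3D view.

Sharing structural interpretations online usually means static 2D
renders, because embedding an interactive 3D view in a web page takes
real JavaScript plumbing. `molpage` is an offline library + CLI that
removes that barrier for two audiences:

* **structural biologists** who have a PDB file or a desktop-viewer
  session and want a single `.html` file they can attach to a paper,
  blog post or departmental page — no server, no accounts;
* **clinical geneticists** who have a list of protein point mutations
  and want one page showing where each variant sits in the structure
  and whether its wild-type environment is sterically strained.

The narrative text of a page can contain **prolinks** —
`<a class="prolink" data-…>` hyperlinks whose data-attributes change the
adjacent 3D view when clicked: camera orientation, residue focus, chain
visibility, model switching, and on-demand steric-clash display as red
"spiky balls".

## What it computes

**Selection transpilation.** A PyMOL-style selection grammar is parsed,
evaluated with set semantics, and transpiled to the NGL browser-viewer
dialect. Supported subset:

| construct | example | NGL output |
|---|---|---|
| `all` / `none` | `all` | `*` / `none` |
| `polymer` / `hetatm` | `hetatm` | `polymer` / `hetero` |
| `chain <ids>` | `chain A+B` | `(:A or :B)` |
| `resi <ranges>` | `resi 10-20+30` | `(10-20 or 30)` |
| `resn <names>` | `resn LIG` | `LIG` |
| `name <names>` | `name CA` | `.CA` |
| `elem <symbols>` | `elem C` | `_C` |
| `not / and / or / ( )` | `chain A and resi 5` | `:A and 5` |
| `[byres] X around r` | `byres (resn LIG around 5)` | explicit residue list |

`not` binds tightest, then `around`, then `and`, then `or`. Keywords are
case-insensitive; chain ids are case-sensitive. Distance selections have
no NGL equivalent in this subset, so `resolve_around` rewrites them to
explicit `chain C and resi …` enumerations before transpilation.
Unsupported PyMOL keywords (`ss`, `b`, `q`, `pepseq`, …) raise a named
error rather than silently mis-selecting.

**Steric clashes.** A clash is an atom pair whose van der Waals overlap

```
overlap = r_vdw(i) + r_vdw(j) − d(i, j) > 0.4 Å (default cutoff)
```

excluding covalently bonded (1-2) pairs, pairs sharing a bonded
neighbor (1-3), and intra-residue pairs. Bonds are inferred from a
covalent-radius distance rule (`d ≤ r_cov(i) + r_cov(j) + 0.45 Å`), so
plain PDB files without CONECT records work. The neighbor search runs on
a KD-tree but is exactly equivalent to the quadratic all-pairs rule.

**Camera conversion.** The desktop viewer's 18-float `get_view` state
(row-major rotation **R**, camera position, rotation origin **o**, slab
near/far, orthoscopic flag) becomes the browser viewer's homogeneous
4×4 orientation

```
M = T(0, 0, −s) · s·Rᵀ · T(−o),    s = |camera z|
```

so the linear block decomposes to `s·Rᵀ`, the rotation origin lands on
the view axis at depth `s`, and zoom is preserved as the uniform scale.
The inverse recovers rotation, origin and zoom exactly; slab depths are
re-synthesized as `(s−10, s+10)` since the 4×4 cannot carry them.

**Variant pages.** Mutations in `A123T` or `p.Ala123Thr` notation are
mapped by author numbering onto the structure; the residue found at the
position must match the stated wild type, so numbering offsets fail
loudly instead of silently highlighting the wrong residue. Each mappable
variant gets a focused view (residue highlighted, 5 Å neighborhood in
ball+stick, clashes as spiky balls) plus an overview; unmappable
variants are listed in a "Not in structure" section.

## Worked example

```sh
$ molpage fixtures helix --n-res 12 -o helix.pdb
wrote helix.pdb
$ molpage variants --pdb helix.pdb --mut A3T --mut R5C --mut A99G -o variants.html
WARNING:molpage:variant R5C not mapped: variant R5C: wild-type mismatch at A5: found ALA expected ARG
WARNING:molpage:variant A99G not mapped: variant A99G: position 99 not in structure (chain A)
wrote variants.html
```

The first command writes an ideal 12-residue polyalanine α-helix
(60 atoms). The second maps three variants onto it: `A3T` maps cleanly
and gets a focused view; `R5C` is rejected because residue 5 is ALA,
not ARG (the wild-type check catching a numbering error); `A99G` is
outside the chain and lands in the "Not in structure" section. The
resulting `variants.html` is ~14 kB, opens in any browser with no
network access, and its body carries one model-switching prolink per
mapped variant:

```sh
$ molpage prolink --focus "chain A and resi 123" --radius 5 "the mutated arginine"
<a href="#" class="prolink" data-focus="chain A and resi 123" data-radius="5.0">the mutated arginine</a>
```

### Prolink vocabulary

`data-load` (view id), `data-view` (18 comma-separated floats in
`get_view` order), `data-focus` (selection), `data-radius` (Å),
`data-show` (`kind:selection;…`), `data-hide` (`selection;…`),
`data-color` (`#RRGGBB:selection;…`), `data-chains` (`A,B`),
`data-clash` (selection), `data-label` (text). Attributes are emitted in
this fixed order, so identical pages are byte-identical and diffable.

### Library use

```python
from molpage import fixtures, build_variant_page, parse_variant, render_page

helix = fixtures.make_helix(12)
doc = build_variant_page(helix, [parse_variant("A5T")], chain="A")
html = render_page(doc)          # single self-contained page
```

Session manifests (JSON mirror of what a desktop session contributes:
objects, representations, colors, 18-float view; schema shipped in
`src/molpage/schemas/`) convert with `import_manifest`, and a live
`.pse` file with `import_pse` when the optional backend is installed.

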