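"""PyMOL-style selection expressions: parse, evaluate, transpile.

The supported subset is a deliberate contract (documented in the README
railroad table): ``all none polymer hetatm chain resi resn name elem``,
boolean ``not/and/or`` with the usual precedence (``not`` tightest,
``and`` tighter than ``or``), parentheses, and distance selections
``X around r`` with an optional ``byres`` expansion.  Everything else in
the PyMOL algebra (``ss``, ``b``, ``q``, ``pepseq`` …) fails loudly with
a named-keyword error instead of silently mis-selecting.

Evaluation has plain set semantics over a :class:`~molpage.structure_io.
Structure`; the transpiler emits the NGL browser-viewer dialect
(``:A``, ``10-20``, ``.CA``, ``_C``), which has no distance operator in
the supported subset — :func:`resolve_around` rewrites ``around`` nodes
to explicit chain/residue enumerations first.

Keywords are case-insensitive; chain ids are case-sensitive; residue,
atom and element names are normalized to upper case.  ``resi`` ranges
match by integer residue number, ignoring insertion codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .structure_io import Structure

# PyMOL keywords we refuse rather than approximate.
UNSUPPORTED_KEYWORDS = {
    "ss", "b", "q", "pepseq", "within", "expand", "neighbor", "bound_to",
    "byring", "bychain", "bymolecule", "like", "in", "first", "last",
    "index", "id", "rank", "state", "present", "donor", "acceptor",
    "solvent", "organic", "inorganic", "sidechain", "backbone", "visible",
    "enabled", "model", "segi", "alt", "flag", "formal_charge",
    "partial_charge", "numeric_type", "text_type",
}


class SelectionSyntaxError(ValueError):
    """Selection parse failure; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnresolvedDistanceError(ValueError):
    """A distance (around) node reached a context that cannot express it."""


# ---------------------------------------------------------------------------
# AST

@dataclass(frozen=True)
class All:
    pass


@dataclass(frozen=True)
class NoneSel:
    pass


@dataclass(frozen=True)
class Polymer:
    pass


@dataclass(frozen=True)
class Hetatm:
    pass


@dataclass(frozen=True)
class Chain:
    ids: tuple[str, ...]


@dataclass(frozen=True)
class Resi:
    ranges: tuple[tuple[int, int], ...]  # inclusive lo <= hi


@dataclass(frozen=True)
class Resn:
    names: tuple[str, ...]


@dataclass(frozen=True)
class Name:
    names: tuple[str, ...]


@dataclass(frozen=True)
class Elem:
    symbols: tuple[str, ...]


@dataclass(frozen=True)
class And:
    left: "SelectionAST"
    right: "SelectionAST"


@dataclass(frozen=True)
class Or:
    left: "SelectionAST"
    right: "SelectionAST"


@dataclass(frozen=True)
class Not:
    child: "SelectionAST"


@dataclass(frozen=True)
class Around:
    inner: "SelectionAST"
    radius: float
    byres: bool = False


SelectionAST = (All | NoneSel | Polymer | Hetatm | Chain | Resi | Resn
                | Name | Elem | And | Or | Not | Around)


# ---------------------------------------------------------------------------
# tokenizer + recursive-descent parser

_TOKEN_RE = re.compile(r"\s*(?:(?P<word>[A-Za-z0-9_.'*]+)|(?P<sym>[()+,\-]))")


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None or m.end() == m.start():
            stripped = expr[pos:].lstrip()
            if not stripped:
                break
            offset = len(expr) - len(stripped)
            raise SelectionSyntaxError(
                f"unexpected character {stripped[0]!r}", offset)
        if m.group("word") is not None:
            tokens.append(("word", m.group("word"), m.start("word")))
        else:
            tokens.append(("sym", m.group("sym"), m.start("sym")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of selection",
                                       len(self.expr))
        self.i += 1
        return tok

    def keyword(self) -> str | None:
        tok = self.peek()
        if tok and tok[0] == "word":
            return tok[1].lower()
        return None

    # expr := or
    def parse(self) -> SelectionAST:
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def parse_or(self) -> SelectionAST:
        node = self.parse_and()
        while self.keyword() == "or":
            self.next()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> SelectionAST:
        node = self.parse_around()
        while self.keyword() == "and":
            self.next()
            node = And(node, self.parse_around())
        return node

    def parse_around(self) -> SelectionAST:
        node = self.parse_unary()
        while self.keyword() == "around":
            self.next()
            tok = self.next()
            try:
                radius = float(tok[1])
            except ValueError:
                raise SelectionSyntaxError(
                    f"around needs a numeric radius, got {tok[1]!r}",
                    tok[2]) from None
            if radius < 0:
                raise SelectionSyntaxError("around radius must be >= 0",
                                           tok[2])
            node = Around(node, radius, byres=False)
        return node

    def parse_unary(self) -> SelectionAST:
        kw = self.keyword()
        if kw == "not":
            self.next()
            return Not(self.parse_unary())
        if kw == "byres":
            tok = self.next()
            inner = self.parse_unary_with_around()
            if not isinstance(inner, Around):
                raise SelectionSyntaxError(
                    "byres is only supported on a distance (around) "
                    "selection in this subset", tok[2])
            return Around(inner.inner, inner.radius, byres=True)
        return self.parse_primary()

    def parse_unary_with_around(self) -> SelectionAST:
        # like parse_around but starting below 'byres'
        node = self.parse_unary()
        while self.keyword() == "around":
            self.next()
            tok = self.next()
            try:
                radius = float(tok[1])
            except ValueError:
                raise SelectionSyntaxError(
                    f"around needs a numeric radius, got {tok[1]!r}",
                    tok[2]) from None
            node = Around(node, radius, byres=False)
        return node

    def parse_primary(self) -> SelectionAST:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of selection",
                                       len(self.expr))
        kind, value, offset = tok
        if kind == "sym" and value == "(":
            self.next()
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing[1] != ")":
                raise SelectionSyntaxError("unbalanced parenthesis", offset)
            self.next()
            # parenthesized around keeps byres applicable from outside
            return node
        if kind != "word":
            raise SelectionSyntaxError(f"unexpected token {value!r}", offset)
        kw = value.lower()
        self.next()
        if kw == "all":
            return All()
        if kw == "none":
            return NoneSel()
        if kw == "polymer":
            return Polymer()
        if kw == "hetatm":
            return Hetatm()
        if kw == "chain":
            return Chain(tuple(self._value_list(offset, upper=False)))
        if kw == "resi":
            return Resi(tuple(self._range_list(offset)))
        if kw == "resn":
            return Resn(tuple(self._value_list(offset)))
        if kw == "name":
            return Name(tuple(self._value_list(offset)))
        if kw == "elem":
            return Elem(tuple(self._value_list(offset)))
        if kw in UNSUPPORTED_KEYWORDS:
            raise SelectionSyntaxError(
                f"unsupported selection keyword {kw!r}", offset)
        raise SelectionSyntaxError(f"unknown selection keyword {kw!r}",
                                   offset)

    _RESERVED = {"and", "or", "not", "around", "byres", "all", "none",
                 "polymer", "hetatm", "chain", "resi", "resn", "name",
                 "elem"}

    def _value_items(self, offset: int) -> list[str]:
        """word (+|, word)* — raw item strings."""
        tok = self.peek()
        if tok is None or tok[0] != "word" or tok[1].lower() in self._RESERVED:
            raise SelectionSyntaxError("expected a value list", offset)
        items = [self.next()[1]]
        while True:
            tok = self.peek()
            if tok and tok[0] == "sym" and tok[1] in "+,":
                self.next()
                nxt = self.next()
                if nxt[0] != "word":
                    raise SelectionSyntaxError(
                        f"expected a value after {tok[1]!r}", nxt[2])
                items.append(nxt[1])
            else:
                return items

    def _value_list(self, offset: int, upper: bool = True) -> list[str]:
        items = self._value_items(offset)
        return [it.upper() for it in items] if upper else items

    def _range_list(self, offset: int) -> list[tuple[int, int]]:
        """n or n-m, joined by + or , — inclusive integer ranges."""
        ranges = []
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("expected residue ranges", offset)
        while True:
            tok = self.next()
            if tok[0] != "word" or not tok[1].isdigit():
                raise SelectionSyntaxError(
                    f"expected a residue number, got {tok[1]!r}", tok[2])
            lo = int(tok[1])
            hi = lo
            nxt = self.peek()
            if nxt and nxt[0] == "sym" and nxt[1] == "-":
                self.next()
                tok2 = self.next()
                if tok2[0] != "word" or not tok2[1].isdigit():
                    raise SelectionSyntaxError(
                        f"expected a residue number, got {tok2[1]!r}",
                        tok2[2])
                hi = int(tok2[1])
                if hi < lo:
                    raise SelectionSyntaxError(
                        f"descending residue range {lo}-{hi}", tok2[2])
            ranges.append((lo, hi))
            nxt = self.peek()
            if nxt and nxt[0] == "sym" and nxt[1] in "+,":
                self.next()
                continue
            return ranges


def parse_selection(expr: str) -> SelectionAST:
    """Parse a selection expression into an AST.

    Raises :class:`SelectionSyntaxError` (with character offset) on
    unknown keywords, named unsupported PyMOL keywords, or malformed
    syntax.
    """
    if not expr or not expr.strip():
        raise SelectionSyntaxError("empty selection", 0)
    return _Parser(expr).parse()


# ---------------------------------------------------------------------------
# evaluation

def _expand_byres(indices: set[int], s: Structure) -> set[int]:
    residues = {s.atoms[i].residue_key() for i in indices}
    return {i for i, a in enumerate(s.atoms) if a.residue_key() in residues}


def evaluate_selection(ast: SelectionAST, s: Structure) -> set[int]:
    """Atom-index set selected by ``ast`` on structure ``s``.

    Literal selectors never raise: unmatched names simply yield the
    empty set.  ``around`` selects atoms within the radius of any inner
    atom, excluding the inner atoms themselves; ``byres`` then expands
    partially included residues to all their atoms.
    """
    universe = set(range(len(s.atoms)))
    if isinstance(ast, All):
        return universe
    if isinstance(ast, NoneSel):
        return set()
    if isinstance(ast, Polymer):
        return {i for i in universe if not s.atoms[i].hetero}
    if isinstance(ast, Hetatm):
        return {i for i in universe if s.atoms[i].hetero}
    if isinstance(ast, Chain):
        ids = set(ast.ids)
        return {i for i in universe if s.atoms[i].chain in ids}
    if isinstance(ast, Resi):
        return {i for i in universe
                if any(lo <= s.atoms[i].resseq <= hi
                       for lo, hi in ast.ranges)}
    if isinstance(ast, Resn):
        names = set(ast.names)
        return {i for i in universe if s.atoms[i].resname.upper() in names}
    if isinstance(ast, Name):
        names = set(ast.names)
        return {i for i in universe if s.atoms[i].name.upper() in names}
    if isinstance(ast, Elem):
        symbols = set(ast.symbols)
        return {i for i in universe if s.atoms[i].element.upper() in symbols}
    if isinstance(ast, And):
        return evaluate_selection(ast.left, s) & evaluate_selection(
            ast.right, s)
    if isinstance(ast, Or):
        return evaluate_selection(ast.left, s) | evaluate_selection(
            ast.right, s)
    if isinstance(ast, Not):
        return universe - evaluate_selection(ast.child, s)
    if isinstance(ast, Around):
        inner = evaluate_selection(ast.inner, s)
        if not inner or ast.radius <= 0:
            return set()
        coords = s.coords()
        inner_idx = sorted(inner)
        d = np.linalg.norm(
            coords[:, None, :] - coords[None, inner_idx, :], axis=-1)
        near = set(np.nonzero((d <= ast.radius).any(axis=1))[0].tolist())
        result = near - inner
        if ast.byres:
            result = _expand_byres(result, s)
        return result
    raise TypeError(f"not a selection node: {ast!r}")


# ---------------------------------------------------------------------------
# printer (input grammar) — needed for prolink serialization and tests

def _needs_parens_in_and(node: SelectionAST) -> bool:
    return isinstance(node, Or)


def print_selection(ast: SelectionAST) -> str:
    """Render an AST back to the input grammar; parse∘print is identity."""
    if isinstance(ast, All):
        return "all"
    if isinstance(ast, NoneSel):
        return "none"
    if isinstance(ast, Polymer):
        return "polymer"
    if isinstance(ast, Hetatm):
        return "hetatm"
    if isinstance(ast, Chain):
        return "chain " + "+".join(ast.ids)
    if isinstance(ast, Resi):
        parts = [str(lo) if lo == hi else f"{lo}-{hi}"
                 for lo, hi in ast.ranges]
        return "resi " + "+".join(parts)
    if isinstance(ast, Resn):
        return "resn " + "+".join(ast.names)
    if isinstance(ast, Name):
        return "name " + "+".join(ast.names)
    if isinstance(ast, Elem):
        return "elem " + "+".join(ast.symbols)
    if isinstance(ast, Not):
        child = print_selection(ast.child)
        if isinstance(ast.child, (And, Or, Around)):
            child = f"({child})"
        return f"not {child}"
    if isinstance(ast, And):
        left = print_selection(ast.left)
        right = print_selection(ast.right)
        if _needs_parens_in_and(ast.left):
            left = f"({left})"
        if _needs_parens_in_and(ast.right) or isinstance(ast.right, And):
            right = f"({right})"
        return f"{left} and {right}"
    if isinstance(ast, Or):
        left = print_selection(ast.left)
        right = print_selection(ast.right)
        if isinstance(ast.right, Or):
            right = f"({right})"
        return f"{left} or {right}"
    if isinstance(ast, Around):
        inner = print_selection(ast.inner)
        if isinstance(ast.inner, (And, Or, Not, Around)):
            inner = f"({inner})"
        core = f"({inner} around {ast.radius!r})"
        return f"byres {core}" if ast.byres else core
    raise TypeError(f"not a selection node: {ast!r}")


# ---------------------------------------------------------------------------
# transpiler to the browser-viewer (NGL) dialect

def to_viewer_selection(ast: SelectionAST) -> str:
    """Emit the NGL selection-dialect string for ``ast``.

    ``around`` nodes have no dialect equivalent in the supported subset;
    resolve them first with :func:`resolve_around`.
    """
    if isinstance(ast, Around):
        raise UnresolvedDistanceError(
            "unresolved distance selection: apply resolve_around() before "
            "transpiling")
    if isinstance(ast, All):
        return "*"
    if isinstance(ast, NoneSel):
        return "none"
    if isinstance(ast, Polymer):
        return "polymer"
    if isinstance(ast, Hetatm):
        return "hetero"
    if isinstance(ast, Chain):
        return _join_or([f":{c}" for c in ast.ids])
    if isinstance(ast, Resi):
        return _join_or([str(lo) if lo == hi else f"{lo}-{hi}"
                         for lo, hi in ast.ranges])
    if isinstance(ast, Resn):
        return _join_or([f"[{n}]" if len(n) > 3 else n for n in ast.names])
    if isinstance(ast, Name):
        return _join_or([f".{n}" for n in ast.names])
    if isinstance(ast, Elem):
        return _join_or([f"_{e}" for e in ast.symbols])
    if isinstance(ast, Not):
        return f"not {_viewer_operand(ast.child)}"
    if isinstance(ast, And):
        return (f"{_viewer_operand(ast.left)} and "
                f"{_viewer_operand(ast.right)}")
    if isinstance(ast, Or):
        return (f"{_viewer_operand(ast.left)} or "
                f"{_viewer_operand(ast.right)}")
    raise TypeError(f"not a selection node: {ast!r}")


def _viewer_operand(node: SelectionAST) -> str:
    text = to_viewer_selection(node)
    if isinstance(node, (And, Or)) or " or " in text:
        return f"({text})"
    return text


def _join_or(parts: list[str]) -> str:
    if len(parts) == 1:
        return parts[0]
    return "(" + " or ".join(parts) + ")"


# ---------------------------------------------------------------------------
# around resolution

def _runs(numbers: list[int]) -> list[tuple[int, int]]:
    """Merge a sorted list of ints into inclusive (lo, hi) runs."""
    runs: list[tuple[int, int]] = []
    for n in sorted(set(numbers)):
        if runs and n == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], n)
        else:
            runs.append((n, n))
    return runs


def _or_fold(nodes: list[SelectionAST]) -> SelectionAST:
    node = nodes[0]
    for nxt in nodes[1:]:
        node = Or(node, nxt)
    return node


def resolve_around(ast: SelectionAST, s: Structure) -> SelectionAST:
    """Rewrite every ``around`` node as an explicit enumeration.

    ``byres`` nodes become per-chain ``chain C and resi …`` unions;
    plain nodes enumerate individual atoms as
    ``chain C and resi N and name X``.  Evaluation is invariant under
    the rewrite; an empty neighborhood becomes ``none``.
    """
    if isinstance(ast, Around):
        selected = evaluate_selection(ast, s)
        if not selected:
            return NoneSel()
        if ast.byres:
            by_chain: dict[str, list[int]] = {}
            for key in sorted({s.atoms[i].residue_key() for i in selected}):
                by_chain.setdefault(key[0], []).append(key[1])
            parts = [And(Chain((chain,)), Resi(tuple(_runs(nums))))
                     for chain, nums in sorted(by_chain.items())]
            return _or_fold(parts)
        parts = []
        for i in sorted(selected):
            a = s.atoms[i]
            parts.append(And(Chain((a.chain,)),
                             And(Resi(((a.resseq, a.resseq),)),
                                 Name((a.name.upper(),)))))
        return _or_fold(parts)
    if isinstance(ast, Not):
        return Not(resolve_around(ast.child, s))
    if isinstance(ast, And):
        return And(resolve_around(ast.left, s), resolve_around(ast.right, s))
    if isinstance(ast, Or):
        return Or(resolve_around(ast.left, s), resolve_around(ast.right, s))
    return ast
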