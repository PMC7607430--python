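"""Boolean constraint expressions attached to reaction rules.

A constraint cell is a disjunction (``or``) of conjunctions (``&``) of
atoms; ``!`` (legacy ``~``) negates an atom. Atoms are either

* pattern atoms — true when the pattern occurs in the glycan; when the
  pattern carries a reaction-site anchor (``@``, legacy ``*``) the atom is
  true only for a match whose site lands exactly on the rule's computed
  reaction site;
* residue-count atoms — ``nA=0`` / legacy ``#A = 0`` / IUPAC-style
  ``nMan(a1-?)>4``, comparing a residue count against an integer;
* macro references — bare names (e.g. ``Gnbis`` for the bisecting-GlcNAc
  motif) expanded from a macro table before evaluation.

Precedence is fixed: ``!`` binds tightest, then ``&``, then ``or``. There
is no parenthesized grouping — parentheses are glycan syntax — so grouping
is achieved by splitting rules (see :func:`atomize_disjunction`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core_model import Glycan, LicorriceSelector, count_residues, _check_dialect
from .errors import LicorrError, ParseError
from .pattern_engine import (
    Pattern,
    Subject,
    find_matches,
    parse_pattern,
)
from .registry import Registry, default_registry

# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Empty:
    """Blank constraint cell: always true."""


@dataclass(frozen=True)
class Not:
    child: object


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass
class PatternAtom:
    pattern: Pattern
    anchored: bool = False

    def __eq__(self, other):
        return (
            isinstance(other, PatternAtom)
            and self.anchored == other.anchored
            and pattern_signature(self.pattern) == pattern_signature(other.pattern)
        )

    def __hash__(self):
        return hash((pattern_signature(self.pattern), self.anchored))


@dataclass(frozen=True)
class CountAtom:
    selector: object  # lc_code str | LicorriceSelector
    cmp: str  # "=", "<", ">", "<=", ">="
    value: int


@dataclass(frozen=True)
class MacroRef:
    name: str


def pattern_signature(p: Pattern) -> tuple:
    """Dialect-independent structural fingerprint of a pattern (the glyph a
    wildcard was written with does not matter)."""
    out = []
    for t in p.tokens:
        if t.su is not None:
            out.append((t.kind, t.su.serialize()))
        elif t.kind == "RAW":
            out.append((t.kind, t.text))
        else:
            out.append((t.kind, ""))
    return tuple(out)


def constraint_signature(e) -> tuple:
    if isinstance(e, Empty):
        return ("EMPTY",)
    if isinstance(e, Not):
        return ("NOT", constraint_signature(e.child))
    if isinstance(e, And):
        return ("AND",) + tuple(constraint_signature(c) for c in e.children)
    if isinstance(e, Or):
        return ("OR",) + tuple(constraint_signature(c) for c in e.children)
    if isinstance(e, PatternAtom):
        return ("PATTERN", pattern_signature(e.pattern), e.anchored)
    if isinstance(e, CountAtom):
        return ("COUNT", repr(e.selector), e.cmp, e.value)
    if isinstance(e, MacroRef):
        return ("MACRO", e.name)
    raise TypeError(f"not a constraint expression: {e!r}")


# ---------------------------------------------------------------------------
# Macros
# ---------------------------------------------------------------------------


class MacroTable(dict):
    """name -> pattern text; names may reference other macros textually."""

    def expand_text(self, name: str, _seen: tuple = ()) -> str:
        if name in _seen:
            raise LicorrError(f"recursive macro {name!r}: {' -> '.join(_seen + (name,))}")
        try:
            text = self[name]
        except KeyError:
            raise LicorrError(f"unknown macro {name!r}") from None
        for other in sorted(self, key=len, reverse=True):
            if other in text:
                text = text.replace(other, self.expand_text(other, _seen + (name,)))
        return text


def default_macro_table() -> MacroTable:
    # Gnbis: the bisecting GlcNAc on the core mannose
    return MacroTable(Gnbis="Ma3(GNb4)(...Ma6)Mb4")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# residue-count atoms; both the "n" and legacy "#" spellings are accepted in
# every dialect (published tables mix them), emission is per dialect
_COUNT_RE = re.compile(
    r"^[n#]\s*([A-Za-z][A-Za-z0-9]*)\s*(?:\(\s*([abαβ?])\s*(\d)?\s*-\s*([\d?])\s*\))?"
    r"\s*(<=|>=|=|<|>)\s*(\d+)$"
)
_MACRO_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")
_GREEK = {"α": "a", "β": "b"}


def _parse_atom(text: str, dialect: str, registry: Registry):
    neg_symbol = "!" if dialect == "licorr" else "~"
    negated = False
    text = text.strip()
    while text.startswith(neg_symbol):
        negated = not negated
        text = text[len(neg_symbol) :].strip()
    if not text:
        raise ParseError("dangling operator in constraint", 0, "E_CONSTRAINT")
    atom = None
    m = _COUNT_RE.match(text)
    if m:
        name, anomer, _ac, pos, cmp_, value = m.groups()
        anomer = _GREEK.get(anomer, anomer)
        if anomer is None and registry.has_monosaccharide(name):
            selector = name
        else:
            # IUPAC-condensed selector; fall back to a Linear Code that has
            # an IUPAC reading (nMan and nM both select mannose)
            if registry.has_monosaccharide(name):
                name = registry.monosaccharide(name).iupac_name
            else:
                registry.by_iupac(name)  # raises if unknown
            position = None if pos in (None, "?") else int(pos)
            selector = LicorriceSelector(name, anomer, position)
        atom = CountAtom(selector, cmp_, int(value))
    else:
        try:
            pattern = parse_pattern(text, dialect, registry)
            atom = PatternAtom(pattern, anchored=pattern.has_site())
        except (ParseError, LicorrError):
            if _MACRO_NAME_RE.match(text):
                atom = MacroRef(text)
            else:
                raise
    return Not(atom) if negated else atom


def parse_constraint(
    text: str, dialect: str = "licorr", registry: Registry | None = None
):
    """Parse a constraint cell; blank input is the always-true Empty."""
    _check_dialect(dialect)
    registry = registry or default_registry()
    text = (text or "").strip().replace("…", "...")
    if not text:
        return Empty()
    disjuncts = []
    for part in re.split(r"\bor\b", text):
        part = part.strip()
        if not part:
            raise ParseError("dangling 'or' in constraint", 0, "E_CONSTRAINT")
        conjuncts = []
        for atom_text in part.split("&"):
            conjuncts.append(_parse_atom(atom_text, dialect, registry))
        disjuncts.append(
            conjuncts[0] if len(conjuncts) == 1 else And(tuple(conjuncts))
        )
    return disjuncts[0] if len(disjuncts) == 1 else Or(tuple(disjuncts))


# ---------------------------------------------------------------------------
# Macro expansion
# ---------------------------------------------------------------------------


def expand_macros(e, table: MacroTable | None = None, dialect: str = "licorr",
                  registry: Registry | None = None):
    """Replace every MacroRef with the pattern atom its text parses to.

    Idempotent once fully expanded; unknown or recursive macros raise."""
    table = table if table is not None else default_macro_table()
    registry = registry or default_registry()
    if isinstance(e, MacroRef):
        pattern = parse_pattern(table.expand_text(e.name), dialect, registry)
        return PatternAtom(pattern, anchored=pattern.has_site())
    if isinstance(e, Not):
        return Not(expand_macros(e.child, table, dialect, registry))
    if isinstance(e, And):
        return And(tuple(expand_macros(c, table, dialect, registry) for c in e.children))
    if isinstance(e, Or):
        return Or(tuple(expand_macros(c, table, dialect, registry) for c in e.children))
    return e


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(
    e,
    g: Glycan,
    site_index: int | None = None,
    registry: Registry | None = None,
    macros: MacroTable | None = None,
) -> bool:
    """Evaluate a constraint against a glycan and an optional reaction site.

    A non-anchored pattern atom is a global presence test; an anchored atom
    requires some match to place its site marker exactly at ``site_index``
    in the sentineled canonical string (error if no site is supplied).
    """
    registry = registry or default_registry()
    subject = Subject.from_glycan(g, registry)
    return _eval(expand_macros(e, macros, registry=registry), g, subject,
                 site_index, registry)


def _eval(e, g, subject, site_index, registry) -> bool:
    if isinstance(e, Empty):
        return True
    if isinstance(e, Not):
        return not _eval(e.child, g, subject, site_index, registry)
    if isinstance(e, And):
        return all(_eval(c, g, subject, site_index, registry) for c in e.children)
    if isinstance(e, Or):
        return any(_eval(c, g, subject, site_index, registry) for c in e.children)
    if isinstance(e, PatternAtom):
        matches = find_matches(e.pattern, subject, registry)
        if not e.anchored:
            return bool(matches)
        if site_index is None:
            raise LicorrError(
                "site-anchored constraint evaluated without a reaction site"
            )
        return any(m.site_index == site_index for m in matches)
    if isinstance(e, CountAtom):
        count = count_residues(g, e.selector, registry)
        return {
            "=": count == e.value,
            "<": count < e.value,
            ">": count > e.value,
            "<=": count <= e.value,
            ">=": count >= e.value,
        }[e.cmp]
    if isinstance(e, MacroRef):
        raise LicorrError(f"unexpanded macro {e.name!r}")
    raise TypeError(f"not a constraint expression: {e!r}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def atomize_disjunction(e) -> list:
    """Distribute top-level disjunction into a list of or-free expressions
    (the rule-splitting normal form); AND-of-OR expands distributively."""
    if isinstance(e, Or):
        return [x for c in e.children for x in atomize_disjunction(c)]
    if isinstance(e, And):
        import itertools

        parts = [atomize_disjunction(c) for c in e.children]
        out = []
        for combo in itertools.product(*parts):
            flat = []
            for c in combo:
                flat.extend(c.children if isinstance(c, And) else [c])
            out.append(And(tuple(flat)) if len(flat) > 1 else flat[0])
        return out
    return [e]


def unparse_constraint(e, dialect: str = "licorr") -> str:
    """Render an expression back to cell text in the given dialect."""
    neg = "!" if dialect == "licorr" else "~"
    num = "n" if dialect == "licorr" else "#"
    if isinstance(e, Empty):
        return ""
    if isinstance(e, Not):
        return neg + unparse_constraint(e.child, dialect)
    if isinstance(e, And):
        return " & ".join(unparse_constraint(c, dialect) for c in e.children)
    if isinstance(e, Or):
        return " or ".join(unparse_constraint(c, dialect) for c in e.children)
    if isinstance(e, PatternAtom):
        return e.pattern.source_text
    if isinstance(e, CountAtom):
        if isinstance(e.selector, LicorriceSelector):
            sel = e.selector
            pos = "?" if sel.position is None else sel.position
            anomer = sel.anomer or "?"
            return f"n{sel.iupac_name}({anomer}1-{pos}){e.cmp}{e.value}"
        return f"{num}{e.selector}{e.cmp}{e.value}"
    if isinstance(e, MacroRef):
        return e.name
    raise TypeError(f"not a constraint expression: {e!r}")


__all__ = [
    "Empty",
    "Not",
    "And",
    "Or",
    "PatternAtom",
    "CountAtom",
    "MacroRef",
    "MacroTable",
    "default_macro_table",
    "pattern_signature",
    "constraint_signature",
    "parse_constraint",
    "expand_macros",
    "evaluate",
    "atomize_disjunction",
    "unparse_constraint",
]
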