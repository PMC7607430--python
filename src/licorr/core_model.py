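"""Glycan data model, Linear Code parser, and canonical serializer.

A glycan is a rooted tree of saccharide units (SUs). The string form reads
from the non-reducing termini (left) to the reducing end (right): each SU
attaches to the next SU on its right, and parenthesized groups are branches
hanging off that same SU. ``Ab3(Fa4)GNb`` is a GlcNAc root carrying a
galactose at carbon 3 and a fucose at carbon 4.

Canonical form follows the consensus branching rule: among the children of a
node, the chain attached at the *lowest* carbon stays on the unparenthesized
backbone and the remaining chains branch in ascending attachment order, so
positions decrease right-to-left from the parent. Abstract schematic glycans
(letters with no linkage data) keep their written order — there is nothing
to sort on.

The parser is structure-preserving: non-canonical input is accepted and
:func:`validate` reports canonicality as a warning, not an error.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field

from .errors import Diagnostic, ParseError, UnsupportedFeatureError
from .registry import (
    UNKNOWN_MS,
    UNKNOWN_SU,
    Registry,
    default_registry,
)

DIALECTS = ("licorr", "legacy", "olc")

_CONJUGATE_SEPS = ";:#"
_STEREO_MARKS = "'^~"


def _check_dialect(dialect: str) -> str:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return dialect


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modification:
    """Positions plus a modification code; ``positions=()`` means unstated."""

    positions: tuple = ()
    code: str = ""

    def serialize(self) -> str:
        pos = ",".join(str(p) for p in self.positions)
        return f"{pos}{self.code}"


@dataclass
class SaccharideUnit:
    """One monosaccharide with its linkage and decorations.

    ``ms`` is the Linear Code monosaccharide ("GN"), ``"*"`` for a wholly
    unknown SU, or ``"?"`` for an unknown identity within a partly known SU.
    ``link_position`` is the carbon on the *parent* by which this SU is
    attached (int, ``"?"`` unknown, or None on the reducing-end root and in
    abstract notation).
    """

    ms: str
    ms_alts: tuple = ()            # "/" alternatives for the identity
    stereo_ring: str = ""          # "", "'", "^", "~"
    modifications: tuple = ()      # tuple[Modification]
    possible_mod: object = None    # None | "ANY" | tuple[Modification]
    anomer: str | None = None      # "a" | "b" | "?" | None
    link_position: object = None   # int | "?" | None
    pos_alts: tuple = ()           # "/" alternatives for the position
    open_form: bool = False
    su_alternatives: tuple = ()    # "//" alternatives (whole-SU)
    cyclic_tail: bool = False      # repeat-rule "c" flag
    head_marker: bool = False      # repeat-rule "-X-" flag
    fragment_markers: tuple = ()   # UR-style "i%" markers preceding this SU

    def serialize(self) -> str:
        parts = []
        for idx in self.fragment_markers:
            parts.append(f"{idx}%")
        if self.head_marker:
            parts.append("-")
        parts.append(self.ms)
        for alt in self.ms_alts:
            parts.append(f"/{alt}")
        if self.cyclic_tail:
            parts.append("c")
        parts.append(self.stereo_ring)
        if self.modifications:
            mods = sorted(
                self.modifications,
                key=lambda m: (m.positions[:1] or (99,), m.code),
            )
            parts.append("[" + ",".join(m.serialize() for m in mods) + "]")
        if self.possible_mod is not None:
            parts.append("$")
            if self.possible_mod != "ANY":
                parts.append(
                    "[" + ",".join(m.serialize() for m in self.possible_mod) + "]"
                )
        if self.anomer is not None:
            parts.append(self.anomer)
        if self.open_form:
            parts.append("o")
        elif self.link_position is not None:
            parts.append(str(self.link_position))
            for alt in self.pos_alts:
                if alt != self.link_position:
                    parts.append(f"/{alt}")
        if self.head_marker:
            parts.append("-")
        return "".join(parts)

    def effective_position(self):
        """Sort key helper: the position, or the first "/" alternative."""
        if isinstance(self.link_position, int):
            return self.link_position
        return None


@dataclass
class GlycanNode:
    su: SaccharideUnit
    children: list = field(default_factory=list)

    def iter_nodes(self):
        for child in self.children:
            yield from child.iter_nodes()
        yield self


@dataclass
class Glycan:
    """Rooted SU tree plus conjugate, fragment, and repeat annotations."""

    root: GlycanNode
    conjugate: tuple | None = None       # (separator, text)
    fragments: tuple = ()                # tuple[(index, Glycan)]
    repeat: object = None                # None | int | "n"

    def iter_nodes(self):
        return self.root.iter_nodes()

    def copy(self) -> "Glycan":
        return copy.deepcopy(self)

    def canonical(self) -> str:
        return serialize_glycan(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return serialize_glycan(self)


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------


@dataclass
class SUToken:
    """A lexed SU with absolute character spans for each element.

    Spans (half-open, absolute offsets) are used by the pattern engine for
    element-aligned prefix matching against canonical strings.
    """

    su: SaccharideUnit
    start: int
    end: int
    spans: dict  # element name -> (start, end)


def lex_su(text: str, i: int, registry: Registry, base: int = 0) -> SUToken:
    """Lex one saccharide unit starting at ``text[i]``.

    Raises :class:`ParseError` (offset ``base + i``) when no SU starts here.
    """
    start = i
    spans: dict = {}
    markers = []
    m = re.match(r"(\d+)%", text[i:])
    while m:
        markers.append(int(m.group(1)))
        i += m.end()
        m = re.match(r"(\d+)%", text[i:])
    su = SaccharideUnit(ms="", fragment_markers=tuple(markers))

    # monosaccharide identity
    ms_start = i
    if i < len(text) and text[i] == UNKNOWN_SU:
        su.ms = UNKNOWN_SU
        i += 1
        spans["ms"] = (ms_start, i)
        su.fragment_markers = tuple(markers)
        return SUToken(su, start, i, spans)
    if i < len(text) and text[i] == UNKNOWN_MS:
        su.ms = UNKNOWN_MS
        i += 1
    else:
        for code in registry.codes_by_length:
            if text.startswith(code, i):
                su.ms = code
                i += len(code)
                break
        else:
            raise ParseError(
                f"unknown monosaccharide code at {text[i:i + 3]!r}",
                base + i,
                "E_UNKNOWN_MS",
            )
    # "/" identity alternatives (e.g. "A/G"): slash followed by a code
    alts = []
    while text.startswith("/", i) and not text.startswith("//", i):
        matched = None
        for code in registry.codes_by_length:
            if text.startswith(code, i + 1):
                matched = code
                break
        if matched is None:
            break  # slash belongs to a position alternative or is stray
        alts.append(matched)
        i += 1 + len(matched)
    su.ms_alts = tuple(alts)
    spans["ms"] = (ms_start, i)

    if text.startswith("c", i):  # repeat-rule tail flag
        su.cyclic_tail = True
        i += 1

    if i < len(text) and text[i] in _STEREO_MARKS:
        spans["stereo"] = (i, i + 1)
        su.stereo_ring = text[i]
        i += 1

    if text.startswith("[", i):
        mods, j = _lex_mod_bracket(text, i, registry, base)
        spans["mods"] = (i, j)
        su.modifications = mods
        i = j

    if text.startswith("$", i):
        pm_start = i
        i += 1
        if text.startswith("[", i):
            mods, j = _lex_mod_bracket(text, i, registry, base)
            su.possible_mod = mods
            i = j
        else:
            su.possible_mod = "ANY"
        spans["possible_mod"] = (pm_start, i)

    if i < len(text) and text[i] in "ab?":
        spans["anomer"] = (i, i + 1)
        su.anomer = text[i]
        i += 1

    if i < len(text) and text[i] == "o":
        su.open_form = True
        i += 1
    elif i < len(text) and (text[i].isdigit() or text[i] == "?"):
        if su.anomer is None and su.ms != UNKNOWN_MS:
            raise ParseError(
                "linkage position without anomer context", base + i, "E_POSITION"
            )
        pos_start = i
        su.link_position = int(text[i]) if text[i].isdigit() else "?"
        i += 1
        palts = [su.link_position]
        while text.startswith("/", i) and not text.startswith("//", i) and \
                i + 1 < len(text) and text[i + 1].isdigit():
            palts.append(int(text[i + 1]))
            i += 2
        if len(palts) > 1:
            su.pos_alts = tuple(palts)
        spans["position"] = (pos_start, i)

    # "//" whole-SU alternatives
    su_alts = []
    while text.startswith("//", i):
        alt_tok = lex_su(text, i + 2, registry, base)
        su_alts.append(alt_tok.su)
        i = alt_tok.end
    su.su_alternatives = tuple(su_alts)

    return SUToken(su, start, i, spans)


def _lex_mod_bracket(text: str, i: int, registry: Registry, base: int):
    """Lex ``[...]``: comma-separated items; positions accumulate until a
    modification code consumes them (``[2,6D]`` = deoxy at carbons 2 and 6)."""
    close = text.find("]", i)
    if close < 0:
        raise ParseError("unterminated modification bracket", base + i, "E_BRACKET")
    inner = text[i + 1 : close]
    mods = []
    pending: list = []
    for item in inner.split(","):
        item = item.strip()
        m = re.fullmatch(r"(\d+|\?)?([A-Z]+)?", item)
        if not m or (m.group(1) is None and m.group(2) is None):
            raise ParseError(
                f"bad modification item {item!r}", base + i, "E_MODIFICATION"
            )
        if m.group(1) is not None:
            pending.append(int(m.group(1)) if m.group(1).isdigit() else "?")
        if m.group(2) is not None:
            code = m.group(2)
            registry.modification(code)  # raises RegistryError if unknown
            mods.append(Modification(tuple(pending), code))
            pending = []
    if pending:
        raise ParseError(
            "modification positions without a code", base + i, "E_MODIFICATION"
        )
    return tuple(mods), close + 1


def tokenize_glycan_body(text: str, registry: Registry, base: int = 0):
    """Flat lexing of a glycan body into '(' / ')' / SUToken items.

    Used by the pattern engine to address canonical strings token-by-token.
    """
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "()":
            tokens.append((ch, base + i, base + i + 1, None))
            i += 1
        elif ch == "-":
            i += 1  # repeat head-marker dash: structurally transparent
        else:
            tok = lex_su(text, i, registry, base)
            i = tok.end
            if base:
                tok = SUToken(
                    su=tok.su,
                    start=base + tok.start,
                    end=base + tok.end,
                    spans={k: (a + base, b + base) for k, (a, b) in tok.spans.items()},
                )
            tokens.append(("SU", tok.start, tok.end, tok))
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------


def _split_conjugate(text: str):
    """Split off a glycoconjugate at the last top-level ';', ':' or '#'."""
    depth = 0
    last = -1
    for i, ch in enumerate(text):
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth -= 1
        elif depth == 0 and ch in _CONJUGATE_SEPS:
            last = i
    if last < 0:
        return text, None
    return text[:last], (text[last], text[last + 1 :])


def _split_fragments(text: str, registry: Registry, dialect: str):
    """Split UR-style fragment definitions (``FRAG=1%|``) from the core."""
    depth = 0
    cuts = [-1]
    for i, ch in enumerate(text):
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth -= 1
        elif depth == 0 and ch == "|":
            cuts.append(i)
    if len(cuts) == 1:
        return text, (), 0
    segments = []
    for a, b in zip(cuts, cuts[1:] + [len(text)]):
        segments.append((text[a + 1 : b], a + 1))
    core, core_base = segments[-1]
    fragments = []
    for seg, seg_base in segments[:-1]:
        m = re.fullmatch(r"(.+)=(\d+)%", seg)
        if not m:
            raise ParseError(
                "fragment definition must look like FRAG=<index>%",
                seg_base,
                "E_FRAGMENT",
            )
        frag = parse_glycan(m.group(1), dialect=dialect, registry=registry)
        fragments.append((int(m.group(2)), frag))
    return core, tuple(fragments), core_base


def _parse_chain(text: str, i: int, registry: Registry, base: int, depth: int):
    """Parse one chain; returns (root GlycanNode, index after the chain)."""
    pending: list[GlycanNode] = []
    last_was_su = False
    marker_mode = False
    while i < len(text) and text[i] != ")":
        ch = text[i]
        if ch == "(":
            child, i = _parse_chain(text, i + 1, registry, base, depth + 1)
            if i >= len(text) or text[i] != ")":
                raise ParseError("unbalanced parenthesis", base + i, "E_PAREN")
            i += 1
            pending.append(child)
            last_was_su = False
        elif ch == "-":
            marker_mode = not marker_mode
            i += 1
        else:
            tok = lex_su(text, i, registry, base)
            if marker_mode:
                tok.su.head_marker = True
            node = GlycanNode(tok.su, children=pending)
            pending = [node]
            i = tok.end
            last_was_su = True
    if not pending:
        raise ParseError("empty branch", base + i, "E_EMPTY_BRANCH")
    if not last_was_su:
        raise ParseError(
            "chain must end with a saccharide unit", base + i, "E_DANGLING_BRANCH"
        )
    return pending[0], i


def parse_glycan(
    text: str,
    dialect: str = "licorr",
    registry: Registry | None = None,
) -> Glycan:
    """Parse a Linear Code / LiCoRR glycan string into a :class:`Glycan`.

    The parse is structure-preserving: branch order and modification order
    are kept as written. Raises :class:`ParseError` with a character offset
    on malformed input.
    """
    _check_dialect(dialect)
    registry = registry or default_registry()
    stripped = text.strip()
    if not stripped:
        raise ParseError("empty glycan string", 0, "E_EMPTY")
    # unicode ellipsis never appears in concrete glycans; normalize anyway
    stripped = stripped.replace("…", "...")

    repeat = None
    body = stripped
    base = 0
    if body.startswith("{") and body.endswith("}"):
        inner = body[1:-1]
        m = re.match(r"(n|\d+)", inner)
        if not m:
            raise ParseError("repeat needs a count prefix", 1, "E_REPEAT")
        repeat = m.group(1) if m.group(1) == "n" else int(m.group(1))
        body = inner[m.end() :]
        base = 1 + m.end()

    body, conjugate = _split_conjugate(body)
    if not body:
        raise ParseError("glycan part is empty", 0, "E_EMPTY")
    core, fragments, core_base = _split_fragments(body, registry, dialect)

    root, end = _parse_chain(core, 0, registry, base + core_base, 0)
    if end != len(core):
        raise ParseError("unbalanced parenthesis", base + core_base + end, "E_PAREN")
    return Glycan(root=root, conjugate=conjugate, fragments=fragments, repeat=repeat)


# ---------------------------------------------------------------------------
# Canonical serialization
# ---------------------------------------------------------------------------


def _child_sort_key(node: GlycanNode):
    """Ascending attachment position; unknown ('?') last with a lexicographic
    tie-break; position-free (abstract) children keep document order."""
    pos = node.su.effective_position()
    if pos is not None:
        return (0, pos, "")
    if node.su.link_position == "?" or node.su.pos_alts:
        return (1, 0, _serialize_node(node, canonical=True))
    return (2, 0, "")


def _serialize_node(node: GlycanNode, canonical: bool = True) -> str:
    children = node.children
    if canonical:
        children = sorted(children, key=_child_sort_key)
    parts = []
    if children:
        parts.append(_serialize_node(children[0], canonical))
        for child in children[1:]:
            parts.append("(" + _serialize_node(child, canonical) + ")")
    parts.append(node.su.serialize())
    return "".join(parts)


def serialize_glycan(g: Glycan, canonical: bool = True) -> str:
    """Canonical string form: lowest-position child on the backbone, the
    remaining branches parenthesized in ascending position order."""
    body = _serialize_node(g.root, canonical)
    prefix = "".join(
        f"{serialize_glycan(frag, canonical)}={idx}%|" for idx, frag in g.fragments
    )
    out = prefix + body
    if g.repeat is not None:
        out = "{" + str(g.repeat) + out + "}"
    if g.conjugate is not None:
        out += g.conjugate[0] + g.conjugate[1]
    return out


def canonicalize(text: str, dialect: str = "licorr", registry: Registry | None = None) -> str:
    return serialize_glycan(parse_glycan(text, dialect, registry))


def strip_conjugate(g: Glycan) -> tuple[Glycan, tuple | None]:
    """Return (glycan without conjugate, conjugate annotation)."""
    if g.conjugate is None:
        return g, None
    bare = Glycan(root=g.root, conjugate=None, fragments=g.fragments, repeat=g.repeat)
    return bare, g.conjugate


# ---------------------------------------------------------------------------
# Structural utilities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LicorriceSelector:
    """Residue+linkage selector in IUPAC-condensed terms, e.g. Man(a1-?).

    ``anomer`` / ``position`` of None (or "?") match anything.
    """

    iupac_name: str
    anomer: str | None = None
    position: object = None


def count_residues(g: Glycan, selector=None, registry: Registry | None = None) -> int:
    """Count SUs in the core tree matching ``selector``.

    ``selector`` may be None (count everything, unknown SUs included), a
    Linear Code monosaccharide code (exact identity: "A" never counts "AN"),
    or a :class:`LicorriceSelector`. Fragments and conjugates are not
    counted; a repeat unit is counted once.
    """
    registry = registry or default_registry()
    if selector is None:
        return sum(1 for _ in g.iter_nodes())
    if isinstance(selector, str):
        registry.monosaccharide(selector)  # unregistered selector -> error
        return sum(1 for n in g.iter_nodes() if n.su.ms == selector)
    if isinstance(selector, LicorriceSelector):
        entry = registry.by_iupac(selector.iupac_name)
        count = 0
        for n in g.iter_nodes():
            if n.su.ms != entry.lc_code:
                continue
            if selector.anomer not in (None, "?") and n.su.anomer != selector.anomer:
                continue
            if selector.position not in (None, "?") and n.su.link_position != selector.position:
                continue
            count += 1
        return count
    raise TypeError(f"unsupported selector {selector!r}")


def enumerate_alternatives(g: Glycan, registry: Registry | None = None) -> list[Glycan]:
    """Cartesian expansion of "/", "//" and fragment-placement uncertainty.

    Output order is deterministic: choice points in document order, the
    leftmost option first; duplicates are removed after canonicalization.
    """
    registry = registry or default_registry()
    work = g.copy()

    choices = []  # (kind, path, options)

    def node_path(root: GlycanNode):
        """Document-order paths (string order: backbone, branches, node)."""
        out = []

        def rec(node, path):
            for ci, child in enumerate(node.children):
                rec(child, path + (ci,))
            out.append(path)

        rec(root, ())
        return out

    paths = node_path(work.root)

    def get_node(root, path):
        node = root
        for ci in path:
            node = node.children[ci]
        return node

    for path in paths:
        su = get_node(work.root, path).su
        if su.ms_alts:
            choices.append(("ms", path, (su.ms,) + su.ms_alts))
        if su.pos_alts:
            choices.append(("pos", path, su.pos_alts))
        if su.su_alternatives:
            base_su = copy.deepcopy(su)
            base_su.su_alternatives = ()
            choices.append(("su", path, (base_su,) + su.su_alternatives))
    for idx, frag in work.fragments:
        marked = [p for p in paths if idx in get_node(work.root, p).su.fragment_markers]
        if not marked:
            raise ParseError(
                f"fragment {idx} has no marker in the core", 0, "E_FRAGMENT"
            )
        choices.append(("frag", idx, tuple(marked)))

    if not choices:
        out = parse_glycan(serialize_glycan(work), registry=registry)
        return [out]

    import itertools

    results = []
    seen = set()
    for combo in itertools.product(*(opts for _, _, opts in choices)):
        variant = work.copy()
        for (kind, key, _), choice in zip(choices, combo):
            if kind == "ms":
                get_node(variant.root, key).su.ms = choice
                get_node(variant.root, key).su.ms_alts = ()
            elif kind == "pos":
                su = get_node(variant.root, key).su
                su.link_position = choice
                su.pos_alts = ()
            elif kind == "su":
                node = get_node(variant.root, key)
                new_su = copy.deepcopy(choice)
                new_su.su_alternatives = ()
                node.su = new_su
            elif kind == "frag":
                frag = dict(variant.fragments)[key]
                target = get_node(variant.root, choice)
                target.children.append(frag.copy().root)
        # clear fragment bookkeeping
        variant.fragments = ()
        for node in variant.iter_nodes():
            node.su.fragment_markers = ()
        text = serialize_glycan(variant)
        if text not in seen:
            seen.add(text)
            results.append(parse_glycan(text, registry=registry))
    return results


def alternative_count(g: Glycan) -> int:
    """Product of per-choice cardinalities before deduplication."""
    n = 1
    for node in g.iter_nodes():
        if node.su.ms_alts:
            n *= 1 + len(node.su.ms_alts)
        if node.su.pos_alts:
            n *= len(node.su.pos_alts)
        if node.su.su_alternatives:
            n *= 1 + len(node.su.su_alternatives)
    for idx, _ in g.fragments:
        n *= sum(
            1 for node in g.iter_nodes() if idx in node.su.fragment_markers
        )
    return n


def expand_repeats(g: Glycan, n: int, registry: Registry | None = None) -> Glycan:
    """Concatenate a repeat unit ``n`` times head-to-tail.

    The trailing attachment position of the final (reducing-end) unit is
    dropped since it has nothing to attach to. Cyclic ("c") and head-marked
    ("-X-") units have under-specified connection semantics and are refused.
    """
    registry = registry or default_registry()
    if g.repeat is None:
        return g
    if n < 1:
        raise ValueError("repeat count must be >= 1")
    for node in g.iter_nodes():
        if node.su.cyclic_tail:
            raise UnsupportedFeatureError("cyclic repeat expansion is not supported")
        if node.su.head_marker:
            raise UnsupportedFeatureError(
                "head-marked repeat expansion is not supported"
            )
    unit = Glycan(root=g.root, conjugate=None, fragments=g.fragments, repeat=None)
    unit_text = serialize_glycan(unit)
    final = re.sub(r"\d(/\d)*$", "", unit_text)
    text = unit_text * (n - 1) + final
    out = parse_glycan(text, registry=registry)
    out.conjugate = g.conjugate
    return out


def validate(
    text: str, dialect: str = "licorr", registry: Registry | None = None
) -> list[Diagnostic]:
    """Machine-readable diagnostics; empty iff the string parses and is
    already canonical. Non-canonical form is a warning, not an error."""
    _check_dialect(dialect)
    try:
        g = parse_glycan(text, dialect, registry)
    except ParseError as exc:
        return [Diagnostic(exc.code, exc.offset, exc.message, "error")]
    canonical = serialize_glycan(g)
    if canonical != text.strip():
        return [
            Diagnostic(
                "W_NONCANONICAL",
                0,
                f"non-canonical form; canonical is {canonical!r}",
                "warning",
            )
        ]
    return []


def diagnostics_to_json(diags: list[Diagnostic]) -> str:
    return json.dumps(
        [
            {"code": d.code, "offset": d.offset, "message": d.message,
             "severity": d.severity}
            for d in diags
        ]
    )


def edge_multiset(g: Glycan):
    """Multiset of (parent ms, child ms, link position) edges — the
    order-free structural fingerprint used to assert that canonicalization
    is an isomorphism."""
    edges = []

    def rec(node):
        for child in node.children:
            edges.append((node.su.ms, child.su.ms, child.su.link_position))
            rec(child)

    rec(g.root)
    return sorted(edges, key=repr)


__all__ = [
    "DIALECTS",
    "Modification",
    "SaccharideUnit",
    "GlycanNode",
    "Glycan",
    "SUToken",
    "LicorriceSelector",
    "lex_su",
    "tokenize_glycan_body",
    "parse_glycan",
    "serialize_glycan",
    "canonicalize",
    "strip_conjugate",
    "count_residues",
    "enumerate_alternatives",
    "alternative_count",
    "expand_repeats",
    "validate",
    "edge_multiset",
]
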