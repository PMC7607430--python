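"""Conversion between Linear Code glycans/patterns and LiCoRRICE.

LiCoRRICE keeps the rule semantics but writes residues with their
IUPAC-condensed names and explicit linkages — ``Ab3GNb`` becomes
``Gal(b1-3)GlcNAc(b1-`` — delineates branches with square brackets, and,
because IUPAC branching is not deterministic, collapses the three
branch-sensitive wildcards into a single ``...``.

The anomeric carbon in each linkage comes from the registry (1 by default;
2 for the sialic acids, KDN, Kdo and fructose, giving ``Neu5Ac(a2-3)``).
Modifications are appended to the residue name (``Gal3S``). The reducing
end is rendered as an open linkage (``GlcNAc(b1-``) when its anomer is
known.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .constraint_lang import (
    And,
    CountAtom,
    Empty,
    Not,
    Or,
    PatternAtom,
    default_macro_table,
    expand_macros,
)
from .core_model import (
    Glycan,
    GlycanNode,
    LicorriceSelector,
    Modification,
    SaccharideUnit,
    parse_glycan,
    serialize_glycan,
)
from .errors import LicorrError, ParseError
from .pattern_engine import (
    ANY_SU,
    CLOSE_PAREN,
    LIGAND,
    OPEN_PAREN,
    RAW,
    SITE,
    Pattern,
    PatternToken,
)
from .registry import UNKNOWN_MS, UNKNOWN_SU, Registry, default_registry

_GREEK = {"a": "α", "b": "β", "?": "?"}
_UNGREEK = {"α": "a", "β": "b", "ᴅ": "D", "ʟ": "L"}


@dataclass(frozen=True)
class LicorriceStyle:
    greek: bool = False
    emit_reducing_tail: bool = True


def _anomer_out(anomer: str | None, style: LicorriceStyle) -> str:
    if anomer is None:
        return "?"
    return _GREEK[anomer] if style.greek else anomer


def _residue_name(su: SaccharideUnit, registry: Registry) -> str:
    if su.ms in (UNKNOWN_SU, UNKNOWN_MS):
        raise LicorrError("unknown saccharide units have no IUPAC rendering")
    if su.stereo_ring:
        raise LicorrError(
            f"stereo/ring marker {su.stereo_ring!r} has no IUPAC-condensed rendering"
        )
    name = registry.monosaccharide(su.ms).iupac_name
    for mod in su.modifications:
        pos = ",".join(str(p) for p in mod.positions)
        name += pos + registry.modification(mod.code).iupac_name
    return name


def _su_licorrice(su: SaccharideUnit, registry: Registry, style: LicorriceStyle,
                  is_root: bool) -> str:
    name = _residue_name(su, registry)
    ac = registry.monosaccharide(su.ms).anomeric_carbon
    if is_root:
        if style.emit_reducing_tail and su.anomer is not None:
            return f"{name}({_anomer_out(su.anomer, style)}{ac}-"
        return name
    pos = su.link_position if su.link_position is not None else "?"
    return f"{name}({_anomer_out(su.anomer, style)}{ac}-{pos})"


def to_licorrice(
    g: Glycan,
    style: LicorriceStyle | None = None,
    registry: Registry | None = None,
) -> str:
    """Render a glycan in IUPAC-condensed / LiCoRRICE form."""
    style = style or LicorriceStyle()
    registry = registry or default_registry()
    # canonical child order first
    g = parse_glycan(serialize_glycan(g), registry=registry)
    if g.fragments or g.repeat is not None:
        raise LicorrError("fragment/repeat annotations have no LiCoRRICE rendering")

    def render(node: GlycanNode, is_root: bool) -> str:
        parts = []
        if node.children:
            parts.append(render(node.children[0], False))
            for child in node.children[1:]:
                parts.append("[" + render(child, False) + "]")
        parts.append(_su_licorrice(node.su, registry, style, is_root))
        return "".join(parts)

    out = render(g.root, True)
    if g.conjugate is not None:
        out += g.conjugate[0] + g.conjugate[1]
    return out


# ---------------------------------------------------------------------------
# Reading LiCoRRICE
# ---------------------------------------------------------------------------

_LINKAGE_RE = re.compile(r"\(\s*([abαβ?])\s*(\d)?\s*-\s*([\d?])?\s*\)?")


def _lex_residue(text: str, i: int, registry: Registry):
    """Lex NAME[mods][(anomer ac-pos)] starting at text[i]."""
    names = sorted(
        {e.iupac_name for e in registry.monosaccharides}
        | set(_alias_names(registry)),
        key=len,
        reverse=True,
    )
    name = None
    for cand in names:
        if text.startswith(cand, i):
            name = cand
            break
    if name is None:
        raise ParseError(f"unknown residue name at {text[i:i + 8]!r}", i, "E_RESIDUE")
    entry = registry.by_iupac(name)
    i += len(name)
    mods = []
    mod_names = sorted(
        {e.iupac_name for e in registry.modifications}, key=len, reverse=True
    )
    while True:
        m = re.match(r"(\d+(?:,\d+)*)", text[i:])
        if not m:
            break
        matched = None
        for cand in mod_names:
            if text.startswith(cand, i + m.end()):
                matched = cand
                break
        if matched is None:
            break
        positions = tuple(int(p) for p in m.group(1).split(","))
        mods.append(
            Modification(positions, registry.modification_by_iupac(matched).lc_code)
        )
        i += m.end() + len(matched)
    anomer = None
    position = None
    has_link = False
    lm = _LINKAGE_RE.match(text, i)
    if lm:
        has_link = True
        anomer = _UNGREEK.get(lm.group(1), lm.group(1))
        position = lm.group(3)
        position = None if position in (None, "?") else int(position)
        if lm.group(3) == "?":
            position = "?"
        i = lm.end()
    su = SaccharideUnit(
        ms=entry.lc_code,
        modifications=tuple(mods),
        anomer=anomer,
        link_position=position,
    )
    return su, i, has_link


def _alias_names(registry: Registry):
    from .registry import IUPAC_ALIASES

    return [alias for alias, target in IUPAC_ALIASES.items()]


def from_licorrice(text: str, registry: Registry | None = None) -> Glycan:
    """Parse IUPAC-condensed / LiCoRRICE text into a canonical Glycan.

    Accepts greek or latin anomers and tolerates a missing reducing tail.
    """
    registry = registry or default_registry()
    text = text.strip()
    if not text:
        raise ParseError("empty input", 0, "E_EMPTY")
    conjugate = None
    # separators cannot occur inside a linkage "(b1-3)", so only square
    # brackets (branches) shield them — the open reducing tail "(b1-" would
    # otherwise never return to depth zero
    for sep in ";:#":
        depth = 0
        for i, ch in enumerate(text):
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
            elif depth == 0 and ch == sep:
                conjugate = (sep, text[i + 1 :])
                text = text[:i]
                break
        if conjugate:
            break

    def parse_chain(i: int):
        pending = []
        last_was_su = False
        while i < len(text) and text[i] != "]":
            if text[i] == "[":
                child, i = parse_chain(i + 1)
                if i >= len(text) or text[i] != "]":
                    raise ParseError("unbalanced square bracket", i, "E_BRACKET")
                i += 1
                pending.append(child)
                last_was_su = False
            else:
                su, i, _ = _lex_residue(text, i, registry)
                node = GlycanNode(su, children=pending)
                pending = [node]
                last_was_su = True
        if not pending or not last_was_su:
            raise ParseError("chain must end with a residue", i, "E_RESIDUE")
        return pending[0], i

    root, end = parse_chain(0)
    if end != len(text):
        raise ParseError("unbalanced square bracket", end, "E_BRACKET")
    g = Glycan(root=root, conjugate=conjugate)
    # canonicalize (and validate) through the round trip
    return parse_glycan(serialize_glycan(g), registry=registry)


# ---------------------------------------------------------------------------
# Patterns and constraints
# ---------------------------------------------------------------------------


def _pattern_su_licorrice(su: SaccharideUnit, registry: Registry,
                          style: LicorriceStyle) -> str:
    name = _residue_name(su, registry)
    if su.anomer is None and su.link_position is None:
        return name
    ac = registry.monosaccharide(su.ms).anomeric_carbon
    pos = su.link_position if su.link_position is not None else "?"
    return f"{name}({_anomer_out(su.anomer, style)}{ac}-{pos})"


def pattern_to_licorrice(
    p: Pattern,
    constraint=None,
    style: LicorriceStyle | None = None,
    registry: Registry | None = None,
) -> str:
    """Render a pattern (optionally under a constraint context) in
    LiCoRRICE: all three branch wildcards collapse to ``...``; literal
    parentheses become square brackets; ``@`` stays the site marker."""
    style = style or LicorriceStyle()
    registry = registry or default_registry()
    out = []
    for tok in p.tokens:
        if tok.kind in (LIGAND, "CONTINUATION", "BRANCH"):
            out.append("...")
        elif tok.kind == ANY_SU:
            out.append("*")
        elif tok.kind == SITE:
            out.append("@")
        elif tok.kind == OPEN_PAREN:
            out.append("[")
        elif tok.kind == CLOSE_PAREN:
            out.append("]")
        elif tok.kind == RAW:
            out.append(tok.text)
        else:
            out.append(_pattern_su_licorrice(tok.su, registry, style))
    text = "".join(out)
    if constraint is not None:
        text = text + " & " + constraint_to_licorrice(constraint, style, registry)
    return text


def constraint_to_licorrice(
    e, style: LicorriceStyle | None = None, registry: Registry | None = None,
    macros=None,
) -> str:
    style = style or LicorriceStyle()
    registry = registry or default_registry()
    e = expand_macros(e, macros or default_macro_table(), registry=registry)
    if isinstance(e, Empty):
        return ""
    if isinstance(e, Not):
        return "!" + constraint_to_licorrice(e.child, style, registry, macros)
    if isinstance(e, And):
        return " & ".join(
            constraint_to_licorrice(c, style, registry, macros) for c in e.children
        )
    if isinstance(e, Or):
        return " or ".join(
            constraint_to_licorrice(c, style, registry, macros) for c in e.children
        )
    if isinstance(e, PatternAtom):
        return pattern_to_licorrice(e.pattern, None, style, registry)
    if isinstance(e, CountAtom):
        if isinstance(e.selector, LicorriceSelector):
            sel = e.selector
            entry = registry.by_iupac(sel.iupac_name)
            pos = "?" if sel.position is None else sel.position
            return (
                f"n{sel.iupac_name}({sel.anomer or '?'}{entry.anomeric_carbon}-{pos})"
                f"{e.cmp}{e.value}"
            )
        entry = registry.monosaccharide(e.selector)
        return f"n{entry.iupac_name}(?{entry.anomeric_carbon}-?){e.cmp}{e.value}"
    raise TypeError(f"cannot render {e!r}")


def pattern_from_licorrice(
    text: str, registry: Registry | None = None
) -> tuple[Pattern, bool]:
    """Inverse pattern conversion. ``...`` necessarily maps back to the
    ligand wildcard; the returned flag is True when that choice was lossy
    (i.e. the pattern contained any wildcard)."""
    registry = registry or default_registry()
    tokens = []
    lossy = False
    i = 0
    text = text.strip().replace("…", "...")
    while i < len(text):
        if text.startswith("...", i):
            tokens.append(PatternToken(LIGAND, "..."))
            lossy = True
            i += 3
        elif text[i] == "[":
            tokens.append(PatternToken(OPEN_PAREN, "("))
            i += 1
        elif text[i] == "]":
            tokens.append(PatternToken(CLOSE_PAREN, ")"))
            i += 1
        elif text[i] == "@":
            tokens.append(PatternToken(SITE, "@"))
            i += 1
        elif text[i] == "*":
            tokens.append(PatternToken(ANY_SU, "*"))
            i += 1
        else:
            su, i, _ = _lex_residue(text, i, registry)
            tokens.append(PatternToken("SU_LITERAL", su.serialize(), su))
    return Pattern(tokens=tokens, dialect="licorr", source_text=text), lossy


__all__ = [
    "LicorriceStyle",
    "to_licorrice",
    "from_licorrice",
    "pattern_to_licorrice",
    "constraint_to_licorrice",
    "pattern_from_licorrice",
]
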