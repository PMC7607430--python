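"""Wildcard pattern matching over sentineled canonical glycan strings.

Patterns mix literal saccharide units and parentheses with three
substring-uncertainty wildcards, each defined by a balanced-parenthesis
class:

* ligand ``...`` — any substring with all parentheses matched (a fragment
  removable with one cut); includes the empty string;
* continuation ``_`` — any substring where every ``(`` is closed later,
  while ``)`` may be unmatched (a path that can exit branches toward the
  root); includes the empty string;
* possible branch ``+`` (``|`` in the legacy dialect) — exactly ``""``,
  ``")"``, ``"(B)"`` or ``")(B)"`` for balanced ``B``.

Matching operates on the *sentineled* canonical string: a ``(`` is prefixed
so the terminal end of every branch — including the lowest-carbon backbone —
is a left parenthesis, letting ``(GN`` mean "a *terminal* GlcNAc".

Literal SUs are element-aligned: a literal can only match at a subject SU
token boundary and consumes exactly the elements it spells out (identity,
stereo mark, modifications, anomer, position) in subject order, leaving any
trailing elements — typically the linkage — unconsumed so rule splicing
preserves them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core_model import (
    Glycan,
    SaccharideUnit,
    lex_su,
    parse_glycan,
    serialize_glycan,
    strip_conjugate,
    tokenize_glycan_body,
    _check_dialect,
)
from .errors import LicorrError, ParseError
from .registry import UNKNOWN_MS, UNKNOWN_SU, Registry, default_registry

# token kinds
SU_LITERAL = "SU_LITERAL"
OPEN_PAREN = "OPEN_PAREN"
CLOSE_PAREN = "CLOSE_PAREN"
LIGAND = "LIGAND"
CONTINUATION = "CONTINUATION"
BRANCH = "BRANCH"
ANY_SU = "ANY_SU"
SITE = "SITE"
RAW = "RAW"  # bare characters (e.g. a position digit left of a site split)

WILDCARD_KINDS = (LIGAND, CONTINUATION, BRANCH, ANY_SU)


@dataclass(frozen=True)
class PatternToken:
    kind: str
    text: str
    su: SaccharideUnit | None = None


@dataclass
class Pattern:
    tokens: list
    dialect: str
    source_text: str

    @property
    def wildcard_kinds(self) -> tuple:
        return tuple(t.kind for t in self.tokens if t.kind in WILDCARD_KINDS)

    def has_site(self) -> bool:
        return any(t.kind == SITE for t in self.tokens)


@dataclass(frozen=True)
class MatchResult:
    """One match over the sentineled canonical string.

    ``bindings`` holds, per wildcard occurrence in pattern order, the
    substring that wildcard absorbed. ``token_spans`` records the consumed
    span of every pattern token, so splicing and the substitution-soundness
    invariant are exact.
    """

    start: int
    end: int
    bindings: tuple
    site_index: int | None = None
    token_spans: tuple = field(default=(), compare=False)


# ---------------------------------------------------------------------------
# Sentinel and substring classes
# ---------------------------------------------------------------------------


def sentinel(text: str) -> str:
    """Prefix the left parenthesis that marks every branch terminal."""
    return "(" + text


def classify_substring(kind: str, s: str) -> bool:
    """Membership test for the three wildcard substring classes."""
    if kind == LIGAND:
        depth = 0
        for ch in s:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    return False
        return depth == 0
    if kind == CONTINUATION:
        depth = 0
        for ch in s:
            if ch == "(":
                depth += 1
            elif ch == ")" and depth > 0:
                depth -= 1
        return depth == 0
    if kind == BRANCH:
        if s in ("", ")"):
            return True
        for prefix in ("(", ")("):
            if s.startswith(prefix) and s.endswith(")"):
                body = s[len(prefix) : -1]
                # the shown parens must be the outermost matching pair
                if classify_substring(LIGAND, body) and _single_group(prefix[-1] + body + ")"):
                    return True
        return False
    raise ValueError(f"unknown wildcard class {kind!r}")


def _single_group(s: str) -> bool:
    """True iff s is '(' + balanced + ')' with the outer pair matching."""
    if len(s) < 2 or s[0] != "(" or s[-1] != ")":
        return False
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth == 0:
                return i == len(s) - 1
    return False


# ---------------------------------------------------------------------------
# Pattern parsing
# ---------------------------------------------------------------------------


def _dialect_symbols(dialect: str) -> dict:
    """Single-character wildcard glyphs per dialect (ligand is always ...)."""
    if dialect == "licorr":
        return {"+": BRANCH, "@": SITE, "*": ANY_SU, "_": CONTINUATION}
    if dialect == "legacy":
        return {"|": BRANCH, "*": SITE, "_": CONTINUATION}
    # original Linear Code: "*" is SU omission; no site/branch wildcards
    return {"*": ANY_SU, "_": CONTINUATION}


def parse_pattern(
    text: str, dialect: str = "licorr", registry: Registry | None = None
) -> Pattern:
    """Tokenize a pattern. Parentheses need not balance — ``(GNb2+Ma3`` is a
    legal pattern anchored at a branch terminal."""
    _check_dialect(dialect)
    registry = registry or default_registry()
    source = text
    text = text.strip().replace("…", "...")
    if not text:
        raise ParseError("empty pattern", 0, "E_EMPTY")
    symbols = _dialect_symbols(dialect)
    tokens = []
    i = 0
    site_seen = False
    while i < len(text):
        ch = text[i]
        if text.startswith("...", i):
            tokens.append(PatternToken(LIGAND, "..."))
            i += 3
        elif ch in symbols:
            kind = symbols[ch]
            if kind == SITE:
                if site_seen:
                    raise ParseError("duplicate reaction site", i, "E_SITE")
                site_seen = True
            tokens.append(PatternToken(kind, ch))
            i += 1
        elif ch == "(":
            tokens.append(PatternToken(OPEN_PAREN, "("))
            i += 1
        elif ch == ")":
            tokens.append(PatternToken(CLOSE_PAREN, ")"))
            i += 1
        elif ch.isdigit():
            # bare digits: the linkage tail left of a reaction-site split
            m = re.match(r"\d+", text[i:])
            tokens.append(PatternToken(RAW, m.group(0)))
            i += m.end()
        else:
            tok = lex_su(text, i, registry, 0)
            tokens.append(PatternToken(SU_LITERAL, text[tok.start : tok.end], tok.su))
            i = tok.end
    return Pattern(tokens=tokens, dialect=dialect, source_text=source)


# ---------------------------------------------------------------------------
# Subject preparation
# ---------------------------------------------------------------------------


@dataclass
class Subject:
    """A glycan rendered for matching: sentineled canonical text plus the SU
    token index of that text."""

    text: str
    su_tokens: dict  # start offset -> SUToken (absolute offsets)

    @classmethod
    def from_glycan(cls, g: Glycan, registry: Registry) -> "Subject":
        bare, _ = strip_conjugate(g)
        body = serialize_glycan(bare)
        s = sentinel(body)
        su_tokens = {}
        for kind, start, end, tok in tokenize_glycan_body(body, registry, base=1):
            if kind == "SU":
                su_tokens[start] = tok
        return cls(text=s, su_tokens=su_tokens)

    @classmethod
    def from_text(cls, text: str, registry: Registry) -> "Subject":
        return cls.from_glycan(parse_glycan(text, registry=registry), registry)

    @classmethod
    def from_raw(cls, body: str, registry: Registry) -> "Subject":
        """Sentinel and index a string verbatim, without parsing it as a
        glycan (test aid for deliberately unbalanced subjects)."""
        su_tokens = {}
        for kind, start, end, tok in tokenize_glycan_body(body, registry, base=1):
            if kind == "SU":
                su_tokens[start] = tok
        return cls(text=sentinel(body), su_tokens=su_tokens)


def _mods_equal(a: tuple, b: tuple) -> bool:
    key = lambda m: (m.positions, m.code)
    return sorted(a, key=key) == sorted(b, key=key)


def _match_su_literal(pat: SaccharideUnit, tok, subject_text: str):
    """Element-aligned prefix match of a literal SU against a subject token.

    Returns the absolute end offset of the consumed span, or None.
    Subject elements appear in the order ms, stereo, mods, anomer, position;
    the literal must match them consecutively from the token start and may
    stop early, leaving trailing elements unconsumed.
    """
    su = tok.su
    spans = tok.spans
    # identity
    if pat.ms == UNKNOWN_MS:
        pass
    elif pat.ms_alts:
        if su.ms not in (pat.ms,) + pat.ms_alts:
            return None
    elif su.ms != pat.ms:
        return None
    consumed = spans["ms"][1]

    def next_is(name):
        return name in spans and spans[name][0] == consumed

    if pat.stereo_ring:
        if not (next_is("stereo") and su.stereo_ring == pat.stereo_ring):
            return None
        consumed = spans["stereo"][1]

    if pat.modifications:
        if not (next_is("mods") and _mods_equal(su.modifications, pat.modifications)):
            return None
        consumed = spans["mods"][1]
    elif pat.possible_mod is not None:
        if next_is("mods"):
            if pat.possible_mod != "ANY" and not _mods_equal(
                su.modifications, pat.possible_mod
            ):
                return None
            consumed = spans["mods"][1]
        # else: unmodified subject — "$" also matches the empty set

    if pat.anomer is not None:
        if not next_is("anomer"):
            return None
        if pat.anomer != "?" and su.anomer != pat.anomer:
            return None
        consumed = spans["anomer"][1]

    if pat.open_form:
        if not su.open_form:
            return None
        consumed = tok.end
    elif pat.link_position is not None:
        if not next_is("position"):
            return None
        if pat.pos_alts:
            if su.link_position not in pat.pos_alts:
                return None
        elif pat.link_position == "?":
            if not (isinstance(su.link_position, int) or su.link_position == "?"):
                return None
        elif su.link_position != pat.link_position or su.pos_alts:
            return None
        consumed = spans["position"][1]
    return consumed


def _wildcard_ends(kind: str, s: str, pos: int):
    """Candidate end offsets for a wildcard starting at ``pos``."""
    if kind == BRANCH:
        ends = [pos]
        if pos < len(s) and s[pos] == ")":
            ends.append(pos + 1)
        for skip in (0, 1):
            j = pos + skip
            if skip == 1 and not (pos < len(s) and s[pos] == ")"):
                continue
            if j < len(s) and s[j] == "(":
                depth = 0
                for k in range(j, len(s)):
                    if s[k] == "(":
                        depth += 1
                    elif s[k] == ")":
                        depth -= 1
                        if depth == 0:
                            ends.append(k + 1)
                            break
        return ends
    ends = []
    depth = 0
    for e in range(pos, len(s) + 1):
        if depth == 0:
            ends.append(e)
        if e == len(s):
            break
        ch = s[e]
        if ch == "(":
            depth += 1
        elif ch == ")":
            if depth > 0:
                depth -= 1
            elif kind == LIGAND:
                break  # an unmatched ')' can never be absorbed by a ligand
    return ends


def find_matches(
    p: Pattern, g: Glycan, registry: Registry | None = None
) -> list[MatchResult]:
    """All distinct (start, bindings) matches of ``p`` in the sentineled
    canonical string of ``g``, ordered by start then binding tuple."""
    registry = registry or default_registry()
    subj = g if isinstance(g, Subject) else Subject.from_glycan(g, registry)
    s = subj.text
    out = []

    def backtrack(ti, pos, bindings, site, spans):
        if ti == len(p.tokens):
            out.append(
                MatchResult(
                    start=spans[0][1] if spans else pos,
                    end=pos,
                    bindings=tuple(b for k, _, _, b in spans if k in WILDCARD_KINDS),
                    site_index=site,
                    token_spans=tuple((k, a, b) for k, a, b, _ in spans),
                )
            )
            return
        tok = p.tokens[ti]
        if tok.kind == SU_LITERAL:
            sub_tok = subj.su_tokens.get(pos)
            if sub_tok is not None:
                consumed = _match_su_literal(tok.su, sub_tok, s)
                if consumed is not None:
                    backtrack(
                        ti + 1, consumed, bindings, site,
                        spans + [(tok.kind, pos, consumed, None)],
                    )
        elif tok.kind in (OPEN_PAREN, CLOSE_PAREN):
            if pos < len(s) and s[pos] == tok.text:
                backtrack(ti + 1, pos + 1, bindings, site,
                          spans + [(tok.kind, pos, pos + 1, None)])
        elif tok.kind == RAW:
            if s.startswith(tok.text, pos):
                e = pos + len(tok.text)
                backtrack(ti + 1, e, bindings, site,
                          spans + [(tok.kind, pos, e, None)])
        elif tok.kind == SITE:
            backtrack(ti + 1, pos, bindings, pos,
                      spans + [(tok.kind, pos, pos, None)])
        elif tok.kind == ANY_SU:
            sub_tok = subj.su_tokens.get(pos)
            if sub_tok is not None:
                e = sub_tok.end
                backtrack(ti + 1, e, bindings + [s[pos:e]], site,
                          spans + [(tok.kind, pos, e, s[pos:e])])
        else:  # LIGAND / CONTINUATION / BRANCH
            for e in _wildcard_ends(tok.kind, s, pos):
                backtrack(ti + 1, e, bindings + [s[pos:e]], site,
                          spans + [(tok.kind, pos, e, s[pos:e])])

    for start in range(len(s) + 1):
        backtrack(0, start, [], None, [(None, start, start, None)][:0] or [])
    # a match's start is its first token's span start; empty-token patterns
    # cannot occur (parse_pattern rejects empty input)
    dedup = {}
    for m in out:
        key = (m.start, m.bindings)
        if key not in dedup:
            dedup[key] = m
    return sorted(dedup.values(), key=lambda m: (m.start, m.bindings))


def brute_force_matches(
    p: Pattern,
    g: Glycan,
    max_len: int = 60,
    registry: Registry | None = None,
) -> list[MatchResult]:
    """Exhaustive oracle: enumerate every start offset and every wildcard
    substring assignment; keep those whose classes pass
    :func:`classify_substring` and whose concatenation with the literal
    texts reproduces the glycan substring. Literals are pinned to SU token
    boundaries and compared textually, with each "?" in a literal treated
    as a one-character class over anomers and digits.

    Literals with "/" alternatives are not supported — the guarantee-match
    generator never produces them.
    """
    registry = registry or default_registry()
    subj = g if isinstance(g, Subject) else Subject.from_glycan(g, registry)
    s = subj.text
    if len(s) > max_len:
        raise LicorrError(f"subject length {len(s)} exceeds oracle guard {max_len}")
    ms_span = {start: tok.spans["ms"] for start, tok in subj.su_tokens.items()}
    out = []

    def rec(ti, pos, bindings, site, spans):
        if ti == len(p.tokens):
            out.append(
                MatchResult(
                    start=spans[0][1] if spans else pos,
                    end=pos,
                    bindings=tuple(b for k, _, _, b in spans if k in WILDCARD_KINDS),
                    site_index=site,
                    token_spans=tuple((k, a, b) for k, a, b, _ in spans),
                )
            )
            return
        tok = p.tokens[ti]
        if tok.kind in (LIGAND, CONTINUATION, BRANCH):
            for e in range(pos, len(s) + 1):
                sub = s[pos:e]
                if classify_substring(tok.kind, sub):
                    rec(ti + 1, e, bindings + [sub], site,
                        spans + [(tok.kind, pos, e, sub)])
        elif tok.kind == ANY_SU:
            if pos in subj.su_tokens:
                e = subj.su_tokens[pos].end
                rec(ti + 1, e, bindings + [s[pos:e]], site,
                    spans + [(tok.kind, pos, e, s[pos:e])])
        elif tok.kind == SITE:
            rec(ti + 1, pos, bindings, pos, spans + [(tok.kind, pos, pos, None)])
        elif tok.kind == SU_LITERAL:
            text = tok.text
            literal_re = re.compile(
                "".join(
                    "[ab?0-9]" if ch == "?" else re.escape(ch) for ch in text
                )
            )
            m = literal_re.match(s, pos)
            if (
                m is not None
                and pos in ms_span
                # the literal's identity must cover the subject token's
                # identity exactly (no matching "A" inside "AN") and the
                # consumed span must stay inside that token
                and ms_span[pos][1] - ms_span[pos][0] == len(tok.su.ms)
                and m.end() <= subj.su_tokens[pos].end
            ):
                e = m.end()
                rec(ti + 1, e, bindings, site, spans + [(tok.kind, pos, e, None)])
        else:  # parens, RAW
            if s.startswith(tok.text, pos):
                e = pos + len(tok.text)
                rec(ti + 1, e, bindings, site, spans + [(tok.kind, pos, e, None)])

    for start in range(len(s) + 1):
        rec(0, start, [], None, [])
    dedup = {}
    for m in out:
        key = (m.start, m.bindings)
        if key not in dedup:
            dedup[key] = m
    return sorted(dedup.values(), key=lambda m: (m.start, m.bindings))


__all__ = [
    "SU_LITERAL",
    "OPEN_PAREN",
    "CLOSE_PAREN",
    "LIGAND",
    "CONTINUATION",
    "BRANCH",
    "ANY_SU",
    "SITE",
    "RAW",
    "WILDCARD_KINDS",
    "PatternToken",
    "Pattern",
    "MatchResult",
    "Subject",
    "sentinel",
    "classify_substring",
    "parse_pattern",
    "find_matches",
    "brute_force_matches",
]
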