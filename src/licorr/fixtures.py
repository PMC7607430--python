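"""Seeded generators and canned worked-example fixtures.

Everything here is reproducible from a small integer seed: random glycans
for round-trip/property testing, patterns constructed from a glycan so that
at least one match is guaranteed (the matcher-vs-oracle test driver), and a
named collection of the worked-example strings and rule tables that the
documentation walks through.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from importlib import resources

from .core_model import (
    Glycan,
    GlycanNode,
    Modification,
    SaccharideUnit,
    parse_glycan,
    serialize_glycan,
)
from .pattern_engine import (
    ANY_SU,
    BRANCH,
    CLOSE_PAREN,
    CONTINUATION,
    LIGAND,
    OPEN_PAREN,
    SU_LITERAL,
    Pattern,
    PatternToken,
    Subject,
    classify_substring,
)
from .registry import Registry, abstract_registry, default_registry
from .rule_engine import RuleTable, read_rule_table

#: Monosaccharides drawn by the default generator profile — the common
#: mammalian glycan alphabet.
_DEFAULT_POOL = ["G", "A", "GN", "AN", "M", "NN", "F", "X"]
_ABSTRACT_POOL = list("ABCDEFGHJK")
_MOD_POOL = ["S", "P", "ME"]
_POSITION_POOL = [2, 3, 4, 6]

_WILDCARD_TEXT = {LIGAND: "...", CONTINUATION: "_", BRANCH: "+", ANY_SU: "*"}


@dataclass(frozen=True)
class GenParams:
    """Knobs for the random glycan generator; identical params (including
    seed) always produce identical output."""

    seed: int = 0
    max_depth: int = 3
    max_children_per_node: int = 2
    alphabet: str = "default"  # "default" | "abstract"
    p_modification: float = 0.1
    p_unknown_anomer: float = 0.05

    def __post_init__(self):
        if not 0 <= self.max_children_per_node <= 3:
            raise ValueError("max_children_per_node must be in 0..3")


def generator_registry(params: GenParams) -> Registry:
    return abstract_registry() if params.alphabet == "abstract" else default_registry()


def random_glycan(params: GenParams) -> Glycan:
    """A valid, canonical random glycan within the configured size bounds."""
    rng = random.Random(params.seed)
    abstract = params.alphabet == "abstract"
    pool = _ABSTRACT_POOL if abstract else _DEFAULT_POOL

    def make_su(position) -> SaccharideUnit:
        ms = rng.choice(pool)
        su = SaccharideUnit(ms=ms)
        if not abstract:
            su.anomer = (
                "?" if rng.random() < params.p_unknown_anomer
                else rng.choice(["a", "b"])
            )
            su.link_position = position
            if rng.random() < params.p_modification:
                su.modifications = (
                    Modification((rng.choice(_POSITION_POOL),), rng.choice(_MOD_POOL)),
                )
        return su

    def build(depth: int, position) -> GlycanNode:
        node = GlycanNode(make_su(position))
        if depth < params.max_depth:
            n_children = rng.randint(0, params.max_children_per_node)
            positions = sorted(rng.sample(_POSITION_POOL, n_children))
            for pos in positions:
                node.children.append(build(depth + 1, pos))
        return node

    root = build(1, None)
    root.su.link_position = None
    registry = generator_registry(params)
    # normalize through the parser so the result is canonical by contract
    return parse_glycan(serialize_glycan(Glycan(root)), registry=registry)


# ---------------------------------------------------------------------------
# Guaranteed-match pattern generator
# ---------------------------------------------------------------------------


def pattern_from_glycan(
    g: Glycan, seed: int, registry: Registry | None = None
) -> Pattern:
    """Derive a pattern with >= 1 guaranteed match in ``g``.

    A contiguous token window of the sentineled canonical string is taken
    literally, then 0-2 non-overlapping sub-spans are replaced by wildcards
    whose class is valid for the removed substring — so the original window
    is always a witness match.
    """
    registry = registry or default_registry()
    rng = random.Random(seed)
    subject = Subject.from_glycan(g, registry)
    s = subject.text
    tokens = []  # (kind, start, end, su)
    tokens.append((OPEN_PAREN, 0, 1, None))
    i = 1
    while i < len(s):
        if s[i] == "(":
            tokens.append((OPEN_PAREN, i, i + 1, None))
            i += 1
        elif s[i] == ")":
            tokens.append((CLOSE_PAREN, i, i + 1, None))
            i += 1
        else:
            tok = subject.su_tokens[i]
            tokens.append((SU_LITERAL, tok.start, tok.end, tok.su))
            i = tok.end

    n = len(tokens)
    wi = rng.randrange(n)
    wj = rng.randrange(wi + 1, n + 1)
    window = tokens[wi:wj]

    n_wild = rng.randint(0, 2)
    spans = []  # (token index lo, token index hi, kind); non-empty spans
    for _ in range(n_wild * 6):
        if len(spans) >= n_wild:
            break
        lo = rng.randrange(len(window))
        hi = rng.randrange(lo + 1, len(window) + 1)
        if any(not (hi <= a or lo >= b) for a, b, _ in spans):
            continue
        sub = s[window[lo][1] : window[hi - 1][2]]
        kinds = [k for k in (LIGAND, CONTINUATION, BRANCH)
                 if classify_substring(k, sub)]
        if hi - lo == 1 and window[lo][0] == SU_LITERAL:
            kinds.append(ANY_SU)
        if not kinds:
            continue
        spans.append((lo, hi, rng.choice(kinds)))
    spans.sort()

    out = []
    k = 0
    idx = 0
    while idx < len(window):
        if k < len(spans) and spans[k][0] == idx:
            lo, hi, kind = spans[k]
            out.append(PatternToken(kind, _WILDCARD_TEXT[kind]))
            idx = hi
            k += 1
            continue
        kind, a, b, su = window[idx]
        if kind == SU_LITERAL:
            out.append(PatternToken(SU_LITERAL, s[a:b], su))
        else:
            out.append(PatternToken(kind, s[a:b]))
        idx += 1

    return Pattern(
        tokens=out,
        dialect="licorr",
        source_text="".join(t.text for t in out),
    )


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("licorr").joinpath("data", name).read_text()


def legacy_of(text: str) -> str:
    """Inverse consensus mapping: render a LiCoRR cell in the legacy symbol
    set (! -> ~, + -> |, @ -> *, nX -> #X)."""
    out = re.sub(
        r"\bn([A-Z][A-Za-z0-9]*)\s*(<=|>=|=|<|>)", r"#\1\2", text
    )
    return out.replace("!", "~").replace("+", "|").replace("@", "*")


def published_fixtures() -> dict:
    """Every worked-example string and table under a stable name."""
    table9_licorr = _data_text("table9.tsv")
    table9_legacy_lines = []
    for i, line in enumerate(table9_licorr.strip().splitlines()):
        if i == 0:
            table9_legacy_lines.append("enzyme\tsubstrate\tproduct\tconstraint")
            continue
        cells = line.split("\t")
        enzyme, substrate, product = cells[0], cells[1], cells[2]
        constraint = cells[3] if len(cells) > 3 else ""
        table9_legacy_lines.append(
            "\t".join(
                [enzyme, legacy_of(substrate), legacy_of(product),
                 legacy_of(constraint)]
            )
        )
    table9_legacy = "\n".join(table9_legacy_lines) + "\n"

    return {
        # one reaction rendered in several nomenclatures
        "table1.reactant": "Ab3GNb",
        "table1.product": "Ab3(Fa4)GNb",
        "table1.reactant_iupac": "Gal(β1-3)GlcNAc(β1-",
        "table1.product_iupac": "Gal(β1-3)[Fuc(α1-4)]GlcNAc(β1-",
        # in-text strings
        "m9": "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN;Asn",
        "m9.core": "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
        "biantennary": "GNb2Ma3(GNb2Ma6)Mb4GNb4GN",
        "fig1.glycan": "KJ(IH)GF(D(E)(C)B)A",
        "branch_reorder.input": "Ab4(GNb4GNb3)(GNb6)Ab4Gb",
        "branch_reorder.canonical": "GNb4GNb3(Ab4)(GNb6)Ab4Gb",
        "gnbis": "Ma3(GNb4)(...Ma6)Mb4",
        "manI.substrate": "(Ma2Ma",
        "manI.product": "(Ma",
        "manI.constraint": "!@2Ma3(...Ma6)Ma6 & !Ga3",
        "manI.constraint_legacy": "~*2Ma3(...Ma6)Ma6 & ~Ga3",
        # uncertainty-rule strings
        "ur5.input": "Ab4//Ga2Aa3",
        "ur5.expansions": ("Ab4Aa3", "Ga2Aa3"),
        "ur6.input": "NNa6=1%|1%Ab4GNb2Ma3(1%Ab4GNb2Ma6)Mb4Gb",
        "unknown_su.input": "ANb3*A",
        # wildcard behavior matrix: (glycan, left context, right context)
        "table6.glycans": ("B(C)A", "BCA", "E(D(C)B)A"),
        "table6.columns": (
            ("B(C)A", "B", "A"),          # add a whole new branch: (C)
            ("B(C)A", "B(C", "A"),        # initiating branch: )
            ("BCA", "B", "A"),            # extending the backbone: C
            ("E(D(C)B)A", "E(D", "A"),    # initiating nested branch: (C)B)
        ),
        "table6.marked": {
            ("_", 0), ("_", 1), ("_", 2), ("_", 3),
            ("...", 0), ("...", 2),
            ("+", 0), ("+", 1),
        },
        # rule tables
        "table7.tsv": _data_text("table7.tsv"),
        "table8.tsv": _data_text("table8.tsv"),
        "table9.tsv": table9_licorr,
        "table9.legacy_tsv": table9_legacy,
    }


def table7_rules(registry: Registry | None = None) -> RuleTable:
    return read_rule_table(_data_text("table7.tsv"), dialect="legacy",
                           registry=registry)


def table8_rules(registry: Registry | None = None) -> RuleTable:
    return read_rule_table(_data_text("table8.tsv"), dialect="legacy",
                           registry=registry)


def table9_rules(registry: Registry | None = None) -> RuleTable:
    return read_rule_table(_data_text("table9.tsv"), dialect="licorr",
                           registry=registry)


__all__ = [
    "GenParams",
    "generator_registry",
    "random_glycan",
    "pattern_from_glycan",
    "published_fixtures",
    "legacy_of",
    "table7_rules",
    "table8_rules",
    "table9_rules",
]
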