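"""Reaction rules: table I/O, legacy modernization, and rule application.

A rule row has an enzyme name, a substrate pattern, a product pattern, and
a constraint cell, optionally a Golgi/ER compartment and an EC number.
Applying a rule to a glycan enumerates every substrate match in the
sentineled canonical string, splices the product pattern (wildcard bindings
transfer positionally), computes the *reaction site* — the index of the
first character at which substrate and product strings differ — and keeps
the product when the constraint holds at that site.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace

from .constraint_lang import (
    atomize_disjunction,
    evaluate,
    parse_constraint,
    unparse_constraint,
)
from .core_model import (
    Glycan,
    parse_glycan,
    serialize_glycan,
    strip_conjugate,
    _check_dialect,
)
from .errors import LicorrError, ParseError, RuleError
from .pattern_engine import (
    SITE,
    WILDCARD_KINDS,
    Pattern,
    Subject,
    find_matches,
    parse_pattern,
)
from .registry import Registry, default_registry


@dataclass
class ReactionRule:
    enzyme: str
    substrate_text: str
    product_text: str
    constraint_text: str = ""
    compartment: str | None = None
    ec_number: str | None = None
    dialect: str = "licorr"
    annotations: dict = field(default_factory=dict)
    # parsed forms (filled lazily or by read_rule_table)
    substrate: Pattern | None = None
    product: Pattern | None = None
    constraint: object = None

    def parse(self, registry: Registry | None = None) -> "ReactionRule":
        registry = registry or default_registry()
        self.substrate = parse_pattern(self.substrate_text, self.dialect, registry)
        self.product = parse_pattern(self.product_text, self.dialect, registry)
        self.constraint = parse_constraint(self.constraint_text, self.dialect, registry)
        for p, role in ((self.substrate, "substrate"), (self.product, "product")):
            if p.has_site():
                raise RuleError(
                    f"{role} pattern must not contain a site marker (the site "
                    "is computed from the first substrate/product difference)"
                )
        if self.substrate.wildcard_kinds != self.product.wildcard_kinds:
            raise RuleError(
                "substrate and product wildcard sequences differ: "
                f"{self.substrate.wildcard_kinds} vs {self.product.wildcard_kinds}"
            )
        return self


@dataclass
class RuleTable:
    rules: list
    source: str = ""
    errors: list = field(default_factory=list)  # (row number, message)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)


_HEADER_ALIASES = {
    "enzyme": "enzyme",
    "enz.": "enzyme",
    "enz": "enzyme",
    "reactant": "substrate",
    "substrate": "substrate",
    "product": "product",
    "constraint": "constraint",
    "constraints": "constraint",
    "compartment": "compartment",
    "localization": "compartment",
    "ec": "ec",
    "ec_number": "ec",
    "ec number": "ec",
}


def read_rule_table(
    stream,
    dialect: str = "licorr",
    registry: Registry | None = None,
    strict: bool = False,
) -> RuleTable:
    """Read a TSV (or CSV) rule table.

    Requires header columns enzyme, substrate/reactant, product, constraint;
    compartment and ec are optional; any other column is kept verbatim in
    ``annotations``. Row-level parse failures are recorded in
    ``RuleTable.errors`` and skipped unless ``strict``.
    """
    _check_dialect(dialect)
    registry = registry or default_registry()
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    if not rows:
        raise RuleError("rule table has no header row")
    header = [
        _HEADER_ALIASES.get(cell.strip().lower(), cell.strip()) for cell in rows[0]
    ]
    for required in ("enzyme", "substrate", "product", "constraint"):
        if required not in header:
            raise RuleError(f"rule table is missing required column {required!r}")
    table = RuleTable(rules=[], source=getattr(stream, "name", "<stream>"))
    for lineno, row in enumerate(rows[1:], start=2):
        cells = dict(zip(header, (c.strip() for c in row)))
        annotations = {
            k: v
            for k, v in cells.items()
            if k not in ("enzyme", "substrate", "product", "constraint",
                         "compartment", "ec")
        }
        rule = ReactionRule(
            enzyme=cells.get("enzyme", ""),
            substrate_text=cells.get("substrate", ""),
            product_text=cells.get("product", ""),
            constraint_text=cells.get("constraint", ""),
            compartment=cells.get("compartment") or None,
            ec_number=cells.get("ec") or None,
            dialect=dialect,
            annotations=annotations,
        )
        try:
            rule.parse(registry)
        except (LicorrError, ParseError) as exc:
            if strict:
                raise RuleError(f"row {lineno}: {exc}") from exc
            table.errors.append((lineno, str(exc)))
            continue
        table.rules.append(rule)
    return table


def write_rule_table(t: RuleTable, stream) -> None:
    """Write TSV that read_rule_table reads back to an equal table."""
    extra_keys = sorted({k for r in t.rules for k in r.annotations})
    has_compartment = any(r.compartment for r in t.rules)
    has_ec = any(r.ec_number for r in t.rules)
    header = ["enzyme", "substrate", "product", "constraint"]
    if has_compartment:
        header.append("compartment")
    if has_ec:
        header.append("ec")
    header += extra_keys
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(header)
    for r in t.rules:
        row = [r.enzyme, r.substrate_text, r.product_text, r.constraint_text]
        if has_compartment:
            row.append(r.compartment or "")
        if has_ec:
            row.append(r.ec_number or "")
        row += [r.annotations.get(k, "") for k in extra_keys]
        writer.writerow(row)


# ---------------------------------------------------------------------------
# Legacy -> LiCoRR modernization
# ---------------------------------------------------------------------------

_COUNT_LEGACY_RE = re.compile(r"#\s*([A-Za-z][A-Za-z0-9]*)\s*(<=|>=|=|<|>)\s*(\d+)")


def modernize(text: str, role: str = "constraint") -> str:
    """Rewrite a legacy-dialect cell into the consensus symbol set:
    ``~`` -> ``!``, ``|`` -> ``+``, ``*`` -> ``@``, ``#X = n`` -> ``nX=n``;
    ``&``, ``or``, ``...`` and ``_`` are unchanged."""
    if role not in ("pattern", "constraint"):
        raise ValueError("role must be 'pattern' or 'constraint'")
    out = text.replace("…", "...")
    if role == "constraint":
        out = _COUNT_LEGACY_RE.sub(lambda m: f"n{m.group(1)}{m.group(2)}{m.group(3)}", out)
        out = out.replace("~", "!")
    out = out.replace("|", "+").replace("*", "@")
    return out


def modernize_rule(rule: ReactionRule, registry: Registry | None = None) -> ReactionRule:
    new = replace(
        rule,
        substrate_text=modernize(rule.substrate_text, "pattern"),
        product_text=modernize(rule.product_text, "pattern"),
        constraint_text=modernize(rule.constraint_text, "constraint"),
        dialect="licorr",
        annotations=dict(rule.annotations),
        substrate=None,
        product=None,
        constraint=None,
    )
    return new.parse(registry)


def modernize_table(t: RuleTable, registry: Registry | None = None) -> RuleTable:
    return RuleTable(
        rules=[modernize_rule(r, registry) for r in t.rules], source=t.source
    )


# ---------------------------------------------------------------------------
# Reaction site and rule application
# ---------------------------------------------------------------------------


def compute_site(substrate_str: str, product_str: str) -> int:
    """0-based index of the first differing character between the substrate
    and product strings (callers pass the sentineled forms)."""
    if substrate_str == product_str:
        raise LicorrError("substrate and product strings are identical")
    for i, (a, b) in enumerate(zip(substrate_str, product_str)):
        if a != b:
            return i
    return min(len(substrate_str), len(product_str))


def _splice(product: Pattern, bindings: tuple) -> str:
    out = []
    it = iter(bindings)
    for tok in product.tokens:
        if tok.kind in WILDCARD_KINDS:
            out.append(next(it))
        elif tok.kind == SITE:  # pragma: no cover - rejected at parse
            continue
        else:
            out.append(tok.text)
    return "".join(out)


def apply_rule(
    rule: ReactionRule, g: Glycan, registry: Registry | None = None
) -> list:
    """Apply one rule everywhere it fits; returns [(product Glycan, site)].

    Conjugate suffixes are stripped before matching and re-attached to every
    product unchanged. Products are deduplicated after canonicalization and
    ordered by site then product string.
    """
    registry = registry or default_registry()
    if rule.substrate is None:
        rule.parse(registry)
    bare, conjugate = strip_conjugate(g)
    subject = Subject.from_glycan(bare, registry)
    results = {}
    for m in find_matches(rule.substrate, subject, registry):
        spliced = (
            subject.text[: m.start] + _splice(rule.product, m.bindings)
            + subject.text[m.end :]
        )
        if spliced == subject.text:
            continue
        site = compute_site(subject.text, spliced)
        product_glycan = parse_glycan(spliced[1:], registry=registry)
        if not evaluate(rule.constraint, bare, site, registry):
            continue
        product_glycan.conjugate = conjugate
        key = (serialize_glycan(product_glycan), site)
        results.setdefault(key, product_glycan)
    return [
        (results[key], key[1])
        for key in sorted(results, key=lambda k: (k[1], k[0]))
    ]


def split_rules(t: RuleTable, registry: Registry | None = None) -> RuleTable:
    """Rewrite every ``or``-constraint rule as one rule per disjunct."""
    registry = registry or default_registry()
    out = RuleTable(rules=[], source=t.source)
    for rule in t.rules:
        if rule.constraint is None:
            rule.parse(registry)
        parts = atomize_disjunction(rule.constraint)
        if len(parts) == 1:
            out.rules.append(rule)
            continue
        for part in parts:
            clone = replace(
                rule,
                constraint_text=unparse_constraint(part, rule.dialect),
                annotations=dict(rule.annotations),
                substrate=rule.substrate,
                product=rule.product,
                constraint=part,
            )
            out.rules.append(clone)
    return out


__all__ = [
    "ReactionRule",
    "RuleTable",
    "read_rule_table",
    "write_rule_table",
    "modernize",
    "modernize_rule",
    "modernize_table",
    "compute_site",
    "apply_rule",
    "split_rules",
]
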