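# licorr

**Linear Code for Reaction Rules (LiCoRR) — parse, match, and apply
glycosylation reaction rules.**

Glycans are branched tree-shaped polymers built by the serial action of
glycosyltransferases and glycosidases. Systems-glycobiology models describe
this biosynthesis with *reaction rules*: a substrate pattern, a product
pattern, and a constraint, all written in Linear Code — the compact
linearization of glycan structure in which `Ab3(Fa4)GNb` is a GlcNAc
carrying a β1-3 galactose and an α1-4 fucose. Over a decade of use, the
rule notation drifted into several incompatible dialects (`~` vs `!` for
negation, `|` vs `+` for a possible branch, `*` vs `@` for the reaction
site, `#A=0` vs `nA=0` for residue counts). `licorr` implements the
consensus notation, LiCoRR v1.0, end to end, for modelers who build or
exchange glycan-synthesis networks:

* **Parsing and canonicalization.** Glycan strings parse into rooted trees
  and serialize back in the consensus branch order: at every residue the
  chain attached at the lowest carbon stays on the unparenthesized
  backbone and the remaining chains branch in ascending attachment order,
  so string equality equals structural identity.
* **Wildcard matching.** Patterns over the *sentineled* string (a `(` is
  prefixed so every branch terminal is a left parenthesis) support the
  three substring-uncertainty classes — ligand `...` (balanced
  parentheses), continuation `_` (every `(` closed, `)` free), possible
  branch `+` (`""`, `)`, `(B)` or `)(B)`) — plus `*` for one unknown
  residue and the zero-width reaction-site anchor `@`.
* **Constraints and rules.** Boolean constraint cells (`!`, `&`, `or`,
  residue counts, site-anchored atoms, macros such as `Gnbis` for the
  bisecting GlcNAc), rule tables as TSV/CSV, legacy-dialect
  modernization, rule application with positional wildcard-binding
  transfer, and `or`-splitting into atomic rules.
* **Network expansion.** Breadth-first closure of a rule table over seed
  glycans with termination limits and optional Golgi-compartment staging;
  export to edge-list TSV, GraphML, or JSON.
* **LiCoRRICE interop.** Conversion to and from the IUPAC-condensed
  flavor: `Ab3GNb` ↔ `Gal(β1-3)GlcNAc(β1-`, square-bracket branches, and
  collapse of all branch wildcards to `...`.

## Worked example

The reaction site of a rule is the first character at which substrate and
product strings differ, and a `!@…`-anchored constraint vetoes specific
sites. The classic case is ER/cis-Golgi α-mannosidase I trimming the
high-mannose N-glycan M9, where the middle-branch α1-2 mannose must not be
removed:

```python
>>> from licorr import ReactionRule, apply_rule, parse_glycan, serialize_glycan
>>> rule = ReactionRule("ManI", "(Ma2Ma", "(Ma",
...                     "!@2Ma3(...Ma6)Ma6 & !Ga3").parse()
>>> m9 = parse_glycan("Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN;Asn")
>>> for product, site in apply_rule(rule, m9):
...     print(site, serialize_glycan(product))
6 Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN;Asn
20 Ma2Ma2Ma3(Ma2Ma3(Ma6)Ma6)Mb4GNb4GN;Asn
```

M9 has three terminal `(Ma2Ma` sites, but only two products appear: the
trim at sentineled-string sites 6 (the lowest arm) and 20 (the upper arm)
pass the constraint, while the middle-branch site matches
`@2Ma3(...Ma6)Ma6` and is blocked by the negation. The Asn conjugate is
stripped for matching and re-attached to every product.

The same machinery drives the command line:

```sh
$ licorr canonicalize "Ab4(GNb4GNb3)(GNb6)Ab4Gb"
GNb4GNb3(Ab4)(GNb6)Ab4Gb
$ licorr convert --to licorrice --greek "Ab3(Fa4)GNb"
Gal(β1-3)[Fuc(α1-4)]GlcNAc(β1-
$ licorr modernize --string "~*2Ma3(...Ma6)Ma6"
!@2Ma3(...Ma6)Ma6
```

## Layout

| Module | Role |
| --- | --- |
| `licorr.registry` | monosaccharide/modification tables, dialect symbol maps |
| `licorr.core_model` | glycan tree, parser, canonical serializer, counting, uncertainty expansion |
| `licorr.pattern_engine` | sentineled-string wildcard matcher plus brute-force oracle |
| `licorr.constraint_lang` | constraint parsing, macros, evaluation, disjunction atomization |
| `licorr.rule_engine` | rule tables, modernization, reaction sites, rule application |
| `licorr.network_builder` | breadth-first network expansion and graph exports |
| `licorr.interop_licorrice` | IUPAC-condensed (LiCoRRICE) conversion |
| `licorr.fixtures` | seeded random glycans/patterns and the worked-example fixtures |
| `licorr.cli` | `licorr` command-line entry point |

See `docs/methods.md` for the notation semantics, design decisions, and
known limitations.
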