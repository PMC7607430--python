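# Methods

This note documents the notation semantics `licorr` implements, the
numerical and design choices made where the notation left room, what the
synthetic-data generator does and does not emulate, and known limitations.

## The glycan model

A glycan is a rooted tree of saccharide units (SUs). Each SU carries a
monosaccharide identity (1–2 uppercase letters resolved against a
registry; `*` for a wholly unknown SU, `?` for an unknown identity inside
a partly known one), an optional stereo/ring mark (`'`, `^`, `~`), a list
of modifications (`[2P]`, `[2,6D]` — positions accumulate until a code
consumes them), an optional possible-modification flag `$` (bare = any
modification set including none; `$[2P]` = unmodified or exactly that),
an anomer (`a`, `b`, `?`), and the carbon of the *parent* residue it is
attached by (1–9, `?`, or absent at the reducing-end root and in abstract
schematic notation). `o` in the position slot marks an open-chain
reducing end. Conjugates split at the last top-level `;`, `:` or `#` and
are carried through matching untouched. Uncertainty annotations —
`/`-element alternatives, `//`-whole-SU alternatives, and
`index%`-fragment placement — are retained on the tree and expanded on
demand.

The string form reads non-reducing (left) to reducing (right): each SU
attaches to the next SU to its right, parenthesized groups branch off
that same SU.

### Canonical branch order

Among the children of a node, the chain attached at the lowest carbon is
written on the unparenthesized backbone; the remaining chains are
parenthesized in ascending attachment order (so positions decrease
right-to-left from the parent). This single position rule replaces the
older residue-frequency ranking, which becomes redundant once the
position rule applies to all residues:
`Ab4(GNb4GNb3)(GNb6)Ab4Gb` canonicalizes to
`GNb4GNb3(Ab4)(GNb6)Ab4Gb`.

Tie-breaking where positions are missing:

* position `?` (stated-but-unknown) sorts after all known positions;
  remaining ties are broken lexicographically on the child's canonical
  serialization — deterministic and registry-independent;
* position *absent* (abstract schematic glycans such as `E(D(C)B)A`)
  keeps document order: there is no linkage information to sort on, and
  reordering would corrupt the published schematic examples.

The parser is structure-preserving; canonicality is a *warning* from
`validate`, never a parse error. Canonicalization is idempotent and
preserves the edge multiset (asserted in tests).

Modification lists canonicalize to ascending first-position order
(`A[6D,2N]` is accepted and emitted as `A[2N,6D]`); the descending form
seen in older material is therefore readable but not canonical.

## The pattern matcher

Matching operates on the **sentineled canonical string**: a `(` is
prefixed so the terminal end of every branch — including the backbone — is
a left parenthesis. `(GN` therefore means *terminal* GlcNAc while `GN`
matches any GlcNAc. Patterns need not have balanced parentheses.

Wildcard classes, defined purely on parentheses:

| wildcard | class |
| --- | --- |
| ligand `...` | all parentheses matched (includes `""`) |
| continuation `_` | every `(` closed later; `)` may be unmatched (includes `""`) |
| possible branch `+` | exactly `""`, `)`, `(B)` or `)(B)`, `B` balanced |
| any-SU `*` | exactly one complete SU token with its linkage |
| site `@` | zero width; binds an index, consumes nothing |

Every ligand is a continuation, and every branch shape is a continuation
(property-tested). For `+` we admit exactly one balanced group after the
optional close — `)(B1)(B2)` is not a branch, matching the enumerated
definition.

**Literal SUs are element-aligned with prefix consumption.** A literal
matches only at a subject SU-token boundary (so `A` never matches inside
`AN`) and consumes exactly the elements it spells out — identity, stereo,
modifications, anomer, position, in subject order — leaving trailing
elements unconsumed. This is what makes rule splicing linkage-preserving:
`(GN → (Ab4GN` applied at `(GNb2…` consumes only `(GN` and yields
`(Ab4GNb2…`. Two consequences are deliberate: a literal that specifies an
element *after* the modification slot (e.g. `GNb`) matches only
unmodified residues (use `$` for possibly-modified), and the
possibly-modified shorthand needs explicit linkage placeholders to bridge
to a following literal (`A$[2P]??GN`). Within literals, `?` matches any
anomer or any digit, `/`-sets match any member. Bare digits at the start
of a pattern (the linkage tail left of a reaction-site split, as in
`@2Ma3(...Ma6)Ma6`) are matched as raw characters.

All wildcard binding assignments are enumerated, not just a greedy one;
matches are deduplicated on (start, bindings) and ordered by start then
binding tuple. The matcher is recursive backtracking with class-aware
span generation; `brute_force_matches` is an independent oracle that
enumerates every split and filters by `classify_substring` plus literal
text/token-boundary checks. The two are held equal (set and order) on
1000 seeded random glycan/pattern pairs with sentineled length ≤ 40 —
sizes chosen so the exhaustive oracle stays exact and the whole suite
runs in seconds.

## Constraints

Precedence is `!` > `&` > `or`, with no grouping parentheses (parentheses
are glycan syntax; grouping is achieved by rule splitting). Whitespace is
ignored around operators, and `or` may abut the next atom (`or*...` as
printed in legacy tables). Count atoms accept both the `nA=0` and legacy
`#A = 0` spellings in every dialect — published LiCoRR tables still mix
them — and the IUPAC-condensed selector form `nMan(a1-?)>4`. Counting is
identity-exact: `nA` never counts `AN` residues.

A pattern atom without a site anchor is a global presence test
("`!Ma6`: the reaction will not happen if an α1-6 mannose is present
anywhere"). An anchored atom is true only if some match places its `@`
exactly at the rule's reaction site — the index of the first character at
which the substrate and product strings differ. The alternative
right-to-left site convention mentioned in the literature is not
implemented; only the left-to-right first-difference site is.

Macros are a name → pattern-text table (default: `Gnbis` =
`Ma3(GNb4)(...Ma6)Mb4`, the bisecting GlcNAc); expansion is textual with
cycle detection, resolved before evaluation, and unknown names only fail
at expansion time.

## Rules and networks

A rule row is enzyme, substrate pattern, product pattern, constraint,
optional compartment and EC number; any further columns (e.g. rates or
adjustment strings) ride along verbatim as annotations and are never
interpreted. Substrate and product must carry identical wildcard
sequences — bindings transfer positionally — and must not contain `@`
(the site is computed, not written). Application: for every substrate
match, splice the product with the transferred bindings, compute the site
against the pre-canonicalization spliced string, keep the product iff the
constraint holds at that site, then canonicalize, re-attach the
conjugate, deduplicate, and order by (site, product).

Network expansion is a breadth-first set closure — one iteration applies
every eligible rule to every frontier glycan; a rule therefore never acts
on its own product within the same generation. Termination is enforced by
hard limits (default 20 iterations, 30 SUs per expandable glycan, 10000
nodes) because processive elongation cycles (iGnT/b4GalT poly-LacNAc)
never terminate on their own; oversized glycans remain as nodes but are
not expanded, and any limit hit sets a `truncated` flag rather than
raising. With a compartment order (cis → medial → trans), each
compartment's rules run only after the previous stage stabilizes;
compartment-less rules are active in every stage. Exports (edge-list TSV,
GraphML via networkx, JSON) are emitted in sorted order and are
byte-identical under permuted seed order; permuting rule rows renumbers
`rule_id` (row index) but leaves the network otherwise identical.

## LiCoRRICE

Residues are rendered `Name(anomer c-position)` with the anomeric carbon
`c` taken from the registry (1 by default; 2 for Neu5Ac, Neu5Gc, Neu,
KDN, Kdo, fructose — fixed from carbohydrate convention, since published
tables only print linkages for 1-linked sugars), branches in square
brackets, modifications appended to the name (`Gal3S`), the reducing end
as an open `(b1-` tail when its anomer is known. Reading accepts greek or
latin anomers and a missing tail. Because IUPAC branching is not
deterministic, the three branch wildcards all collapse to `...` on
conversion; converting back maps `...` to the ligand class and flags the
result as lossy. Unknown SUs, stereo/ring marks, fragments and repeats
have no LiCoRRICE rendering and raise.

## Repeats and other notation edges

`{nGb4}` parses as a repeat annotation; `expand_repeats` concatenates the
unit head-to-tail and drops the final unit's dangling attachment
position, so three cellulose units give `Gb4Gb4Gb` and one gives `Gb`.
Cyclic tails (`c`) and head markers (`-X-`) are parsed and retained but
their connection semantics were never fully specified, so expansion of
such units is refused with an explicit unsupported-feature error rather
than guessed.

Fragment placement (`NNa6=1%|1%…`) attaches the fragment's root chain to
exactly one marked residue per expansion, in document order, left choice
first; expansions are deduplicated after canonicalization, and the
pre-deduplication count equals the product of per-choice cardinalities.

## The synthetic-data generator

`fixtures.random_glycan` draws trees from a seeded `random.Random`
stream: the common mammalian monosaccharide alphabet (Glc, Gal, GlcNAc,
GalNAc, Man, Neu5Ac, Fuc, Xyl), 0–2 children per node at distinct
attachment carbons from {2,3,4,6}, depth ≤ 3 (9-residue scale, matching
the N-glycan worked examples), 10% per-residue modification probability
and 5% unknown-anomer probability — enough to exercise every matcher code
path without dominating the strings. Outputs are canonical by
construction and bit-stable per seed. The generator emulates *structural*
diversity only: it knows nothing of biosynthetic reachability, empirical
branching frequencies, or real glycome abundances, so passing property
suites demonstrate notation correctness (round trips, matcher/oracle
agreement), not biological realism. `pattern_from_glycan` cuts a token
window from the sentineled string and replaces 0–2 non-overlapping spans
with wildcards valid for the removed substring, so the original window
witnesses at least one match — the guarantee the oracle-equivalence suite
relies on.

## Known limitations

* Glycopeptide-embedded notation (`PEP(AG(LY)CAN)TIDE`) is not parsed;
  its tokenization against amino-acid letters is ambiguous.
* Cyclic and head-marked repeat expansion is refused (see above).
* `//`-alternatives are implemented per-SU; multi-SU alternative chains
  have no published example and are not supported.
* The brute-force oracle compares literals textually (with `?` as a
  one-character anomer/digit class) and does not support `/`-alternative
  literals — which the generator never produces; the production matcher
  has no such restriction.
* Fragment (`%`) notation is retained in all dialects; the consensus
  table marks the legacy fragment divider as dropped, but the uncertainty
  rule that uses it has no replacement, so dropping it would lose
  information.
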