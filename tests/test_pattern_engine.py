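import pytest
from hypothesis import given
from hypothesis import strategies as st

from licorr.core_model import parse_glycan, serialize_glycan
from licorr.errors import ParseError
from licorr.fixtures import GenParams, pattern_from_glycan, random_glycan
from licorr.pattern_engine import (
    ANY_SU,
    BRANCH,
    CLOSE_PAREN,
    CONTINUATION,
    LIGAND,
    OPEN_PAREN,
    SITE,
    SU_LITERAL,
    Subject,
    brute_force_matches,
    classify_substring,
    find_matches,
    parse_pattern,
    sentinel,
)


def test_sentinel():
    assert sentinel("Ab3GNb") == "(Ab3GNb"
    assert sentinel("") == "("
    assert sentinel("GNb2Ma3(GNb2Ma6)Mb4GNb4GN") == "(GNb2Ma3(GNb2Ma6)Mb4GNb4GN"


class TestSubstringClasses:
    @pytest.mark.parametrize(
        "kind,s,expected",
        [
            (LIGAND, "XX(XXX)XX", True),
            (LIGAND, "XXX)X", False),
            (LIGAND, "XX(XX", False),
            (LIGAND, "X)(XX", False),
            (LIGAND, "", True),
            (CONTINUATION, "XXX)XX", True),
            (CONTINUATION, "X)(XX)XX", True),
            (CONTINUATION, "XX(XX", False),
            (CONTINUATION, "", True),
            (BRANCH, "", True),
            (BRANCH, ")", True),
            (BRANCH, "(C)", True),
            (BRANCH, ")(C)", True),
            (BRANCH, "((", False),
            (BRANCH, "C", False),
            (BRANCH, "(X)(Y)", False),  # one balanced group only
        ],
    )
    def test_membership(self, kind, s, expected):
        assert classify_substring(kind, s) is expected

    @given(st.text(alphabet="()X", max_size=12))
    def test_every_ligand_is_a_continuation(self, s):
        if classify_substring(LIGAND, s):
            assert classify_substring(CONTINUATION, s)

    @given(st.text(alphabet="()X", max_size=12))
    def test_every_branch_shape_is_a_continuation(self, s):
        if classify_substring(BRANCH, s):
            assert classify_substring(CONTINUATION, s)


class TestPatternParsing:
    def test_licorr_symbols(self, reg):
        p = parse_pattern("(GNb2+Ma3", "licorr", reg)
        assert [t.kind for t in p.tokens] == \
            [OPEN_PAREN, SU_LITERAL, BRANCH, SU_LITERAL]
        assert p.tokens[1].su.ms == "GN" and p.tokens[1].su.link_position == 2

    def test_legacy_symbols(self, reg):
        p = parse_pattern("Ma3|(*_Ma6)Mb4", "legacy", reg)
        assert [t.kind for t in p.tokens] == [
            SU_LITERAL, BRANCH, OPEN_PAREN, SITE, CONTINUATION,
            SU_LITERAL, CLOSE_PAREN, SU_LITERAL,
        ]

    def test_any_su_is_licorr_only(self, reg):
        p = parse_pattern("ANb3*A", "licorr", reg)
        assert [t.kind for t in p.tokens] == [SU_LITERAL, ANY_SU, SU_LITERAL]

    def test_duplicate_site_rejected(self, reg):
        with pytest.raises(ParseError):
            parse_pattern("@Ma3@Mb4", "licorr", reg)

    def test_site_split_linkage_digits_become_raw(self, reg):
        p = parse_pattern("@2Ma3(...Ma6)Ma6", "licorr", reg)
        assert p.tokens[0].kind == SITE
        assert p.tokens[1].kind == "RAW" and p.tokens[1].text == "2"


class TestFindMatches:
    def test_terminal_anchor_semantics(self, reg):
        g = parse_glycan("Ab3GNb")
        assert find_matches(parse_pattern("(GN"), g) == []
        assert len(find_matches(parse_pattern("GN"), g)) == 1

    def test_wildcard_bindings(self, areg):
        g = parse_glycan("E(D(C)B)A", registry=areg)
        (m,) = find_matches(parse_pattern("B_A", registry=areg), g, areg)
        assert m.bindings == (")",)
        (m,) = find_matches(parse_pattern("E(D_A", registry=areg), g, areg)
        assert m.bindings == ("(C)B)",)

    def test_branch_binds_empty(self, areg):
        g = parse_glycan("BA", registry=areg)
        (m,) = find_matches(parse_pattern("B+A", registry=areg), g, areg)
        assert m.bindings == ("",)

    def test_ligand_binds_branch(self, areg):
        g = parse_glycan("B(C)A", registry=areg)
        (m,) = find_matches(parse_pattern("B...A", registry=areg), g, areg)
        assert m.bindings == ("(C)",)

    def test_no_bisecting_glcnac_in_high_mannose(self, examples, reg):
        m9 = parse_glycan(examples["m9.core"])
        assert find_matches(parse_pattern("Ma3(GNb4)(_Ma6)Mb4"), m9) == []

    def test_matches_are_ordered_and_distinct(self, examples, reg):
        m9 = parse_glycan(examples["m9.core"])
        matches = find_matches(parse_pattern("(Ma2Ma"), m9)
        starts = [m.start for m in matches]
        assert starts == sorted(starts) and len(set(starts)) == 3

    def test_substitution_soundness(self, examples, reg, areg):
        cases = [
            ("(Ma2Ma", examples["m9.core"], reg),
            ("B_A", "E(D(C)B)A", areg),
            ("GNb2+Ma3", examples["biantennary"], reg),
        ]
        for pat, gly, r in cases:
            g = parse_glycan(gly, registry=r)
            subject = Subject.from_glycan(g, r)
            for m in find_matches(parse_pattern(pat, registry=r), g, r):
                recon = "".join(subject.text[a:b] for _, a, b in m.token_spans)
                assert recon == subject.text[m.start : m.end]

    def test_open_paren_anchors_at_leaves_only(self, reg):
        # in a sentineled canonical string each "(" precedes exactly one
        # branch-terminal residue, so "(X" matches count = leaf X count
        for seed in range(30):
            g = random_glycan(GenParams(seed=seed))
            subject = Subject.from_glycan(g, reg)
            leaves = [n.su.ms for n in g.iter_nodes() if not n.children]
            assert subject.text.count("(") == len(leaves)
            for ms in {n.su.ms for n in g.iter_nodes()}:
                p = parse_pattern("(" + ms)
                matches = find_matches(p, g, reg)
                assert len(matches) == leaves.count(ms)
                assert all(subject.text[m.start] == "(" for m in matches)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(250))
    def test_matcher_equals_brute_force(self, seed, reg):
        g = random_glycan(GenParams(seed=seed, max_depth=3))
        subject = Subject.from_glycan(g, reg)
        if len(subject.text) > 40:
            return
        p = pattern_from_glycan(g, seed * 7 + 1, reg)
        fast = find_matches(p, g, reg)
        slow = brute_force_matches(p, g, 60, reg)
        assert fast == slow
        assert len(fast) >= 1  # the construction guarantees a witness

    def test_oracle_guard(self, reg):
        g = parse_glycan("Ab3GNb")
        with pytest.raises(Exception):
            brute_force_matches(parse_pattern("GN"), g, max_len=3, registry=reg)

    def test_no_balanced_binding_no_match(self, areg):
        subject = Subject.from_raw("B(CA", areg)
        p = parse_pattern("B...A", registry=areg)
        assert find_matches(p, subject, areg) == []
        assert brute_force_matches(p, subject, 60, areg) == []


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(60))
    def test_ligand_matches_are_continuation_matches(self, seed, reg):
        # "..." accepts a subset of what "_" accepts at every position
        g = random_glycan(GenParams(seed=seed, max_depth=2))
        p_lig = pattern_from_glycan(g, seed + 1000, reg)
        if LIGAND not in [t.kind for t in p_lig.tokens]:
            return
        from licorr.pattern_engine import Pattern, PatternToken

        cont_tokens = [
            PatternToken(CONTINUATION, "_") if t.kind == LIGAND else t
            for t in p_lig.tokens
        ]
        p_cont = Pattern(cont_tokens, "licorr", "")
        lig_keys = {(m.start, m.end) for m in find_matches(p_lig, g, reg)}
        cont_keys = {(m.start, m.end) for m in find_matches(p_cont, g, reg)}
        assert lig_keys <= cont_keys
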