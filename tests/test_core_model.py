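import pytest

from licorr.core_model import (
    LicorriceSelector,
    alternative_count,
    canonicalize,
    count_residues,
    edge_multiset,
    enumerate_alternatives,
    expand_repeats,
    parse_glycan,
    serialize_glycan,
    tokenize_glycan_body,
    validate,
)
from licorr.errors import ParseError, UnsupportedFeatureError
from licorr.fixtures import GenParams, random_glycan


class TestParsing:
    def test_simple_disaccharide_structure(self):
        g = parse_glycan("Ab3GNb")
        assert g.root.su.ms == "GN" and g.root.su.anomer == "b"
        assert g.root.su.link_position is None
        (child,) = g.root.children
        assert child.su.ms == "A" and child.su.anomer == "b"
        assert child.su.link_position == 3

    def test_modification_parse(self):
        g = parse_glycan("A[2P]b3Gb")
        (child,) = g.root.children
        ((positions, code),) = [
            (m.positions, m.code) for m in child.su.modifications
        ]
        assert positions == (2,) and code == "P"

    def test_unknown_su(self):
        g = parse_glycan("ANb3*A")
        assert count_residues(g) == 3
        middle = g.root.children[0]
        assert middle.su.ms == "*"

    def test_conjugates_are_split_and_kept(self):
        for text, sep in [("Gb:C", ":"), ("Ga;NY-S-C", ";"),
                          ("GNb3Ab#4-Trifluoroacetamidophenol", "#")]:
            g = parse_glycan(text)
            assert g.conjugate[0] == sep
            assert serialize_glycan(g) == text

    def test_open_form(self):
        g = parse_glycan("AbG[P]o")
        assert g.root.su.open_form
        assert serialize_glycan(g) == "AbG[P]o"

    @pytest.mark.parametrize(
        "text,code",
        [
            ("", "E_EMPTY"),
            ("Ab3(GNb", "E_PAREN"),
            ("Ab3()Gb", "E_EMPTY_BRANCH"),
            ("QQb3Gb", "E_UNKNOWN_MS"),
            ("G3Gb", "E_POSITION"),
        ],
    )
    def test_parse_errors_carry_codes(self, text, code):
        with pytest.raises(ParseError) as err:
            parse_glycan(text)
        assert err.value.code == code

    def test_uncertainty_forms_round_trip(self):
        for text in ["AN?3Gb", "AN??Gb", "ANb3/4Gb", "A???b"]:
            assert canonicalize(text) == text


class TestCanonicalization:
    def test_branch_reorder_worked_example(self, examples):
        assert canonicalize(examples["branch_reorder.input"]) == \
            examples["branch_reorder.canonical"]

    def test_already_canonical_is_fixed_point(self, examples):
        assert canonicalize("Ab3(Fa4)GNb") == "Ab3(Fa4)GNb"
        assert canonicalize("Gb") == "Gb"

    def test_modification_order_normalized(self):
        # ascending first-position order; the descending form is accepted
        assert canonicalize("A[6D,2N]b3Gb") == "A[2N,6D]b3Gb"
        assert canonicalize("A[2,6D]a3Gb") == "A[2,6D]a3Gb"

    def test_canonicalization_preserves_edges(self, examples):
        g1 = parse_glycan(examples["branch_reorder.input"])
        g2 = parse_glycan(canonicalize(examples["branch_reorder.input"]))
        assert edge_multiset(g1) == edge_multiset(g2)

    def test_abstract_document_order_is_kept(self, areg):
        # schematic glycans carry no positions: nothing to sort on
        for text in ["E(D(C)B)A", "B(C)A", "KJ(IH)GF(D(E)(C)B)A"]:
            assert canonicalize(text, registry=areg) == text

    @pytest.mark.parametrize("seed", range(300))
    def test_round_trip_and_idempotence(self, seed):
        g = random_glycan(GenParams(seed=seed))
        s = serialize_glycan(g)
        assert serialize_glycan(parse_glycan(s)) == s
        assert canonicalize(canonicalize(s)) == canonicalize(s)


class TestCounting:
    def test_counts(self, examples, reg):
        assert count_residues(parse_glycan("Gb")) == 1
        m9 = parse_glycan(examples["m9"])
        assert count_residues(m9, "M") == 9
        assert count_residues(m9) == 11

    def test_identity_counting_is_exact(self):
        g = parse_glycan("ANb3ANb4Gb")
        assert count_residues(g, "A") == 0
        assert count_residues(g, "AN") == 2

    def test_licorrice_selector(self, examples):
        m9 = parse_glycan(examples["m9"])
        assert count_residues(m9, LicorriceSelector("Man", "a")) == 8
        assert count_residues(m9, LicorriceSelector("Man", "a", 3)) == 2

    def test_count_matches_tokenizer(self, reg):
        for seed in range(50):
            g = random_glycan(GenParams(seed=seed))
            body = serialize_glycan(g)
            tokens = [t for t in tokenize_glycan_body(body, reg) if t[0] == "SU"]
            assert count_residues(g) == len(tokens)


class TestAlternatives:
    def test_whole_su_alternatives(self, examples):
        out = [serialize_glycan(g) for g in
               enumerate_alternatives(parse_glycan(examples["ur5.input"]))]
        assert out == list(examples["ur5.expansions"])

    def test_no_uncertainty_is_identity(self):
        out = enumerate_alternatives(parse_glycan("Gb"))
        assert [serialize_glycan(g) for g in out] == ["Gb"]

    def test_fragment_placement(self, examples):
        g = parse_glycan(examples["ur6.input"])
        out = [serialize_glycan(x) for x in enumerate_alternatives(g)]
        assert out == [
            "NNa6Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4Gb",
            "Ab4GNb2Ma3(NNa6Ab4GNb2Ma6)Mb4Gb",
        ]

    def test_position_alternatives(self):
        out = [serialize_glycan(g) for g in
               enumerate_alternatives(parse_glycan("ANb3/4Gb"))]
        assert out == ["ANb3Gb", "ANb4Gb"]

    def test_output_size_matches_choice_product(self, examples):
        for text in [examples["ur5.input"], examples["ur6.input"], "ANb3/4Gb"]:
            g = parse_glycan(text)
            assert len(enumerate_alternatives(g)) == alternative_count(g)


class TestRepeats:
    def test_linear_repeat_expansion(self):
        g = parse_glycan("{nGb4}")
        assert serialize_glycan(expand_repeats(g, 3)) == "Gb4Gb4Gb"
        assert serialize_glycan(expand_repeats(g, 1)) == "Gb"

    def test_no_repeat_is_unchanged(self):
        g = parse_glycan("Gb")
        assert expand_repeats(g, 5) is g

    def test_cyclic_repeat_refused(self):
        g = parse_glycan("{nGa6Hca3Ha3}")
        with pytest.raises(UnsupportedFeatureError):
            expand_repeats(g, 2)

    def test_repeat_annotation_round_trips(self):
        assert canonicalize("{nGb4}") == "{nGb4}"
        assert canonicalize("{3Gb4}") == "{3Gb4}"


class TestValidate:
    def test_clean_string(self):
        assert validate("Ab3GNb") == []

    def test_noncanonical_is_warning(self, examples):
        diags = validate(examples["branch_reorder.input"])
        assert len(diags) == 1 and diags[0].severity == "warning"
        assert diags[0].code == "W_NONCANONICAL"

    def test_unbalanced_is_error(self):
        diags = validate("Ab3(GNb")
        assert len(diags) == 1 and diags[0].severity == "error"
        assert diags[0].offset == 7
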