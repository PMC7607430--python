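import io

import pytest

from licorr.constraint_lang import constraint_signature, parse_constraint
from licorr.core_model import count_residues, parse_glycan, serialize_glycan, validate
from licorr.errors import LicorrError, RuleError
from licorr.fixtures import (
    legacy_of,
    published_fixtures,
    table7_rules,
    table8_rules,
    table9_rules,
)
from licorr.pattern_engine import parse_pattern
from licorr.rule_engine import (
    ReactionRule,
    apply_rule,
    compute_site,
    modernize,
    modernize_table,
    read_rule_table,
    split_rules,
    write_rule_table,
)


class TestTableIO:
    def test_read_published_galt_table(self):
        t = table8_rules()
        assert len(t) == 4 and not t.errors
        assert {r.substrate_text for r in t} == {"(GN"}
        assert {r.product_text for r in t} == {"(Ab4GN"}

    def test_header_only_table(self):
        t = read_rule_table("enzyme\tsubstrate\tproduct\tconstraint\n")
        assert len(t) == 0

    def test_published_nglycan_ruleset_parses(self):
        t = table9_rules()
        assert len(t) == 13 and t.errors == []

    def test_missing_column_raises(self):
        with pytest.raises(RuleError):
            read_rule_table("enzyme\tsubstrate\tproduct\nX\t(GN\t(Ab4GN\n")

    def test_bad_row_is_reported_not_fatal(self):
        text = (
            "enzyme\tsubstrate\tproduct\tconstraint\n"
            "ok\t(GN\t(Ab4GN\t\n"
            "bad\t(QQQQ##\t(Ab4GN\t\n"
        )
        t = read_rule_table(text)
        assert len(t) == 1 and len(t.errors) == 1 and t.errors[0][0] == 3
        with pytest.raises(RuleError):
            read_rule_table(text, strict=True)

    def test_csv_accepted(self):
        t = read_rule_table("enzyme,substrate,product,constraint\nE,(GN,(Ab4GN,\n")
        assert len(t) == 1

    def test_write_read_round_trip(self):
        t = table8_rules()
        buf = io.StringIO()
        write_rule_table(t, buf)
        t2 = read_rule_table(buf.getvalue(), dialect="legacy")
        assert [
            (r.enzyme, r.substrate_text, r.product_text, r.constraint_text)
            for r in t
        ] == [
            (r.enzyme, r.substrate_text, r.product_text, r.constraint_text)
            for r in t2
        ]

    def test_compartment_and_ec_preserved(self):
        text = (
            "enzyme\tsubstrate\tproduct\tconstraint\tcompartment\tec\n"
            "b4GalT\t(GN\t(Ab4GN\t\ttrans\t2.4.1.38\n"
        )
        t = read_rule_table(text)
        rule = t.rules[0]
        assert rule.compartment == "trans" and rule.ec_number == "2.4.1.38"
        buf = io.StringIO()
        write_rule_table(t, buf)
        assert "trans" in buf.getvalue() and "2.4.1.38" in buf.getvalue()

    def test_rate_columns_survive_as_annotations(self):
        text = (
            "enzyme\tsubstrate\tproduct\tconstraint\trate\n"
            "E\t(GN\t(Ab4GN\t\t0.73\n"
        )
        t = read_rule_table(text)
        assert t.rules[0].annotations == {"rate": "0.73"}


class TestModernize:
    @pytest.mark.parametrize(
        "legacy,expected,role",
        [
            ("~Ma6", "!Ma6", "constraint"),
            ("*...GNb2|Ma3", "@...GNb2+Ma3", "constraint"),
            ("#A = 0", "nA=0", "constraint"),
            ("(GNb2|Ma3", "(GNb2+Ma3", "pattern"),
        ],
    )
    def test_symbol_translation(self, legacy, expected, role):
        assert modernize(legacy, role) == expected

    def test_equivalence_on_published_legacy_strings(self, reg):
        examples = published_fixtures()
        legacy_cells = []
        for tsv in (examples["table7.tsv"], examples["table9.legacy_tsv"]):
            for line in tsv.strip().splitlines()[1:]:
                cells = line.split("\t")
                legacy_cells.append(("pattern", cells[1]))
                legacy_cells.append(("pattern", cells[2]))
                if len(cells) > 3 and cells[3]:
                    legacy_cells.append(("constraint", cells[3]))
        assert len(legacy_cells) > 20
        for role, cell in legacy_cells:
            modern = modernize(cell, role)
            if role == "constraint":
                a = parse_constraint(cell, "legacy", reg)
                b = parse_constraint(modern, "licorr", reg)
                assert constraint_signature(a) == constraint_signature(b), cell
            else:
                from licorr.constraint_lang import pattern_signature

                a = parse_pattern(cell, "legacy", reg)
                b = parse_pattern(modern, "licorr", reg)
                assert pattern_signature(a) == pattern_signature(b), cell

    def test_modernized_table_parses_as_licorr(self):
        t = modernize_table(table7_rules())
        assert t.rules[0].dialect == "licorr"
        assert "or" in t.rules[0].constraint_text
        assert "|" not in t.rules[0].constraint_text


class TestComputeSite:
    def test_first_difference(self):
        assert compute_site(
            "(GNb2Ma3(GNb2Ma6)Mb4GNb4GN", "(Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4GN"
        ) == 1

    def test_identical_strings_error(self):
        with pytest.raises(LicorrError):
            compute_site("(Ma", "(Ma")

    def test_m9_middle_branch_site(self, examples):
        sub = "(" + examples["m9.core"]
        prod = "(" + "Ma2Ma2Ma3(Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"
        assert compute_site(sub, prod) == 13


class TestApplyRule:
    def test_fucosylation_worked_example(self, examples):
        rule = ReactionRule("FucT", examples["table1.reactant"],
                            examples["table1.product"]).parse()
        out = apply_rule(rule, parse_glycan(examples["table1.reactant"]))
        assert [serialize_glycan(g) for g, _ in out] == [examples["table1.product"]]

    def test_galt_adds_to_both_arms(self, examples):
        rule = ReactionRule("b4GalT", "(GN", "(Ab4GN").parse()
        out = apply_rule(rule, parse_glycan(examples["biantennary"]))
        assert [serialize_glycan(g) for g, _ in out] == [
            "Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4GN",
            "GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4GN",
        ]

    def test_mani_blocks_middle_branch(self, examples):
        rule = ReactionRule("ManI", examples["manI.substrate"],
                            examples["manI.product"],
                            examples["manI.constraint"]).parse()
        out = apply_rule(rule, parse_glycan(examples["m9"]))
        products = [serialize_glycan(g) for g, _ in out]
        assert len(out) == 2
        blocked = "Ma2Ma2Ma3(Ma3(Ma2Ma6)Ma6)Mb4GNb4GN;Asn"
        assert blocked not in products
        # conjugate is stripped for matching and re-attached
        assert all(p.endswith(";Asn") for p in products)

    def test_no_match_is_empty(self, examples):
        rule = ReactionRule("b4GalT", "(GN", "(Ab4GN").parse()
        assert apply_rule(rule, parse_glycan("Ma3(Ma6)Mb4")) == []

    def test_products_are_canonical_and_grow_by_pattern_delta(self, examples):
        rule = ReactionRule("GnTV", "(GNb2Ma6", "(GNb2(GNb6)Ma6").parse()
        g = parse_glycan(examples["biantennary"])
        for product, _ in apply_rule(rule, g):
            text = serialize_glycan(product)
            assert validate(text) == []
            assert count_residues(product) == count_residues(g) + 1

    def test_wildcard_sequence_mismatch_rejected(self):
        with pytest.raises(RuleError):
            ReactionRule("bad", "(GN...Ma3", "(Ab4GN+Ma3").parse()

    def test_site_marker_in_rule_pattern_rejected(self):
        with pytest.raises(RuleError):
            ReactionRule("bad", "(@GN", "(Ab4GN").parse()

    def test_wildcard_binding_transfer(self, examples):
        # GnTII carries a possible-branch wildcard through to the product
        t = table9_rules()
        gnt2 = next(r for r in t if r.enzyme == "GnTII")
        g = parse_glycan("GNb2Ma3(Ma6)Mb4GNb4GN")
        out = apply_rule(gnt2, g)
        assert [serialize_glycan(p) for p, _ in out] == [examples["biantennary"]]


class TestSplitRules:
    def test_table7_splits_into_table8(self):
        split = split_rules(table7_rules())
        published = table8_rules()
        assert len(split) == 4
        assert [r.constraint_text for r in split] == [
            r.constraint_text for r in published
        ]

    def test_empty_constraint_passes_through(self):
        t = read_rule_table("enzyme\tsubstrate\tproduct\tconstraint\nE\t(GN\t(Ab4GN\t\n")
        assert split_rules(t).rules == t.rules

    def test_and_of_or_distributes(self, reg):
        t = read_rule_table(
            "enzyme\tsubstrate\tproduct\tconstraint\n"
            "E\t(GN\t(Ab4GN\tMa3 & Ma6 or Ga3\n"
        )
        # OR binds loosest: (Ma3 & Ma6) or Ga3 -> two rows
        assert len(split_rules(t)) == 2

    @pytest.mark.parametrize("table_maker", [table7_rules, table9_rules])
    def test_split_equivalence_of_products(self, table_maker, examples):
        glycans = [
            parse_glycan(examples["biantennary"]),
            parse_glycan(examples["m9"]),
            parse_glycan("Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4GN"),
        ]
        whole = table_maker()
        split = split_rules(whole)
        for g in glycans:
            prods_whole = {
                (serialize_glycan(p), s)
                for r in whole
                for p, s in apply_rule(r, g)
            }
            prods_split = {
                (serialize_glycan(p), s)
                for r in split
                for p, s in apply_rule(r, g)
            }
            assert prods_whole == prods_split


def test_legacy_of_inverts_modernize():
    for cell in ["!Ma6", "@...GNb2+Ma3", "nA=0", "!@2Ma3(...Ma6)Ma6 & !Ga3"]:
        assert modernize(legacy_of(cell), "constraint") == cell
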