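"""Template parsing, bridge generation, renaming, and term generation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gochem.biochebi import build_biochebi
from gochem.defgen import (
    assemble_label,
    bridge_ontologies,
    containing_compound_rename,
    default_rules,
    extract_logical_definitions,
    generate_term,
    make_logical_definition,
    parse_label,
)
from gochem.errors import DuplicateTermError, MissingChemicalError
from gochem.lexicon import MatchResult
from gochem.model import (
    Existential,
    Intersection,
    Named,
    Ontology,
    equivalent_classes,
)


def rules_by_id():
    return {r.id: r for r in default_rules()}


class TestDefaultRules:
    @pytest.mark.parametrize(
        "rule_id,genus,relation",
        [
            ("metabolic", "GO:0008152", "has_participant"),
            ("biosynthetic", "GO:0009058", "has_output"),
            ("catabolic", "GO:0009056", "has_input"),
            ("transport", "GO:0006810",
             "transports_or_maintains_localization_of"),
            ("response_to", "GO:0050896", "has_input"),
            ("binding", "GO:0005488", "has_input"),
        ],
    )
    def test_core_rule_table(self, rule_id, genus, relation):
        rule = rules_by_id()[rule_id]
        assert rule.genus == genus
        assert rule.relation == relation
        assert not rule.extension

    def test_extension_families_are_flagged(self):
        rules = rules_by_id()
        assert {r for r, v in rules.items() if v.extension} == {
            "secretion",
            "homeostasis",
            "transporter_activity",
        }

    def test_priority_prevents_substring_capture(self):
        rules = rules_by_id()
        assert rules["biosynthetic"].priority > rules["metabolic"].priority
        assert rules["catabolic"].priority > rules["biosynthetic"].priority
        assert (
            rules["transporter_activity"].priority
            > rules["transport"].priority
        )


class TestParseLabel:
    @pytest.mark.parametrize(
        "label,rule_id,chemical",
        [
            ("xanthine biosynthetic process", "biosynthetic", "xanthine"),
            ("glucose-6-phosphate transport", "transport",
             "glucose-6-phosphate"),
            ("carbohydrate binding", "binding", "carbohydrate"),
            ("response to citrate(1-)", "response_to", "citrate(1-)"),
            ("glucose transporter activity", "transporter_activity",
             "glucose"),
            ("calcium ion homeostasis", "homeostasis", "calcium ion"),
        ],
    )
    def test_examples(self, label, rule_id, chemical):
        parsed = parse_label(label)
        assert parsed is not None
        assert (parsed.rule.id, parsed.chemical_string) == (rule_id, chemical)

    @pytest.mark.parametrize(
        "label",
        [
            "binding",
            "transport",
            "regulation of xanthine biosynthetic process",
            "positive regulation of glucose transport",
            "negative regulation of carbohydrate binding",
            "protein folding",
        ],
    )
    def test_non_chemical_labels_return_none(self, label):
        assert parse_label(label) is None

    def test_biosynthetic_not_captured_by_metabolic_rule(self):
        parsed = parse_label("x biosynthetic process")
        assert parsed.rule.id == "biosynthetic"
        assert parsed.chemical_string == "x"

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sampled_from([r.id for r in default_rules()]),
        st.from_regex(r"[a-z][a-z0-9,()\- ]{0,20}[a-z0-9)]", fullmatch=True),
    )
    def test_parse_assemble_inverse(self, rule_id, chemical):
        """Reassembling a parsed label reproduces the input, for chemical
        strings free of template keywords."""
        keywords = (
            "metabolic", "biosynthetic", "catabolic", "transport",
            "binding", "secretion", "homeostasis", "response",
        )
        if any(k in chemical for k in keywords):
            return
        rule = rules_by_id()[rule_id]
        label = assemble_label(rule, chemical)
        parsed = parse_label(label)
        assert parsed is not None
        assert (parsed.rule.id, parsed.chemical_string) == (rule_id, chemical)


class TestLogicalDefinitions:
    def test_carbohydrate_binding_definition(self):
        parsed = parse_label("carbohydrate binding")
        match = MatchResult("carbohydrate", "CHEBI:16646", "label")
        ld, ax = make_logical_definition("GO:0030246", parsed, match)
        assert ld.genus == "GO:0005488"
        assert ld.differentia == (("has_input", "CHEBI:16646"),)
        assert ax == equivalent_classes(
            Named("GO:0030246"),
            Intersection(
                (
                    Named("GO:0005488"),
                    Existential("has_input", Named("CHEBI:16646")),
                )
            ),
            provenance="bridge",
        )

    def test_temporary_filler_propagates_provenance(self):
        parsed = parse_label("aldoxime metabolic process")
        match = MatchResult("aldoxime", "GOCHE:0000001", "temporary")
        _, ax = make_logical_definition("FIX:go_aldoxime_mp", parsed, match)
        assert ax.provenance == "temporary"

    def test_definitions_round_trip_through_extraction(self, bridge):
        ont = Ontology("defs")
        for ld in bridge.definitions:
            from gochem.model import Term

            ont.add_term(Term(id=ld.defined))
        for ax in bridge.axioms:
            ont.add_axiom(ax)
        assert sorted(extract_logical_definitions(ont)) == sorted(
            bridge.definitions
        )


class TestBridge:
    def test_every_matched_term_gets_exactly_one_definition(
        self, bundle, bridge
    ):
        defined = [ld.defined for ld in bridge.definitions]
        assert len(defined) == len(set(defined))
        assert len(defined) == bundle.expected["defined_terms"]
        assert bridge.unmatched == bundle.expected["unmatched"]

    def test_family_counts_match_hand_enumeration(self, bundle, bridge):
        assert bridge.counts == bundle.expected["family_counts"]

    def test_empty_process_ontology_empty_bridge(self, bundle):
        result = bridge_ontologies(Ontology("empty"), bundle.mini_chebi)
        assert result.axioms == [] and result.definitions == []

    def test_deterministic_output(self, bundle):
        r1 = bridge_ontologies(bundle.mini_go, bundle.mini_chebi)
        r2 = bridge_ontologies(bundle.mini_go, bundle.mini_chebi)
        assert r1.axioms == r2.axioms
        assert r1.unmatched_tsv() == r2.unmatched_tsv()
        assert r1.counts_tsv() == r2.counts_tsv()

    def test_single_genus_single_differentia_everywhere(self, bridge):
        for ld in bridge.definitions:
            assert len(ld.differentia) == 1


class TestContainingCompoundRename:
    @pytest.mark.parametrize(
        "label,family,expected",
        [
            (
                "phenol metabolic process",
                "phenols",
                "phenol-containing compound metabolic process",
            ),
            (
                "pyridine catabolic process",
                "pyridines",
                "pyridine-containing compound catabolic process",
            ),
            # EXACT reading: the chemical is one molecule, not a family
            ("benzene metabolic process", "benzene",
             "benzene metabolic process"),
        ],
    )
    def test_examples(self, label, family, expected):
        assert containing_compound_rename(label, family) == expected

    def test_label_without_chemical_token_raises(self):
        with pytest.raises(ValueError):
            containing_compound_rename("binding", "phenols")

    def test_non_plural_family_mismatch_raises(self):
        with pytest.raises(ValueError, match="manual review"):
            containing_compound_rename(
                "phenol metabolic process", "quinolines"
            )


@pytest.fixture
def go_without_xanthine_term(bundle):
    go = bundle.mini_go.copy()
    del go.terms["FIX:go_xanthine_bp"]
    for ax in [
        a
        for a in go.axioms
        if isinstance(a.a, Named) and a.a.id == "FIX:go_xanthine_bp"
    ]:
        go.remove_axiom(ax)
    return go


class TestGenerateTerm:
    def test_xanthine_biosynthesis_generated_and_placed(
        self, bundle, go_without_xanthine_term
    ):
        go = go_without_xanthine_term
        result = bridge_ontologies(go, bundle.mini_chebi)
        overlay = build_biochebi(bundle.mini_chebi)
        gcis = [ax for ax in overlay.axioms if ax.provenance == "gci"]
        record = generate_term(
            rules_by_id()["biosynthetic"],
            "FIX:xanthine",
            go,
            bundle.mini_chebi,
            gcis=gcis,
            bridge_axioms=result.axioms,
        )
        assert record.term.label == "xanthine biosynthetic process"
        assert record.term.textual_definition == (
            "The chemical reactions and pathways resulting in the "
            "formation of xanthine."
        )
        # EXACT synonyms inherited from the chemical's EXACT synonyms
        assert [s.text for s in record.term.synonyms] == [
            "2,6-dihydroxypurine biosynthetic process"
        ]
        assert all(s.scope == "EXACT" for s in record.term.synonyms)
        # placed under the most specific biosynthesis parent, not the genus
        assert record.placement == ("FIX:go_purine_bp",)

    def test_missing_chemical_is_a_request_needed_error(self, bundle):
        with pytest.raises(MissingChemicalError, match="request missing"):
            generate_term(
                rules_by_id()["transport"],
                "FIX:aldoxime",
                bundle.mini_go,
                bundle.mini_chebi,
            )

    def test_duplicate_label_rejected(self, bundle):
        with pytest.raises(DuplicateTermError):
            generate_term(
                rules_by_id()["biosynthetic"],
                "FIX:xanthine",
                bundle.mini_go,
                bundle.mini_chebi,
            )
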