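"""Conjugate pair detection, GCI generation, overlay and import subset."""

import pytest

from gochem.biochebi import (
    EXTENDED_GCI_RELATIONS,
    PSEUDOCODE_RELATIONS,
    ConjugatePair,
    build_biochebi,
    find_conjugate_pairs,
    generate_gcis,
    import_subset,
    strip_gcis,
)
from gochem.errors import ConfigurationError, ResolutionError
from gochem.model import (
    Existential,
    Named,
    Ontology,
    Term,
    equivalent_classes,
    subclass_of,
)
from gochem.reasoner import classify_axioms


def citrate_chain_pairs(bundle):
    return {
        p
        for p in find_conjugate_pairs(bundle.mini_chebi)
        if p.pair & {"FIX:citric_acid", "FIX:citrate1", "FIX:citrate2",
                     "FIX:citrate3"}
    }


class TestFindPairs:
    def test_fixture_has_four_pairs(self, bundle):
        pairs = find_conjugate_pairs(bundle.mini_chebi)
        assert len(pairs) == bundle.expected["conjugate_pairs"]
        assert {p.pair for p in pairs} == {
            frozenset({"FIX:nta_acid", "FIX:nta"}),
            frozenset({"FIX:citric_acid", "FIX:citrate1"}),
            frozenset({"FIX:citrate1", "FIX:citrate2"}),
            frozenset({"FIX:citrate2", "FIX:citrate3"}),
        }

    def test_citric_chain_has_three_adjacent_pairs(self, bundle):
        assert len(citrate_chain_pairs(bundle)) == 3

    def test_no_conjugate_relations_no_pairs(self):
        ont = Ontology("plain")
        ont.add_term(Term(id="C:1", label="x"))
        assert find_conjugate_pairs(ont) == set()

    def test_both_directions_asserted_counted_once(self, bundle):
        # citric acid -> citrate(1-) is asserted acid_of AND base_of
        (pair,) = [
            p
            for p in find_conjugate_pairs(bundle.mini_chebi)
            if p.pair == frozenset({"FIX:citric_acid", "FIX:citrate1"})
        ]
        assert pair.evidence == frozenset(
            {"acid_of_asserted", "base_of_asserted"}
        )

    def test_pair_invariants(self):
        with pytest.raises(ValueError):
            ConjugatePair(frozenset({"C:1"}), frozenset({"acid_of_asserted"}))
        with pytest.raises(ValueError):
            ConjugatePair(frozenset({"C:1", "C:2"}), frozenset())


class TestGenerateGcis:
    def test_citrate_chain_times_four_relations_is_twelve(self, bundle):
        axioms = generate_gcis(citrate_chain_pairs(bundle))
        assert len(axioms) == 12
        assert all(ax.provenance == "gci" for ax in axioms)
        assert all(ax.kind == "equivalent_classes" for ax in axioms)

    def test_single_pair_single_relation(self):
        pair = ConjugatePair(
            frozenset({"FIX:citric_acid", "FIX:citrate1"}),
            frozenset({"base_of_asserted"}),
        )
        (ax,) = generate_gcis({pair}, ["has_input"])
        assert ax == equivalent_classes(
            Existential("has_input", Named("FIX:citric_acid")),
            Existential("has_input", Named("FIX:citrate1")),
            provenance="gci",
        )

    def test_empty_pair_set(self):
        assert generate_gcis(set()) == []

    def test_symmetric_under_pair_orientation(self):
        p1 = ConjugatePair(
            frozenset({"C:acid", "C:base"}), frozenset({"acid_of_asserted"})
        )
        p2 = ConjugatePair(
            frozenset({"C:base", "C:acid"}), frozenset({"base_of_asserted"})
        )
        assert generate_gcis({p1}) == generate_gcis({p2})

    def test_default_relations_are_the_four_pseudocode_ones(self):
        assert PSEUDOCODE_RELATIONS == (
            "has_participant",
            "transports",
            "has_input",
            "has_output",
        )

    def test_unknown_relation_is_a_configuration_error(self):
        pair = ConjugatePair(
            frozenset({"C:1", "C:2"}), frozenset({"acid_of_asserted"})
        )
        with pytest.raises(ConfigurationError):
            generate_gcis({pair}, ["not_a_relation"])


class TestBuildOverlay:
    def test_gci_count_is_four_times_pair_count(self, bundle):
        overlay = build_biochebi(bundle.mini_chebi)
        gcis = [ax for ax in overlay.axioms if ax.provenance == "gci"]
        assert len(gcis) == 4 * bundle.expected["conjugate_pairs"]

    def test_chem_without_conjugates_unchanged_axioms(self):
        ont = Ontology("plain")
        ont.header = [("format-version", "1.2")]
        ont.add_term(Term(id="C:1", label="x"))
        overlay = build_biochebi(ont)
        assert overlay.axioms == ont.axioms

    def test_stripping_gcis_recovers_input_axioms(self, bundle):
        overlay = build_biochebi(bundle.mini_chebi)
        stripped = strip_gcis(overlay)
        assert stripped.axioms_sorted() == bundle.mini_chebi.axioms_sorted()
        assert stripped.terms == bundle.mini_chebi.terms

    def test_transports_registered_under_full_transport_relation(
        self, bundle
    ):
        overlay = build_biochebi(bundle.mini_chebi, EXTENDED_GCI_RELATIONS)
        rel = overlay.relations["transports"]
        assert "transports_or_maintains_localization_of" in rel.parents


class TestChainEquivalence:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_chain_of_length_k_reasons_to_equivalence(self, k):
        """Processes over any two members of a conjugate chain become
        equivalent under the GCIs, for every default relation."""
        ont = Ontology("chain")
        ids = [f"C:{i}" for i in range(k + 1)]
        for tid in ids:
            ont.add_term(Term(id=tid, label=tid))
        ont.ensure_relation("is_conjugate_base_of")
        for i in range(k):
            ont.add_axiom(
                subclass_of(
                    Named(ids[i + 1]),
                    Existential("is_conjugate_base_of", Named(ids[i])),
                )
            )
        gcis = generate_gcis(find_conjugate_pairs(ont))
        for rel in PSEUDOCODE_RELATIONS:
            probes = [
                equivalent_classes(
                    Named("P:first"), Existential(rel, Named(ids[0]))
                ),
                equivalent_classes(
                    Named("P:last"), Existential(rel, Named(ids[k]))
                ),
            ]
            res = classify_axioms(
                list(ont.axioms) + gcis + probes,
                {},
                set(ids) | {"P:first", "P:last"},
            )
            assert res.entails("P:first", "P:last")
            assert res.entails("P:last", "P:first")


class TestImportSubset:
    def test_carboxylic_acid_subset_pulls_conjugates(self, bundle):
        overlay = build_biochebi(bundle.mini_chebi)
        subset = import_subset(overlay, {"FIX:carboxylic_acid"})
        assert {
            "FIX:tricarboxylic_acid",
            "FIX:nta_acid",
            "FIX:nta",  # conjugate partner of a descendant
            "FIX:citric_acid",
            "FIX:citrate1",
            "FIX:citrate2",
            "FIX:citrate3",
            "CHEBI:30772",
            "FIX:chemical_entity",  # ancestor keeping the hierarchy rooted
        } <= set(subset.terms)
        assert "FIX:g6p" not in subset.terms
        # the GCIs over included chemicals come along
        assert any(ax.provenance == "gci" for ax in subset.axioms)

    def test_empty_used_set_gives_empty_subset(self, bundle):
        subset = import_subset(bundle.mini_chebi, set())
        assert subset.terms == {} and subset.axioms == []

    def test_idempotent_fixed_point(self, bundle):
        overlay = build_biochebi(bundle.mini_chebi)
        s1 = import_subset(overlay, {"FIX:carboxylic_acid"})
        s2 = import_subset(s1, {"FIX:carboxylic_acid"})
        assert s1 == s2

    def test_unknown_used_id_raises(self, bundle):
        with pytest.raises(ResolutionError):
            import_subset(bundle.mini_chebi, {"FIX:nonexistent"})
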