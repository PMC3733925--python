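"""EL normalization, classification, and agreement with the naive oracle."""

import random

import pytest

from gochem.fixtures import worked_example, random_ontology
from gochem.model import (
    TOP,
    Existential,
    Intersection,
    Named,
    equivalent_classes,
    subclass_of,
)
from gochem.pipeline import classify_pipeline
from gochem.reasoner import (
    classify,
    classify_axioms,
    naive_oracle,
    normalize,
)


class TestNormalize:
    def test_nf1_axiom_passes_through(self):
        ax = subclass_of(Named("T:a"), Named("T:b"))
        assert normalize([ax]) == {("nf1", "T:a", "T:b")}

    def test_gci_equivalence_decomposes_via_fresh_intermediates(self):
        ax = equivalent_classes(
            Existential("has_input", Named("C:x")),
            Existential("has_input", Named("C:y")),
        )
        norm = normalize([ax])
        nf3 = {n for n in norm if n[0] == "nf3"}
        nf4 = {n for n in norm if n[0] == "nf4"}
        assert len(norm) == 4 and len(nf3) == 2 and len(nf4) == 2
        # each direction routes through its own fresh intermediate:
        # ∃r.x ⊑ F ⊑ ∃r.y  and  ∃r.y ⊑ F' ⊑ ∃r.x
        for (_, rel, filler, fresh) in nf4:
            assert rel == "has_input" and filler in {"C:x", "C:y"}
            other = "C:y" if filler == "C:x" else "C:x"
            assert ("nf3", fresh, "has_input", other) in nf3

    def test_bridge_axiom_shape_decomposition(self):
        ax = equivalent_classes(
            Named("T:t"),
            Intersection(
                (Named("T:g"), Existential("r", Named("C:c")))
            ),
        )
        norm = normalize([ax])
        assert ("nf1", "T:t", "T:g") in norm
        assert ("nf3", "T:t", "r", "C:c") in norm
        # reverse direction: ∃r.C ⊑ F, then G ⊓ F ⊑ T
        nf4 = [n for n in norm if n[0] == "nf4"]
        nf2 = [n for n in norm if n[0] == "nf2"]
        assert len(nf4) == 1 and len(nf2) == 1
        (_, _, _, fresh) = nf4[0]
        assert set(nf2[0][1:3]) == {"T:g", fresh}
        assert nf2[0][3] == "T:t"

    def test_deterministic_across_runs(self):
        axioms = [
            equivalent_classes(
                Existential("r", Named("C:a")),
                Intersection((Named("C:b"), Existential("s", Named("C:c")))),
            )
        ]
        assert normalize(axioms) == normalize(list(axioms))


class TestClassify:
    def test_empty_axioms_reflexive_and_top_only(self):
        res = classify(set(), classes={"T:a"})
        assert res.S["T:a"] == {"T:a", TOP}
        assert res.subsumers("T:a") == {"T:a"}

    def test_entailment_flip_needs_the_gci_overlay(self, bundle, bridge, gcis):
        sub, sup = bundle.expected["flip"]
        without = classify_pipeline(
            bundle.mini_go, bundle.mini_chebi, gcis=[],
            extra_axioms=bridge.axioms,
        )
        with_gcis = classify_pipeline(
            bundle.mini_go, bundle.mini_chebi, gcis=gcis,
            extra_axioms=bridge.axioms,
        )
        assert not without.entails(sub, sup)
        assert with_gcis.entails(sub, sup)

    def test_reflexive_entailment(self, bundle, bridge, gcis):
        res = classify_pipeline(
            bundle.mini_go, bundle.mini_chebi, gcis=gcis,
            extra_axioms=bridge.axioms,
        )
        assert res.entails("FIX:go_nta_mp", "FIX:go_nta_mp")

    def test_genus_scaffold_subsumption(self, bundle, bridge):
        # biosynthesis is a kind of metabolism in the scaffold, so a defined
        # biosynthetic term is entailed under the metabolic genus
        res = classify_pipeline(
            bundle.mini_go, bundle.mini_chebi, extra_axioms=bridge.axioms
        )
        assert res.entails("FIX:go_xanthine_bp", "GO:0008152")

    def test_g6p_is_not_a_glucose_in_the_reference(self, bundle):
        res = classify_axioms(
            bundle.mini_chebi.axioms,
            bundle.mini_chebi.relation_parent_map(),
            set(bundle.mini_chebi.terms),
        )
        assert not res.entails("FIX:g6p", "FIX:glucose")
        assert res.entails("FIX:g6p", "FIX:hexose_phosphate")


class TestDirectSuperclasses:
    def test_chain_gives_immediate_parent_only(self):
        axioms = [
            subclass_of(Named("T:a"), Named("T:b")),
            subclass_of(Named("T:b"), Named("T:c")),
        ]
        res = classify_axioms(axioms)
        assert res.direct_superclasses("T:a") == {"T:b"}
        assert res.direct_superclasses("T:b") == {"T:c"}

    def test_equivalent_class_reported_as_equivalent_not_parent(self):
        axioms = [
            subclass_of(Named("T:a"), Named("T:b")),
            subclass_of(Named("T:b"), Named("T:a")),
            subclass_of(Named("T:b"), Named("T:c")),
        ]
        res = classify_axioms(axioms)
        assert res.equivalents("T:a") == {"T:b"}
        assert res.direct_superclasses("T:a") == {"T:c"}

    def test_generated_term_placement_is_most_specific(self, bundle, bridge, gcis):
        res = classify_pipeline(
            bundle.mini_go, bundle.mini_chebi, gcis=gcis,
            extra_axioms=bridge.axioms,
        )
        direct = {
            d
            for d in res.direct_superclasses("FIX:go_xanthine_bp")
            if d in bundle.mini_go.terms
        }
        assert direct == {"FIX:go_purine_bp"}


def _random_instance(seed):
    n = 5 + (seed % 36)  # up to 40 classes
    n_rel = 1 + seed % 3  # up to 3 relations
    density = 0.1 + 0.8 * ((seed * 37) % 10) / 10  # density swept
    return random_ontology(
        n,
        n_rel,
        density,
        seed=seed,
        gci_axioms=(seed % 2 == 0),
        conjugate_chain=seed % 4,
    )


class TestOracleAgreement:
    @pytest.mark.parametrize("block", range(20))
    def test_classify_equals_naive_oracle(self, block):
        """Worklist saturation and full-pass re-saturation agree on the
        user-class subsumption set, across 200 seeded random ontologies."""
        for seed in range(block * 10, block * 10 + 10):
            ont = _random_instance(seed)
            rel = ont.relation_parent_map()
            classes = set(ont.terms)
            res = classify_axioms(ont.axioms, rel, classes)
            oracle = naive_oracle(ont.axioms, rel, classes)
            assert res.subsumption_pairs() == oracle, f"seed {seed}"

    def test_agreement_on_the_worked_example(self, bundle, bridge, gcis):
        from gochem.pipeline import merged_relation_parents, recapitulation_basis

        axioms = recapitulation_basis(
            bundle.mini_go, bundle.mini_chebi, gcis, bridge.axioms
        )
        rel = merged_relation_parents(bundle.mini_go, bundle.mini_chebi)
        classes = set(bundle.mini_go.terms) | set(bundle.mini_chebi.terms)
        res = classify_axioms(axioms, rel, classes)
        assert res.subsumption_pairs() == naive_oracle(axioms, rel, classes)


class TestProperties:
    @pytest.mark.parametrize("block", range(10))
    def test_monotonicity_under_axiom_subsets(self, block):
        """Removing axioms never adds subsumers (100 seeded cases)."""
        for seed in range(block * 10, block * 10 + 10):
            ont = random_ontology(
                5 + seed % 20, 2, 0.4, seed=seed, gci_axioms=True
            )
            rng = random.Random(seed)
            axioms = list(ont.axioms)
            subset = rng.sample(axioms, rng.randrange(len(axioms) + 1))
            rel = ont.relation_parent_map()
            classes = set(ont.terms)
            small = classify_axioms(subset, rel, classes)
            big = classify_axioms(axioms, rel, classes)
            for c in classes:
                assert small.subsumers(c) <= big.subsumers(c)

    @pytest.mark.parametrize("block", range(10))
    def test_idempotence_after_asserting_entailments(self, block):
        """Feeding every entailed atomic subsumption back in changes
        nothing (100 seeded cases)."""
        for seed in range(block * 10, block * 10 + 10):
            ont = random_ontology(
                5 + seed % 15, 2, 0.4, seed=1000 + seed, gci_axioms=True
            )
            rel = ont.relation_parent_map()
            classes = set(ont.terms)
            r1 = classify_axioms(ont.axioms, rel, classes)
            extra = [
                subclass_of(Named(a), Named(b))
                for a, b in sorted(r1.subsumption_pairs())
                if a != b
            ]
            r2 = classify_axioms(list(ont.axioms) + extra, rel, classes)
            assert r1.subsumption_pairs() == r2.subsumption_pairs()

    def test_relation_hierarchy_propagates_links(self):
        # a link via a sub-relation satisfies an existential over the super
        axioms = [
            subclass_of(Named("T:a"), Existential("r_sub", Named("T:b"))),
            subclass_of(Existential("r_super", Named("T:b")), Named("T:c")),
        ]
        res = classify_axioms(axioms, {"r_sub": ("r_super",)})
        assert res.entails("T:a", "T:c")
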