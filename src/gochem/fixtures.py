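"""Worked-example mini-ontologies and seeded random ontologies.

``worked_example`` builds a matched pair of miniature ontologies — a
process/function ontology and a chemical ontology — that embed every worked
example the package's operations are specified against: the
glucose-6-phosphate transport/transporter-activity asymmetry, the
nitrilotriacetate/nitrilotriacetic-acid conjugate conflation, the citric
acid deprotonation chain, pyridine vs pyridines (EXACT vs CLASS readings),
butyric/butanoic acid synonym matching, xanthine placement, and the
aldoxime/oxime coverage gap. The bundle also carries an ``expected`` ledger
of known-answer facts that the test suite re-derives from the bundle.

``random_ontology`` produces seeded, reproducible ontologies with an
acyclic is_a core plus EL-shaped extra axioms, used by the round-trip and
reasoner property suites.

Identifiers: canonical GO/ChEBI ids are reused for the famous classes;
everything invented for the fixture is minted under the FIX: prefix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    Existential,
    Intersection,
    Named,
    Ontology,
    RelationType,
    Synonym,
    Term,
    equivalent_classes,
    subclass_of,
)

__all__ = ["FixtureBundle", "worked_example", "move_xanthine", "random_ontology"]

# widely-known canonical identifiers used by the fixture
CARBOHYDRATE = "CHEBI:16646"
BUTYRIC_ACID = "CHEBI:30772"
PYRIDINE = "CHEBI:16227"
PYRIDINES = "CHEBI:26421"
CARBOHYDRATE_BINDING = "GO:0030246"
BINDING = "GO:0005488"
METABOLIC = "GO:0008152"
BIOSYNTHETIC = "GO:0009058"
CATABOLIC = "GO:0009056"
TRANSPORT = "GO:0006810"
TRANSPORTER_ACTIVITY = "GO:0005215"
RESPONSE_TO_STIMULUS = "GO:0050896"
SECRETION = "GO:0046903"
CHEMICAL_HOMEOSTASIS = "GO:0048878"
PHENOL_MP = "GO:0018958"


@dataclass
class FixtureBundle:
    mini_go: Ontology
    mini_chebi: Ontology
    expected: dict = field(default_factory=dict)


def _term(ont, tid, label, parents=(), synonyms=(), relationships=()):
    ont.add_term(Term(id=tid, label=label, synonyms=tuple(synonyms)))
    for p in parents:
        if isinstance(p, tuple):
            target, provenance = p
        else:
            target, provenance = p, "asserted"
        ont.add_axiom(subclass_of(Named(tid), Named(target), provenance))
    for rel, target in relationships:
        ont.ensure_relation(rel)
        ont.add_axiom(subclass_of(Named(tid), Existential(rel, Named(target))))


def _mini_chebi() -> Ontology:
    ont = Ontology("mini-chebi")
    ont.header = [("format-version", "1.2"), ("ontology", "mini-chebi")]
    for rel in ("is_conjugate_acid_of", "is_conjugate_base_of"):
        ont.add_relation(RelationType(rel, label=rel, declared=True))
    root = "FIX:chemical_entity"
    _term(ont, root, "chemical entity")
    _term(ont, CARBOHYDRATE, "carbohydrate", [root])
    _term(ont, "FIX:hexose", "hexose", [CARBOHYDRATE])
    _term(ont, "FIX:glucose", "glucose", ["FIX:hexose"])
    _term(ont, "FIX:hexose_phosphate", "hexose phosphate", [CARBOHYDRATE])
    # deliberately under hexose phosphate ONLY: the structural view
    _term(ont, "FIX:g6p", "glucose-6-phosphate", ["FIX:hexose_phosphate"])
    _term(ont, "FIX:carboxylic_acid", "carboxylic acid", [root])
    _term(
        ont,
        "FIX:tricarboxylic_acid",
        "tricarboxylic acid",
        ["FIX:carboxylic_acid"],
    )
    _term(
        ont,
        "FIX:nta_acid",
        "nitrilotriacetic acid",
        ["FIX:tricarboxylic_acid"],
    )
    _term(ont, "FIX:organic_anion", "organic anion", [root])
    _term(
        ont,
        "FIX:nta",
        "nitrilotriacetate",
        ["FIX:organic_anion"],
        relationships=[("is_conjugate_base_of", "FIX:nta_acid")],
    )
    _term(
        ont,
        "FIX:citric_acid",
        "citric acid",
        ["FIX:tricarboxylic_acid"],
        relationships=[("is_conjugate_acid_of", "FIX:citrate1")],
    )
    # citric acid <-> citrate(1-) is asserted in both directions: the pair
    # must still be counted once
    _term(
        ont,
        "FIX:citrate1",
        "citrate(1-)",
        ["FIX:organic_anion"],
        relationships=[("is_conjugate_base_of", "FIX:citric_acid")],
    )
    _term(
        ont,
        "FIX:citrate2",
        "citrate(2-)",
        ["FIX:organic_anion"],
        relationships=[("is_conjugate_base_of", "FIX:citrate1")],
    )
    _term(
        ont,
        "FIX:citrate3",
        "citrate(3-)",
        ["FIX:organic_anion"],
        relationships=[("is_conjugate_base_of", "FIX:citrate2")],
    )
    _term(ont, "FIX:heterocyclic_compound", "heterocyclic compound", [root])
    _term(ont, PYRIDINE, "pyridine", ["FIX:heterocyclic_compound"])
    _term(ont, PYRIDINES, "pyridines", ["FIX:heterocyclic_compound"])
    _term(ont, "FIX:phenols", "phenols", [root])
    _term(ont, "FIX:phenol", "phenol", ["FIX:phenols"])
    _term(ont, "FIX:benzene", "benzene", [root])
    _term(
        ont,
        BUTYRIC_ACID,
        "butyric acid",
        ["FIX:carboxylic_acid"],
        synonyms=[Synonym("butanoic acid", "EXACT")],
    )
    _term(ont, "FIX:purine", "purine", ["FIX:heterocyclic_compound"])
    _term(
        ont,
        "FIX:xanthine",
        "xanthine",
        ["FIX:purine"],
        synonyms=[Synonym("2,6-dihydroxypurine", "EXACT")],
    )
    # present in the chemical ontology but referenced by no process term
    _term(ont, "FIX:oxime", "oxime", [root])
    return ont


def _mini_go() -> Ontology:
    ont = Ontology("mini-go")
    ont.header = [("format-version", "1.2"), ("ontology", "mini-go")]
    # genus scaffold
    _term(ont, METABOLIC, "metabolic process")
    _term(ont, BIOSYNTHETIC, "biosynthetic process", [METABOLIC])
    _term(ont, CATABOLIC, "catabolic process", [METABOLIC])
    _term(ont, TRANSPORT, "transport")
    _term(ont, TRANSPORTER_ACTIVITY, "transporter activity")
    _term(ont, BINDING, "binding")
    _term(ont, RESPONSE_TO_STIMULUS, "response to stimulus")
    _term(ont, SECRETION, "secretion", [TRANSPORT])
    _term(ont, CHEMICAL_HOMEOSTASIS, "chemical homeostasis")
    # transport view of glucose-6-phosphate: under glucose AND hexose
    # phosphate (the first link is the cross-family inconsistency)
    _term(ont, "FIX:go_glucose_transport", "glucose transport", [TRANSPORT])
    _term(
        ont,
        "FIX:go_hexp_transport",
        "hexose phosphate transport",
        [TRANSPORT],
    )
    _term(
        ont,
        "FIX:go_g6p_transport",
        "glucose-6-phosphate transport",
        ["FIX:go_glucose_transport", "FIX:go_hexp_transport"],
    )
    # transporter-activity view: under hexose phosphate only
    _term(
        ont,
        "FIX:go_glucose_ta",
        "glucose transporter activity",
        [TRANSPORTER_ACTIVITY],
    )
    _term(
        ont,
        "FIX:go_hexp_ta",
        "hexose phosphate transporter activity",
        [TRANSPORTER_ACTIVITY],
    )
    _term(
        ont,
        "FIX:go_g6p_ta",
        "glucose-6-phosphate transporter activity",
        ["FIX:go_hexp_ta"],
    )
    # acid/conjugate-base conflation chain
    _term(
        ont,
        "FIX:go_carbox_mp",
        "carboxylic acid metabolic process",
        [METABOLIC],
    )
    _term(
        ont,
        "FIX:go_tricarbox_mp",
        "tricarboxylic acid metabolic process",
        ["FIX:go_carbox_mp"],
    )
    _term(
        ont,
        "FIX:go_nta_mp",
        "nitrilotriacetate metabolic process",
        ["FIX:go_tricarbox_mp"],
    )
    _term(
        ont,
        "FIX:go_butanoic_mp",
        "butanoic acid metabolic process",
        ["FIX:go_carbox_mp"],
    )
    # chemical present in the process ontology but absent from the
    # chemical ontology
    _term(ont, "FIX:go_aldoxime_mp", "aldoxime metabolic process", [METABOLIC])
    # CLASS vs EXACT readings
    _term(ont, PHENOL_MP, "phenol metabolic process", [METABOLIC])
    _term(ont, "FIX:go_benzene_mp", "benzene metabolic process", [METABOLIC])
    _term(ont, "FIX:go_pyridine_mp", "pyridine metabolic process", [METABOLIC])
    _term(ont, CARBOHYDRATE_BINDING, "carbohydrate binding", [BINDING])
    # biosynthesis chain hosting the xanthine placement example; the
    # xanthine link is reasoner-derived, hence inferred-tagged
    _term(
        ont,
        "FIX:go_het_bp",
        "heterocyclic compound biosynthetic process",
        [BIOSYNTHETIC],
    )
    _term(
        ont,
        "FIX:go_purine_bp",
        "purine biosynthetic process",
        ["FIX:go_het_bp"],
    )
    _term(
        ont,
        "FIX:go_xanthine_bp",
        "xanthine biosynthetic process",
        [("FIX:go_purine_bp", "inferred")],
    )
    return ont


def worked_example() -> FixtureBundle:
    """Deterministic worked-example bundle; see module docstring."""
    mini_go = _mini_go()
    mini_chebi = _mini_chebi()
    expected = {
        "conjugate_pairs": 4,
        "defined_terms": 17,
        "family_counts": {
            "transport": 3,
            "transporter_activity": 3,
            "metabolic": 7,
            "binding": 1,
            "biosynthetic": 3,
            "catabolic": 0,
            "secretion": 0,
            "homeostasis": 0,
            "response_to": 0,
        },
        "unmatched": [("FIX:go_aldoxime_mp", "aldoxime")],
        "conflict": {
            "child": "FIX:g6p",
            "parent": "FIX:glucose",
            "supporting": {"transport"},
            "absent": {"transporter_activity"},
        },
        "edge_not_in_reference": [("FIX:g6p", "FIX:glucose")],
        "reference_edge_missing": [
            (PYRIDINE, "FIX:heterocyclic_compound"),
            ("FIX:hexose_phosphate", CARBOHYDRATE),
        ],
        "flip": ("FIX:go_nta_mp", "FIX:go_carbox_mp"),
        "sync_move": {
            "remove": ("FIX:go_xanthine_bp", "FIX:go_purine_bp"),
            "add": ("FIX:go_xanthine_bp", "FIX:go_het_bp"),
        },
    }
    return FixtureBundle(mini_go, mini_chebi, expected)


def move_xanthine(mini_chebi: Ontology) -> Ontology:
    """A new chemical-ontology release in which xanthine moves from purine
    to a direct child of heterocyclic compound."""
    out = mini_chebi.copy()
    out.remove_axiom(subclass_of(Named("FIX:xanthine"), Named("FIX:purine")))
    out.add_axiom(
        subclass_of(Named("FIX:xanthine"), Named("FIX:heterocyclic_compound"))
    )
    return out


def random_ontology(
    n_classes: int,
    n_relations: int = 2,
    density: float = 0.2,
    seed: int = 0,
    conjugate_chain: int = 0,
    gci_axioms: bool = False,
) -> Ontology:
    """Seeded random ontology with an acyclic is_a core.

    Extra axioms are EL-normal-form shaped (conjunction subsumptions,
    existential successors, existential subsumers); an optional conjugate
    chain links the first ``conjugate_chain + 1`` classes for GCI tests.
    Always passes :meth:`Ontology.validate`.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = random.Random(seed)
    ont = Ontology(f"random-{seed}")
    ont.header = [("format-version", "1.2"), ("ontology", f"random-{seed}")]
    ids = [f"RND:c{i:04d}" for i in range(n_classes)]
    for i, tid in enumerate(ids):
        ont.add_term(Term(id=tid, label=f"random class {i}"))
    rels = [f"r{i}" for i in range(n_relations)]
    for r in rels:
        ont.add_relation(RelationType(r, label=r, declared=True))
    # acyclic is_a core: edges only from higher to lower index
    for j in range(1, n_classes):
        for i in range(j):
            if rng.random() < density / 2:
                ont.add_axiom(subclass_of(Named(ids[j]), Named(ids[i])))
    if n_classes >= 2:
        n_extra = max(1, int(density * n_classes))
        for _ in range(n_extra):  # conjunction subsumptions
            a, b = rng.sample(ids, 2)
            c = rng.choice(ids)
            if c not in (a, b):
                ont.add_axiom(
                    subclass_of(
                        Intersection((Named(a), Named(b))), Named(c)
                    )
                )
        if rels:
            for _ in range(n_extra):  # existential successors
                a, b = rng.choice(ids), rng.choice(ids)
                ont.add_axiom(
                    subclass_of(
                        Named(a), Existential(rng.choice(rels), Named(b))
                    )
                )
            for _ in range(n_extra):  # existential subsumers
                a, b = rng.choice(ids), rng.choice(ids)
                ont.add_axiom(
                    subclass_of(
                        Existential(rng.choice(rels), Named(a)), Named(b)
                    )
                )
            if gci_axioms:
                for _ in range(max(1, n_extra // 2)):
                    a, b = rng.sample(ids, 2)
                    r = rng.choice(rels)
                    ont.add_axiom(
                        equivalent_classes(
                            Existential(r, Named(a)),
                            Existential(r, Named(b)),
                            provenance="gci",
                        )
                    )
    if conjugate_chain:
        ont.add_relation(
            RelationType("is_conjugate_base_of", declared=True)
        )
        for i in range(min(conjugate_chain, n_classes - 1)):
            ont.add_axiom(
                subclass_of(
                    Named(ids[i + 1]),
                    Existential("is_conjugate_base_of", Named(ids[i])),
                )
            )
    return ont
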