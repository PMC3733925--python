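"""Conjugate acid/base bridging axioms (the BioChEBI overlay).

Biologists routinely conflate an oxoacid with its deprotonated forms: at
physiological pH "citrate" and "citric acid" name the same pool of
interconverting species. The chemical ontology keeps them as distinct
classes linked by ``is_conjugate_acid_of`` / ``is_conjugate_base_of``. To
let process definitions use either member of a pair interchangeably, every
asserted conjugate pair {X, Y} contributes four general concept inclusions

    ∃has_participant.X ≡ ∃has_participant.Y
    ∃transports.X      ≡ ∃transports.Y
    ∃has_input.X       ≡ ∃has_input.Y
    ∃has_output.X      ≡ ∃has_output.Y

so any process over the acid is equivalent to the same process over its
conjugate base — without minting grouping classes. Chains of pairs
(citric acid / citrate(1-)/(2-)/(3-)) become equivalent transitively under
reasoning; only asserted links generate pairs.

Tautomers are linked by ``is_tautomer_of`` in the chemical ontology but are
deliberately NOT equated here, and stereoisomers/salts are untouched: those
distinctions map 1:1 between the ontologies and cause no conflation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, ResolutionError
from .model import (
    Axiom,
    Existential,
    Named,
    Ontology,
    RelationType,
    equivalent_classes,
)

__all__ = [
    "CONJUGATE_RELATIONS",
    "PSEUDOCODE_RELATIONS",
    "EXTENDED_GCI_RELATIONS",
    "KNOWN_RELATIONS",
    "ConjugatePair",
    "find_conjugate_pairs",
    "generate_gcis",
    "build_biochebi",
    "import_subset",
]

CONJUGATE_RELATIONS = ("is_conjugate_acid_of", "is_conjugate_base_of")

#: Default GCI relations, exactly the four of the generation procedure.
PSEUDOCODE_RELATIONS = (
    "has_participant",
    "transports",
    "has_input",
    "has_output",
)

#: Optional wider list: 'transports' is a sub-relation of the full transport
#: relation used by the template rules; callers that want GCIs over both can
#: pass this list instead of the default.
EXTENDED_GCI_RELATIONS = PSEUDOCODE_RELATIONS + (
    "transports_or_maintains_localization_of",
)

#: Relation catalog for configuration validation.
KNOWN_RELATIONS = frozenset(
    {
        "is_a",
        "has_participant",
        "has_input",
        "has_output",
        "transports",
        "transports_or_maintains_localization_of",
        "regulates_levels_of",
        "is_conjugate_acid_of",
        "is_conjugate_base_of",
        "has_functional_parent",
        "has_role",
        "is_tautomer_of",
    }
)


@dataclass(frozen=True)
class ConjugatePair:
    """Unordered conjugate pair with the directions actually asserted."""

    pair: frozenset[str]
    evidence: frozenset[str]  # subset of {acid_of_asserted, base_of_asserted}

    def __post_init__(self):
        if len(self.pair) != 2:
            raise ValueError("conjugate pair must have two distinct members")
        if not self.evidence:
            raise ValueError("conjugate pair needs at least one evidence flag")

    def sorted_members(self) -> tuple[str, str]:
        a, b = sorted(self.pair)
        return a, b


def find_conjugate_pairs(chem: Ontology) -> set[ConjugatePair]:
    """Scan asserted SubClassOf(Named, ∃is_conjugate_*_of.Named) axioms.

    A pair asserted in both directions is counted once, with both evidence
    flags set.
    """
    evidence: dict[frozenset[str], set[str]] = {}
    for ax in chem.axioms:
        if ax.kind != "subclass_of" or not isinstance(ax.a, Named):
            continue
        if not (
            isinstance(ax.b, Existential) and isinstance(ax.b.filler, Named)
        ):
            continue
        if ax.b.relation not in CONJUGATE_RELATIONS:
            continue
        key = frozenset({ax.a.id, ax.b.filler.id})
        if len(key) != 2:
            continue
        flag = (
            "acid_of_asserted"
            if ax.b.relation == "is_conjugate_acid_of"
            else "base_of_asserted"
        )
        evidence.setdefault(key, set()).add(flag)
    return {
        ConjugatePair(pair, frozenset(flags))
        for pair, flags in evidence.items()
    }


def generate_gcis(
    pairs: set[ConjugatePair],
    relations: tuple[str, ...] | list[str] = PSEUDOCODE_RELATIONS,
) -> list[Axiom]:
    """One EquivalentClasses(∃R.a, ∃R.b) per (pair, relation).

    Axiom count is exactly ``len(pairs) * len(relations)``; operand order is
    canonicalized, so the output is invariant under pair orientation.
    """
    for r in relations:
        if r not in KNOWN_RELATIONS:
            raise ConfigurationError(f"unknown GCI relation id: {r}")
    out = []
    for pair in sorted(pairs, key=lambda p: p.sorted_members()):
        a, b = pair.sorted_members()
        for r in relations:
            out.append(
                equivalent_classes(
                    Existential(r, Named(a)),
                    Existential(r, Named(b)),
                    provenance="gci",
                )
            )
    return out


def build_biochebi(
    chem: Ontology,
    relations: tuple[str, ...] | list[str] = PSEUDOCODE_RELATIONS,
) -> Ontology:
    """Return the chemical ontology with the GCI overlay attached.

    The original axioms are untouched; stripping ``provenance == "gci"``
    axioms recovers the input exactly. The 'transports' sub-relation is
    registered under the full transport relation so both spellings reason
    together.
    """
    out = chem.copy()
    for r in relations:
        out.ensure_relation(r)
    if "transports" in out.relations:
        t = out.relations["transports"]
        if "transports_or_maintains_localization_of" not in t.parents:
            t.parents = t.parents + (
                "transports_or_maintains_localization_of",
            )
        out.ensure_relation("transports_or_maintains_localization_of")
    for ax in generate_gcis(find_conjugate_pairs(chem), relations):
        out.add_axiom(ax)
    return out


def strip_gcis(ont: Ontology) -> Ontology:
    """Remove the GCI overlay (inverse of :func:`build_biochebi` modulo
    relation registration)."""
    out = ont.copy()
    for ax in [a for a in out.axioms if a.provenance == "gci"]:
        out.remove_axiom(ax)
    return out


def _conjugate_partners(chem: Ontology) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = {}
    for pair in find_conjugate_pairs(chem):
        a, b = pair.sorted_members()
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return partners


def import_subset(chem: Ontology, used: set[str]) -> Ontology:
    """The release-import subset: the used chemical classes together with
    their descendants, the ancestors needed to keep the hierarchy connected,
    and conjugate partners of everything included (so the GCIs stay
    meaningful inside the subset)."""
    for tid in used:
        if tid not in chem.terms:
            raise ResolutionError(f"unknown used id: {tid}")
    partners = _conjugate_partners(chem)
    # phase 1: used terms, their descendants, and conjugate partners of
    # anything included (closing over partners-of-partners)
    core: set[str] = set()
    frontier = set(used)
    while frontier:
        nxt: set[str] = set()
        for tid in frontier:
            if tid in core or tid not in chem.terms:
                continue
            core.add(tid)
            nxt |= chem.descendants(tid) - core
            nxt |= partners.get(tid, set()) - core
        frontier = nxt
    # phase 2: is_a ancestors keep the subset hierarchy connected, but do
    # not trigger further descendant expansion
    keep = set(core)
    for tid in core:
        keep |= {a for a in chem.ancestors(tid) if a in chem.terms}
    sub = Ontology(chem.id)
    sub.header = list(chem.header)
    for rel in chem.relations.values():
        sub.add_relation(
            RelationType(
                rel.id,
                rel.label,
                rel.parents,
                rel.is_transitive,
                rel.declared,
                rel.extra_tags,
            )
        )
    for tid in sorted(keep):
        sub.add_term(chem.terms[tid])
    from .model import named_ids

    for ax in chem.axioms:
        refs = named_ids(ax.a) | named_ids(ax.b)
        if refs <= keep:
            sub.add_axiom(ax)
    return sub
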