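"""Assembly of classification inputs across ontologies.

The recapitulation principle: when the reasoner is asked whether the
asserted placement of a chemically-defined term is justified, the asserted
is_a links of defined terms must NOT be part of the input — otherwise every
placement trivially recapitulates itself. The basis therefore consists of
the chemical ontology, the logical definitions, the GCI overlay, the
relation hierarchies, and only those process-ontology links whose subclass
carries no logical definition (the hand-built genus scaffold).
"""

from __future__ import annotations

from .model import Axiom, Named, Ontology
from .reasoner import ClassificationResult, classify_axioms

__all__ = [
    "defined_terms",
    "recapitulation_basis",
    "classify_pipeline",
    "merged_relation_parents",
]


def defined_terms(go: Ontology, extra_axioms=()) -> set[str]:
    """Terms carrying a genus-differentia equivalence axiom."""
    out = set()
    for ax in list(go.axioms) + list(extra_axioms):
        if ax.kind != "equivalent_classes":
            continue
        for x in (ax.a, ax.b):
            if isinstance(x, Named):
                out.add(x.id)
    return out


def merged_relation_parents(*onts: Ontology) -> dict[str, tuple[str, ...]]:
    parents: dict[str, set[str]] = {}
    for ont in onts:
        for rel in ont.relations.values():
            parents.setdefault(rel.id, set()).update(rel.parents)
    return {r: tuple(sorted(ps)) for r, ps in parents.items()}


def recapitulation_basis(
    go: Ontology,
    chem: Ontology,
    gcis=(),
    extra_axioms=(),
    defined: set[str] | None = None,
) -> list[Axiom]:
    """Axiom set for placement reasoning (see module docstring)."""
    if defined is None:
        defined = defined_terms(go, extra_axioms)
    axioms: list[Axiom] = []
    for ax in go.axioms:
        if (
            ax.kind == "subclass_of"
            and isinstance(ax.a, Named)
            and isinstance(ax.b, Named)
            and ax.a.id in defined
        ):
            continue  # placement under test; must be re-derived
        axioms.append(ax)
    axioms.extend(chem.axioms)
    axioms.extend(extra_axioms)
    axioms.extend(gcis)
    return axioms


def classify_pipeline(
    go: Ontology,
    chem: Ontology,
    gcis=(),
    extra_axioms=(),
    defined: set[str] | None = None,
) -> ClassificationResult:
    """Classify the combined process + chemical + GCI axiom set."""
    axioms = recapitulation_basis(go, chem, gcis, extra_axioms, defined)
    classes = set(go.terms) | set(chem.terms) | go.external | chem.external
    return classify_axioms(
        axioms, merged_relation_parents(go, chem), classes
    )
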