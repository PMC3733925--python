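"""Shared ontology data model.

A single in-memory :class:`Ontology` container holds terms, relation types and
axioms for every graph the package manipulates: the process/function ontology
(GO-like), the chemical ontology (ChEBI-like), the genus-differentia bridge,
the GOCHE registry of provisional chemicals, and the GCI overlay.

Class expressions are the EL fragment: named classes, existential
restrictions, and intersections. Axioms are SubClassOf or EquivalentClasses
over canonicalized expressions, each tagged with a provenance drawn from
``{asserted, bridge, gci, inferred, temporary}`` so that overlays remain
separable from curated content.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace

import networkx as nx

from .errors import ResolutionError

__all__ = [
    "TOP",
    "PROVENANCES",
    "SYNONYM_SCOPES",
    "Synonym",
    "Term",
    "RelationType",
    "Named",
    "Existential",
    "Intersection",
    "ClassExpression",
    "Axiom",
    "Violation",
    "Ontology",
    "check_curie",
    "canon",
    "render",
    "named_ids",
    "subclass_of",
    "equivalent_classes",
]

#: Identifier used for the universal class (top) in classification results.
TOP = "owl:Thing"

PROVENANCES = frozenset({"asserted", "bridge", "gci", "inferred", "temporary"})
SYNONYM_SCOPES = frozenset({"EXACT", "BROAD", "NARROW", "RELATED"})

_CURIE_RE = re.compile(r"^[^:\s]+:[^:\s]+$")


def check_curie(curie: str) -> str:
    """Validate a PREFIX:LOCAL identifier; return it unchanged.

    Exactly one colon; both prefix and local part non-empty.
    """
    if not isinstance(curie, str) or not _CURIE_RE.match(curie):
        raise ValueError(f"not a valid CURIE (PREFIX:LOCAL): {curie!r}")
    return curie


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "RELATED"


@dataclass
class Term:
    """A named ontology class.

    ``extra_tags`` preserves unsupported OBO tag lines verbatim so that files
    survive a parse/write cycle without silent loss.
    """

    id: str
    label: str = ""
    synonyms: tuple[Synonym, ...] = ()
    namespace: str = ""
    textual_definition: str = ""
    def_trailer: str = ""  # raw remainder of the OBO def line (xref list)
    xrefs: tuple[str, ...] = ()
    obsolete: bool = False
    extra_tags: tuple[tuple[str, str], ...] = ()


@dataclass
class RelationType:
    """A relation (OBO Typedef). ``is_a`` is built in and has no parents."""

    id: str
    label: str = ""
    parents: tuple[str, ...] = ()
    is_transitive: bool = False
    declared: bool = False  # True when it came from / should emit a [Typedef]
    extra_tags: tuple[tuple[str, str], ...] = ()


# --------------------------------------------------------------------------
# Class expressions

@dataclass(frozen=True)
class Named:
    id: str


@dataclass(frozen=True)
class Existential:
    relation: str
    filler: "ClassExpression"


@dataclass(frozen=True)
class Intersection:
    parts: tuple["ClassExpression", ...]


ClassExpression = Named | Existential | Intersection


def render(expr: ClassExpression) -> str:
    """Deterministic textual rendering; the canonical order key."""
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Existential):
        inner = render(expr.filler)
        if not isinstance(expr.filler, Named):
            inner = f"({inner})"
        return f"{expr.relation} some {inner}"
    if isinstance(expr, Intersection):
        rendered = []
        for p in expr.parts:
            r = render(p)
            if isinstance(p, Intersection):
                r = f"({r})"
            rendered.append(r)
        return " and ".join(rendered)
    raise TypeError(f"not a class expression: {expr!r}")


def canon(expr: ClassExpression) -> ClassExpression:
    """Canonical form: intersections flattened, deduplicated and sorted by
    their rendering. Idempotent."""
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, Existential):
        return Existential(expr.relation, canon(expr.filler))
    if isinstance(expr, Intersection):
        flat: list[ClassExpression] = []
        for p in expr.parts:
            cp = canon(p)
            if isinstance(cp, Intersection):
                flat.extend(cp.parts)
            else:
                flat.append(cp)
        uniq = sorted(set(flat), key=render)
        if len(uniq) == 1:
            return uniq[0]
        return Intersection(tuple(uniq))
    raise TypeError(f"not a class expression: {expr!r}")


def named_ids(expr: ClassExpression) -> set[str]:
    """All named-class identifiers mentioned in an expression."""
    if isinstance(expr, Named):
        return {expr.id}
    if isinstance(expr, Existential):
        return named_ids(expr.filler)
    return set().union(*(named_ids(p) for p in expr.parts))


# --------------------------------------------------------------------------
# Axioms

@dataclass(frozen=True)
class Axiom:
    """SubClassOf(a, b) or EquivalentClasses(a, b) with provenance.

    Operands are canonicalized on construction; EquivalentClasses operands
    are order-normalized so equality is symmetric. A SubClassOf axiom whose
    operands coincide is rejected.
    """

    kind: str  # "subclass_of" | "equivalent_classes"
    a: ClassExpression
    b: ClassExpression
    provenance: str = "asserted"

    def __post_init__(self):
        if self.kind not in ("subclass_of", "equivalent_classes"):
            raise ValueError(f"unknown axiom kind {self.kind!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        a, b = canon(self.a), canon(self.b)
        if self.kind == "equivalent_classes" and render(b) < render(a):
            a, b = b, a
        if self.kind == "subclass_of" and a == b:
            raise ValueError(f"trivial SubClassOf rejected: {render(a)}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.kind, render(self.a), render(self.b), self.provenance)


def subclass_of(a, b, provenance: str = "asserted") -> Axiom:
    return Axiom("subclass_of", a, b, provenance)


def equivalent_classes(a, b, provenance: str = "asserted") -> Axiom:
    return Axiom("equivalent_classes", a, b, provenance)


@dataclass(frozen=True)
class Violation:
    rule: str
    entity: str
    message: str


# --------------------------------------------------------------------------
# Ontology container

class Ontology:
    """Terms + relation types + axioms with provenance tags.

    The built-in ``is_a`` relation is always registered. Identifiers that
    axioms reference but that carry no :class:`Term` must be registered via
    :meth:`add_external` (cross-ontology references, e.g. chemical fillers in
    a bridge file).
    """

    def __init__(self, id: str = "ontology"):
        self.id = id
        self.terms: dict[str, Term] = {}
        self.relations: dict[str, RelationType] = {
            "is_a": RelationType("is_a", label="is_a")
        }
        self.axioms: list[Axiom] = []
        self.external: set[str] = set()
        self.header: list[tuple[str, str]] = []
        self.warnings: list[str] = []
        self.unsupported_tags: list[tuple[str, str, str]] = []
        self.unsupported_stanzas: list[str] = []
        self._axiom_set: set[Axiom] = set()

    # -- construction -----------------------------------------------------
    def add_term(self, term: Term) -> Term:
        check_curie(term.id)
        self.terms[term.id] = term
        return term

    def add_relation(self, rel: RelationType) -> RelationType:
        if rel.id == "is_a" and rel.parents:
            raise ValueError("is_a is built-in and has no parents")
        self.relations[rel.id] = rel
        return rel

    def ensure_relation(self, rel_id: str) -> RelationType:
        if rel_id not in self.relations:
            self.relations[rel_id] = RelationType(rel_id)
        return self.relations[rel_id]

    def add_axiom(self, ax: Axiom) -> Axiom:
        """Insert an axiom; exact duplicates are ignored."""
        if ax not in self._axiom_set:
            self.axioms.append(ax)
            self._axiom_set.add(ax)
        return ax

    def remove_axiom(self, ax: Axiom) -> None:
        if ax in self._axiom_set:
            self._axiom_set.discard(ax)
            self.axioms.remove(ax)

    def has_axiom(self, ax: Axiom) -> bool:
        return ax in self._axiom_set

    def add_external(self, term_id: str) -> None:
        check_curie(term_id)
        self.external.add(term_id)

    def resolves(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.external

    # -- queries ----------------------------------------------------------
    def label_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for t in self.terms.values():
            if not t.obsolete:
                idx.setdefault(t.label, []).append(t.id)
        return idx

    def term_by_label(self, label: str) -> Term | None:
        for t in self.terms.values():
            if t.label == label and not t.obsolete:
                return t
        return None

    def parents(self, term_id: str, relation: str = "is_a") -> list[str]:
        """Direct parents of a named class along one relation.

        ``is_a`` walks SubClassOf(Named, Named); any other relation walks
        SubClassOf(Named, relation some Named).
        """
        out = set()
        for ax in self.axioms:
            if ax.kind != "subclass_of" or ax.a != Named(term_id):
                continue
            if relation == "is_a":
                if isinstance(ax.b, Named):
                    out.add(ax.b.id)
            elif (
                isinstance(ax.b, Existential)
                and ax.b.relation == relation
                and isinstance(ax.b.filler, Named)
            ):
                out.add(ax.b.filler.id)
        return sorted(out)

    def children(self, term_id: str, relation: str = "is_a") -> list[str]:
        out = set()
        for ax in self.axioms:
            if ax.kind != "subclass_of" or not isinstance(ax.a, Named):
                continue
            if relation == "is_a":
                if ax.b == Named(term_id):
                    out.add(ax.a.id)
            elif ax.b == Existential(relation, Named(term_id)):
                out.add(ax.a.id)
        return sorted(out)

    def ancestors(self, start: str, relation: str = "is_a") -> set[str]:
        """Reflexive-transitive closure over asserted edges of one relation."""
        if not self.resolves(start):
            raise ResolutionError(f"unknown term id: {start}")
        if relation not in self.relations:
            raise ResolutionError(f"unknown relation id: {relation}")
        seen = {start}
        stack = [start]
        while stack:
            for p in self.parents(stack.pop(), relation):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def descendants(self, start: str, relation: str = "is_a") -> set[str]:
        if not self.resolves(start):
            raise ResolutionError(f"unknown term id: {start}")
        if relation not in self.relations:
            raise ResolutionError(f"unknown relation id: {relation}")
        seen = {start}
        stack = [start]
        while stack:
            for c in self.children(stack.pop(), relation):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    def is_a_graph(self) -> nx.DiGraph:
        """Directed graph of asserted SubClassOf edges between named classes
        (child -> parent)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for ax in self.axioms:
            if (
                ax.kind == "subclass_of"
                and isinstance(ax.a, Named)
                and isinstance(ax.b, Named)
            ):
                g.add_edge(ax.a.id, ax.b.id)
        return g

    # -- validation --------------------------------------------------------
    def validate(self) -> list[Violation]:
        """Structural invariant check; violations are data, not exceptions."""
        out: list[Violation] = []
        for tid, term in self.terms.items():
            if not _CURIE_RE.match(tid):
                out.append(Violation("curie", tid, "malformed identifier"))
            for syn in term.synonyms:
                if not syn.text:
                    out.append(Violation("synonym", tid, "empty synonym text"))
                if syn.scope not in SYNONYM_SCOPES:
                    out.append(
                        Violation("synonym", tid, f"bad scope {syn.scope!r}")
                    )
        by_label: dict[str, list[str]] = {}
        for t in self.terms.values():
            if not t.obsolete and t.label:
                by_label.setdefault(t.label, []).append(t.id)
        for label, ids in sorted(by_label.items()):
            if len(ids) > 1:
                out.append(
                    Violation(
                        "duplicate label",
                        ",".join(sorted(ids)),
                        f"label {label!r} used by {len(ids)} non-obsolete terms",
                    )
                )
        obsolete = {t.id for t in self.terms.values() if t.obsolete}
        for ax in self.axioms:
            if isinstance(ax.a, Named) and ax.a.id in obsolete:
                out.append(
                    Violation(
                        "obsolete axiom",
                        ax.a.id,
                        "obsolete term carries an outgoing axiom",
                    )
                )
            for ref in named_ids(ax.a) | named_ids(ax.b):
                if not self.resolves(ref):
                    out.append(
                        Violation(
                            "dangling reference",
                            ref,
                            "axiom references an unknown, unregistered id",
                        )
                    )
        g = self.is_a_graph()
        for scc in nx.strongly_connected_components(g):
            if len(scc) > 1:
                out.append(
                    Violation(
                        "cycle",
                        ",".join(sorted(scc)),
                        "is_a cycle among named classes",
                    )
                )
        rg = nx.DiGraph()
        rg.add_nodes_from(self.relations)
        for rel in self.relations.values():
            for p in rel.parents:
                rg.add_edge(rel.id, p)
        for scc in nx.strongly_connected_components(rg):
            if len(scc) > 1:
                out.append(
                    Violation(
                        "relation cycle",
                        ",".join(sorted(scc)),
                        "relation hierarchy is cyclic",
                    )
                )
        if self.relations["is_a"].parents:
            out.append(Violation("is_a", "is_a", "is_a must not have parents"))
        return out

    # -- misc ---------------------------------------------------------------
    def copy(self) -> "Ontology":
        return copy.deepcopy(self)

    def axioms_sorted(self) -> list[Axiom]:
        return sorted(self.axioms, key=Axiom.sort_key)

    def relation_parent_map(self) -> dict[str, tuple[str, ...]]:
        return {r.id: tuple(r.parents) for r in self.relations.values()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.id == other.id
            and self.terms == other.terms
            and self.relations == other.relations
            and self.axioms_sorted() == other.axioms_sorted()
            and self.external == other.external
            and self.header == other.header
        )

    def __repr__(self) -> str:
        return (
            f"<Ontology {self.id!r}: {len(self.terms)} terms, "
            f"{len(self.axioms)} axioms>"
        )


def relabel(term: Term, new_label: str) -> Term:
    """Return a copy of a term with a new primary label."""
    return replace(term, label=new_label)
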