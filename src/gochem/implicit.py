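"""The implicit chemical ontology embedded in a process/function ontology.

Every asserted is_a link between two chemically-defined terms of the same
family ("glucose-6-phosphate transport" is_a "glucose transport") implicitly
asserts a relationship between the chemicals themselves (glucose-6-phosphate
is_a glucose). Collecting these edges over all term families yields a
stand-alone chemical ontology whose union can be audited:

* internally — a chemical pair asserted in one family but absent from
  another family that mentions both chemicals is a cross-family
  inconsistency;
* externally — an implicit edge the reference chemical ontology does not
  entail (directly, or after identifying conjugate acid/base partners) is a
  candidate error in one of the two ontologies.

Family tags come from the genus of each logical definition, not from label
suffixes, so audits survive term renames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .biochebi import find_conjugate_pairs
from .defgen import LogicalDefinition, TemplateRule, default_rules
from .model import Axiom, Named, Ontology
from .reasoner import ClassificationResult

__all__ = [
    "ImplicitChemicalOntology",
    "CrossFamilyConflict",
    "ReferenceDiscrepancy",
    "extract_implicit",
    "find_cross_family_conflicts",
    "diff_against_reference",
]


@dataclass
class ImplicitChemicalOntology:
    """Chemicals plus is_a edges, each edge tagged with the family that
    implied it; ``mentions`` records which chemicals each family defines."""

    chemicals: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    mentions: dict[str, set[str]] = field(default_factory=dict)

    def families(self) -> set[str]:
        return set(self.mentions)

    def family_edges(self, family: str) -> set[tuple[str, str]]:
        return {(c, p) for c, p, f in self.edges if f == family}

    def union_edges(self) -> set[tuple[str, str]]:
        return {(c, p) for c, p, _ in self.edges}

    def to_tsv(self) -> str:
        lines = ["child\tparent\tfamily"]
        for c, p, f in sorted(self.edges):
            lines.append(f"{c}\t{p}\t{f}")
        return "\n".join(lines) + "\n"

    def to_dot(self, labels: dict[str, str] | None = None) -> str:
        labels = labels or {}

        def node(x):
            return json.dumps(labels.get(x, x))

        lines = ["digraph implicit_chemical_ontology {", "  rankdir=BT;"]
        for c, p, f in sorted(self.edges):
            lines.append(f"  {node(c)} -> {node(p)} [label={json.dumps(f)}];")
        lines.append("}")
        return "\n".join(lines) + "\n"


def extract_implicit(
    go: Ontology,
    defs: list[LogicalDefinition],
    rules: list[TemplateRule] | None = None,
) -> ImplicitChemicalOntology:
    """Project the process-ontology is_a graph onto chemicals.

    For each is_a edge between two defined terms sharing a genus family and
    relation, emit (chemical(child), chemical(parent), family). Output is a
    set union, independent of term iteration order.
    """
    if rules is None:
        rules = default_rules()
    family_of_genus = {r.genus: r.id for r in rules}
    info: dict[str, tuple[str, str, str]] = {}  # term -> (family, rel, chem)
    impl = ImplicitChemicalOntology()
    for d in defs:
        family = family_of_genus.get(d.genus)
        if family is None or len(d.differentia) != 1:
            continue
        rel, chem = d.differentia[0]
        info[d.defined] = (family, rel, chem)
        impl.chemicals.add(chem)
        impl.mentions.setdefault(family, set()).add(chem)
    for ax in go.axioms:
        if (
            ax.kind != "subclass_of"
            or not isinstance(ax.a, Named)
            or not isinstance(ax.b, Named)
        ):
            continue
        sub, sup = info.get(ax.a.id), info.get(ax.b.id)
        if sub is None or sup is None:
            continue
        if sub[0] == sup[0] and sub[1] == sup[1] and sub[2] != sup[2]:
            impl.edges.add((sub[2], sup[2], sub[0]))
    return impl


@dataclass(frozen=True)
class CrossFamilyConflict:
    child: str
    parent: str
    supporting: frozenset[str]
    absent: frozenset[str]

    def __post_init__(self):
        if self.supporting & self.absent:
            raise ValueError("supporting and absent families must not overlap")
        if not self.supporting or not self.absent:
            raise ValueError("both family sets must be non-empty")


def _closure(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    parents: dict[str, set[str]] = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    out = set()
    for start in parents:
        seen: set[str] = set()
        stack = [start]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        out |= {(start, p) for p in seen}
    return out


def find_cross_family_conflicts(
    impl: ImplicitChemicalOntology,
) -> list[CrossFamilyConflict]:
    """A pair (child, parent) asserted in some family conflicts with every
    family that mentions both chemicals yet does not entail the edge even
    after transitive closure within that family. Silence in a family that
    never mentions one of the chemicals is vacuous, not conflicting."""
    closures = {f: _closure(impl.family_edges(f)) for f in impl.families()}
    out = []
    for c, p in sorted(impl.union_edges()):
        supporting = frozenset(
            f for f in impl.families() if (c, p) in closures[f]
        )
        absent = frozenset(
            f
            for f in impl.families()
            if c in impl.mentions[f]
            and p in impl.mentions[f]
            and (c, p) not in closures[f]
        )
        if supporting and absent:
            out.append(CrossFamilyConflict(c, p, supporting, absent))
    return out


@dataclass(frozen=True)
class ReferenceDiscrepancy:
    kind: str  # edge_not_in_reference | chemical_not_in_reference |
    #            reference_edge_missing_in_implicit
    payload: tuple[str, ...]
    entailment_checked: bool = False


def _conjugate_classes(chem: Ontology) -> dict[str, set[str]]:
    """Union-find over asserted conjugate pairs: each chemical mapped to the
    set of species it is identified with for entailment purposes."""
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for pair in find_conjugate_pairs(chem):
        a, b = pair.sorted_members()
        union(a, b)
    groups: dict[str, set[str]] = {}
    for x in list(parent):
        groups.setdefault(find(x), set()).add(x)
    return {x: groups[find(x)] for x in parent}


def diff_against_reference(
    impl: ImplicitChemicalOntology,
    chem: Ontology,
    gcis: list[Axiom],
    res: ClassificationResult,
) -> list[ReferenceDiscrepancy]:
    """Audit the implicit ontology against the reference chemical ontology.

    An implicit edge passes when the reference (as classified, GCIs
    included) entails child ⊑ parent, directly or after identifying each
    chemical with its conjugate acid/base partners; chemicals absent from
    the reference and direct reference edges with no implicit counterpart
    are also reported.
    """
    conj = _conjugate_classes(chem)
    out: list[ReferenceDiscrepancy] = []
    for c in sorted(impl.chemicals):
        if c not in chem.terms:
            out.append(ReferenceDiscrepancy("chemical_not_in_reference", (c,)))
    for c, p in sorted(impl.union_edges()):
        if c not in chem.terms or p not in chem.terms:
            continue
        subs = conj.get(c, {c}) | {c}
        sups = conj.get(p, {p}) | {p}
        entailed = any(
            res.entails(s, t) for s in subs for t in sups
        )
        if not entailed:
            out.append(
                ReferenceDiscrepancy(
                    "edge_not_in_reference", (c, p), entailment_checked=True
                )
            )
    union = _closure(impl.union_edges()) | impl.union_edges()
    for ax in chem.axioms:
        if (
            ax.kind == "subclass_of"
            and isinstance(ax.a, Named)
            and isinstance(ax.b, Named)
            and ax.a.id in impl.chemicals
            and ax.b.id in impl.chemicals
            and (ax.a.id, ax.b.id) not in union
        ):
            out.append(
                ReferenceDiscrepancy(
                    "reference_edge_missing_in_implicit",
                    (ax.a.id, ax.b.id),
                )
            )
    return sorted(out, key=lambda d: (d.kind, d.payload))


def discrepancies_tsv(discrepancies: list[ReferenceDiscrepancy]) -> str:
    lines = ["kind\tpayload\tentailment_checked"]
    for d in discrepancies:
        lines.append(
            f"{d.kind}\t{','.join(d.payload)}\t{str(d.entailment_checked).lower()}"
        )
    return "\n".join(lines) + "\n"


def conflicts_tsv(conflicts: list[CrossFamilyConflict]) -> str:
    lines = ["child\tparent\tsupporting_families\tabsent_families"]
    for c in conflicts:
        lines.append(
            f"{c.child}\t{c.parent}\t"
            f"{','.join(sorted(c.supporting))}\t{','.join(sorted(c.absent))}"
        )
    return "\n".join(lines) + "\n"
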