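"""Synchronizing the asserted hierarchy with reasoner output.

After a chemical-ontology release moves a chemical class, the placement of
chemically-defined process terms can change. The sync protocol keeps the
editors file current without ever touching curated content:

* new entailed direct superclasses not already asserted (directly or
  transitively) are added as SubClassOf axioms tagged ``inferred``;
* previously added inferred-tagged links that are no longer valid
  inferences are removed;
* curator-asserted links the reasoner cannot recapitulate are reported as
  warnings for discussion — never auto-deleted.

A report of additions and removals is produced for every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import StaleInputError, SyncConflictError
from .model import Axiom, Named, Ontology, subclass_of
from .pipeline import defined_terms
from .reasoner import ClassificationResult

__all__ = ["SyncReport", "compute_sync", "apply_sync"]


@dataclass
class SyncReport:
    to_add: list[Axiom] = field(default_factory=list)
    to_remove: list[Axiom] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unchanged: int = 0

    def is_empty(self) -> bool:
        return not self.to_add and not self.to_remove

    def to_tsv(self) -> str:
        lines = ["action\tsubclass\tsuperclass"]
        for ax in self.to_add:
            lines.append(f"add\t{ax.a.id}\t{ax.b.id}")
        for ax in self.to_remove:
            lines.append(f"remove\t{ax.a.id}\t{ax.b.id}")
        for w in self.warnings:
            lines.append(f"warning\t{w}\t")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "to_add": [[ax.a.id, ax.b.id] for ax in self.to_add],
                "to_remove": [[ax.a.id, ax.b.id] for ax in self.to_remove],
                "warnings": self.warnings,
                "unchanged": self.unchanged,
            },
            indent=2,
        )


def compute_sync(
    go: Ontology,
    res: ClassificationResult,
    defined: set[str] | None = None,
) -> SyncReport:
    """Diff the asserted hierarchy against the classification.

    ``res`` must cover the combined input (process ontology + definitions +
    chemical ontology + GCIs) computed on the recapitulation basis; a
    result that does not cover the defined terms is stale.
    """
    if defined is None:
        defined = defined_terms(go)
    defined = {t for t in defined if t in go.terms}
    for t in sorted(defined):
        if not res.covers(t):
            raise StaleInputError(
                f"classification does not cover defined term {t}"
            )
    report = SyncReport()

    inferred_tagged = [
        ax
        for ax in go.axioms
        if ax.kind == "subclass_of"
        and ax.provenance == "inferred"
        and isinstance(ax.a, Named)
        and isinstance(ax.b, Named)
    ]
    removed_edges = set()
    for ax in inferred_tagged:
        if not res.entails(ax.a.id, ax.b.id):
            report.to_remove.append(ax)
            removed_edges.add((ax.a.id, ax.b.id))

    def asserted_ancestors(t: str) -> set[str]:
        # reflexive-transitive closure over asserted is_a edges, ignoring
        # the links this very report retracts
        seen = {t}
        stack = [t]
        while stack:
            cur = stack.pop()
            for p in go.parents(cur, "is_a"):
                if (cur, p) in removed_edges or p in seen:
                    continue
                seen.add(p)
                stack.append(p)
        return seen

    for t in sorted(defined):
        covered = asserted_ancestors(t)
        direct = {
            d for d in res.direct_superclasses(t) if d in go.terms
        }
        for d in sorted(direct):
            if d in covered:
                report.unchanged += 1
            else:
                report.to_add.append(subclass_of(Named(t), Named(d), "inferred"))

    for ax in go.axioms:
        if (
            ax.kind == "subclass_of"
            and ax.provenance == "asserted"
            and isinstance(ax.a, Named)
            and isinstance(ax.b, Named)
            and ax.a.id in defined
            and not res.entails(ax.a.id, ax.b.id)
        ):
            report.warnings.append(
                f"asserted link not recapitulated by reasoning: "
                f"{ax.a.id} is_a {ax.b.id}"
            )
    return report


def apply_sync(go: Ontology, report: SyncReport) -> Ontology:
    """Apply a report to the ontology state it was computed against.

    Asserted-provenance axioms are never touched; a report that no longer
    matches the ontology (axioms vanished or appeared since) is rejected.
    """
    for ax in report.to_remove:
        if ax.provenance != "inferred":
            raise SyncConflictError(
                "refusing to remove a non-inferred axiom: "
                f"{ax.a.id} is_a {ax.b.id}"
            )
        if not go.has_axiom(ax):
            raise SyncConflictError(
                f"stale report: {ax.a.id} is_a {ax.b.id} is not asserted"
            )
    for ax in report.to_add:
        if go.has_axiom(ax):
            raise SyncConflictError(
                f"stale report: {ax.a.id} is_a {ax.b.id} already asserted"
            )
    out = go.copy()
    for ax in report.to_remove:
        out.remove_axiom(ax)
    for ax in report.to_add:
        out.add_axiom(ax)
    return out
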