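"""EL completion-rule reasoner.

Axioms (including general concept inclusions between complex expressions)
are first normalized to the four EL normal forms

    NF1  A ⊑ B        NF2  A1 ⊓ A2 ⊑ B
    NF3  A ⊑ ∃r.B     NF4  ∃r.A ⊑ B

over named classes, introducing fresh names for complex subexpressions (a
deterministic function of the expression's canonical rendering). The
subsumption closure is then computed by worklist saturation of the standard
completion rules, with a simple relation hierarchy (r ⊑ s) folded in. The
fragment is exactly what the bridging axioms need: no role composition, no
disjointness, no nominals — so unsatisfiability cannot arise and is not
detected; modeling conflicts surface through the audit module instead.

``naive_oracle`` is an independently-implemented full-pass re-saturation
used as a test oracle for ``classify``.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field

from .model import (
    TOP,
    Axiom,
    Existential,
    Intersection,
    Named,
    canon,
    render,
)

__all__ = [
    "FRESH_PREFIX",
    "normalize",
    "classify",
    "classify_axioms",
    "naive_oracle",
    "ClassificationResult",
]

FRESH_PREFIX = "F_"


def is_fresh(class_id: str) -> bool:
    return class_id.startswith(FRESH_PREFIX)


def _fresh_name(expr) -> str:
    digest = hashlib.sha1(render(expr).encode("utf-8")).hexdigest()[:12]
    return f"{FRESH_PREFIX}{digest}"


# --------------------------------------------------------------------------
# Normalization

def normalize(axioms) -> set[tuple]:
    """Normalize to NF1-NF4 tuples:

    ``("nf1", A, B)`` | ``("nf2", A1, A2, B)`` | ``("nf3", A, r, B)`` |
    ``("nf4", r, A, B)``.

    EquivalentClasses axioms are split into two SubClassOf; complex
    operands are decomposed with fresh names keyed by the expression they
    stand for, so normalization is deterministic across runs.
    """
    out: set[tuple] = set()
    queue: deque[tuple] = deque()
    for ax in axioms:
        a, b = canon(ax.a), canon(ax.b)
        if ax.kind == "equivalent_classes":
            if a != b:
                queue.append((a, b))
                queue.append((b, a))
        else:
            queue.append((a, b))
    while queue:
        c, d = queue.popleft()
        if c == d:
            continue
        c_named, d_named = isinstance(c, Named), isinstance(d, Named)
        if c_named and d_named:
            out.add(("nf1", c.id, d.id))
        elif c_named and isinstance(d, Existential):
            if isinstance(d.filler, Named):
                out.add(("nf3", c.id, d.relation, d.filler.id))
            else:
                a = Named(_fresh_name(d.filler))
                queue.append((c, Existential(d.relation, a)))
                queue.append((a, d.filler))
        elif c_named and isinstance(d, Intersection):
            for part in d.parts:
                queue.append((c, part))
        elif isinstance(c, Existential) and d_named:
            if isinstance(c.filler, Named):
                out.add(("nf4", c.relation, c.filler.id, d.id))
            else:
                a = Named(_fresh_name(c.filler))
                queue.append((c.filler, a))
                queue.append((Existential(c.relation, a), d))
        elif isinstance(c, Intersection) and d_named:
            named_parts = []
            for part in c.parts:
                if isinstance(part, Named):
                    named_parts.append(part.id)
                else:
                    a = Named(_fresh_name(part))
                    queue.append((part, a))
                    named_parts.append(a.id)
            named_parts.sort()
            if len(named_parts) == 1:
                out.add(("nf1", named_parts[0], d.id))
            else:
                # left-fold longer conjunctions through fresh names
                acc = named_parts[0]
                for nxt in named_parts[1:-1]:
                    inter = canon(Intersection((Named(acc), Named(nxt))))
                    f = _fresh_name(inter)
                    out.add(("nf2", acc, nxt, f))
                    acc = f
                out.add(("nf2", acc, named_parts[-1], d.id))
        else:
            # complex on both sides: route through a fresh intermediate
            f = Named(_fresh_name(c))
            queue.append((c, f))
            queue.append((f, d))
    return out


def _classes_of(norm) -> set[str]:
    classes = set()
    for nf in norm:
        if nf[0] == "nf1":
            classes.update((nf[1], nf[2]))
        elif nf[0] == "nf2":
            classes.update((nf[1], nf[2], nf[3]))
        elif nf[0] == "nf3":
            classes.update((nf[1], nf[3]))
        elif nf[0] == "nf4":
            classes.update((nf[2], nf[3]))
    return classes


def _super_relations(relation_parents) -> dict[str, set[str]]:
    """Reflexive-transitive closure of the relation hierarchy."""
    parents = {r: set(ps) for r, ps in (relation_parents or {}).items()}
    rels = set(parents)
    for ps in parents.values():
        rels |= ps
    closure = {}
    for r in rels:
        seen = {r}
        stack = [r]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        closure[r] = seen
    return closure


@dataclass
class ClassificationResult:
    """Saturated subsumption relation S plus relation links R."""

    S: dict[str, set[str]]
    R: dict[str, set[tuple[str, str]]]
    fixpoint: bool = True

    def covers(self, class_id: str) -> bool:
        return class_id in self.S

    def subsumers(self, class_id: str) -> set[str]:
        """Named (user-facing) subsumers, fresh names and top excluded."""
        s = self.S.get(class_id, {class_id, TOP})
        return {x for x in s if not is_fresh(x) and x != TOP}

    def entails(self, sub: str, super_: str) -> bool:
        if sub == super_:
            return True
        return super_ in self.S.get(sub, ())

    def equivalents(self, class_id: str) -> set[str]:
        return {
            x
            for x in self.subsumers(class_id)
            if x != class_id and class_id in self.S.get(x, ())
        }

    def direct_superclasses(self, class_id: str) -> set[str]:
        """Most specific strict subsumers; members of one equivalence group
        are reported together."""
        equiv = self.equivalents(class_id) | {class_id}
        cands = self.subsumers(class_id) - equiv
        out = set()
        for s in cands:
            direct = True
            for t in cands:
                if t == s or s in self.S.get(t, ()) and t in self.S.get(s, ()):
                    continue
                if s in self.S.get(t, ()):  # class_id < t < s
                    direct = False
                    break
            if direct:
                out.add(s)
        return out

    def subsumption_pairs(self) -> set[tuple[str, str]]:
        """All (sub, super) pairs over user classes, including reflexive."""
        out = set()
        for c, supers in self.S.items():
            if is_fresh(c):
                continue
            for s in supers:
                if not is_fresh(s) and s != TOP:
                    out.add((c, s))
        return out

    def dump_tsv(self) -> str:
        lines = ["class\tdirect_superclasses"]
        for c in sorted(self.S):
            if is_fresh(c):
                continue
            supers = ",".join(sorted(self.direct_superclasses(c)))
            lines.append(f"{c}\t{supers}")
        return "\n".join(lines) + "\n"


def classify(
    norm: set[tuple],
    relation_parents: dict | None = None,
    classes: set[str] | None = None,
) -> ClassificationResult:
    """Least fixpoint of the EL completion rules by worklist saturation."""
    super_rels = _super_relations(relation_parents)
    all_classes = _classes_of(norm) | (classes or set())

    nf1: dict[str, list[str]] = {}
    nf2: dict[str, list[tuple[str, str]]] = {}  # conjunct -> (other, B)
    nf3: dict[str, list[tuple[str, str]]] = {}
    nf4: dict[tuple[str, str], list[str]] = {}
    for nf in norm:
        if nf[0] == "nf1":
            nf1.setdefault(nf[1], []).append(nf[2])
        elif nf[0] == "nf2":
            _, a1, a2, b = nf
            nf2.setdefault(a1, []).append((a2, b))
            if a1 != a2:
                nf2.setdefault(a2, []).append((a1, b))
        elif nf[0] == "nf3":
            _, a, r, b = nf
            nf3.setdefault(a, []).append((r, b))
        elif nf[0] == "nf4":
            _, r, a, b = nf
            nf4.setdefault((r, a), []).append(b)

    S: dict[str, set[str]] = {c: {c, TOP} for c in all_classes}
    R: dict[str, set[tuple[str, str]]] = {}
    preds: dict[str, set[tuple[str, str]]] = {}  # D -> {(C, r)}
    work: deque[tuple] = deque()
    for c in sorted(all_classes):
        work.append(("S", c, c))
        work.append(("S", c, TOP))

    def push_s(c, x):
        if x not in S[c]:
            S[c].add(x)
            work.append(("S", c, x))

    def push_r(r, c, d):
        for s in super_rels.get(r, {r}):
            pairs = R.setdefault(s, set())
            if (c, d) not in pairs:
                pairs.add((c, d))
                work.append(("R", s, c, d))

    # seed reflexive/top entries processed below
    while work:
        item = work.popleft()
        if item[0] == "S":
            _, c, x = item
            for b in nf1.get(x, ()):  # rule: X ⊑ B
                push_s(c, b)
            for other, b in nf2.get(x, ()):  # rule: X ⊓ other ⊑ B
                if other in S[c]:
                    push_s(c, b)
            for r, b in nf3.get(x, ()):  # rule: X ⊑ ∃r.B
                push_r(r, c, b)
            for p, r in preds.get(c, set()):  # rule: ∃r.X ⊑ B upstream
                for b in nf4.get((r, x), ()):
                    push_s(p, b)
        else:
            _, r, c, d = item
            preds.setdefault(d, set()).add((c, r))
            if d not in S:
                S[d] = {d, TOP}
                work.append(("S", d, d))
                work.append(("S", d, TOP))
            for dprime in list(S[d]):  # rule: ∃r.D' ⊑ B
                for b in nf4.get((r, dprime), ()):
                    push_s(c, b)
    return ClassificationResult(S=S, R=R)


def classify_axioms(
    axioms,
    relation_parents: dict | None = None,
    classes: set[str] | None = None,
) -> ClassificationResult:
    """Normalize then classify a raw axiom set."""
    return classify(normalize(axioms), relation_parents, classes)


def naive_oracle(
    axioms,
    relation_parents: dict | None = None,
    classes: set[str] | None = None,
) -> set[tuple[str, str]]:
    """Unoptimized full-pass re-saturation; the reference for ``classify``.

    Recomputes every completion rule over every class each round until
    nothing changes, with none of the worklist indexing used by
    ``classify``. Returns the (sub, super) pairs over user classes.
    """
    norm = normalize(axioms)
    super_rels = _super_relations(relation_parents)
    all_classes = _classes_of(norm) | (classes or set())
    S = {c: {c, TOP} for c in all_classes}
    R: dict[str, set[tuple[str, str]]] = {}
    changed = True
    while changed:
        changed = False
        for nf in norm:
            if nf[0] == "nf1":
                _, a, b = nf
                for c in all_classes:
                    if a in S[c] and b not in S[c]:
                        S[c].add(b)
                        changed = True
            elif nf[0] == "nf2":
                _, a1, a2, b = nf
                for c in all_classes:
                    if a1 in S[c] and a2 in S[c] and b not in S[c]:
                        S[c].add(b)
                        changed = True
            elif nf[0] == "nf3":
                _, a, r, b = nf
                for c in all_classes:
                    if a in S[c]:
                        for s in super_rels.get(r, {r}):
                            if (c, b) not in R.setdefault(s, set()):
                                R[s].add((c, b))
                                changed = True
            elif nf[0] == "nf4":
                _, r, a, b = nf
                for (c, d) in list(R.get(r, ())):
                    if a in S.get(d, ()) and b not in S[c]:
                        S[c].add(b)
                        changed = True
        # relation hierarchy propagation for pairs added via other relations
        for r, pairs in list(R.items()):
            for s in super_rels.get(r, {r}):
                if s == r:
                    continue
                target = R.setdefault(s, set())
                missing = pairs - target
                if missing:
                    target |= missing
                    changed = True
    out = set()
    for c, supers in S.items():
        if is_fresh(c):
            continue
        for s in supers:
            if not is_fresh(s) and s != TOP:
                out.add((c, s))
    return out
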