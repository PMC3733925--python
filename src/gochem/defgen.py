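"""Genus-differentia logical definitions from chemical-referencing labels.

A process/function label such as "xanthine biosynthetic process" is parsed
against a priority-ordered template table into a chemical string plus a
rule; the rule supplies the genus class and relation for the equivalence
axiom

    <term> EquivalentTo: <genus> and <relation> some <chemical>

The module also implements the two curation operations built on top of the
templates: renaming CLASS-reading (plural chemical family) labels to
"X-containing compound ..." and TermGenie-style generation of new terms
with reasoner-computed placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, DuplicateTermError, MissingChemicalError
from .lexicon import (
    GocheRegistry,
    MatchResult,
    NameIndex,
    build_index,
    match_chemical,
    normalize_name,
)
from .model import (
    Axiom,
    Existential,
    Intersection,
    Named,
    Ontology,
    Synonym,
    Term,
    equivalent_classes,
)

__all__ = [
    "TemplateRule",
    "ParsedLabel",
    "LogicalDefinition",
    "NewTermRecord",
    "BridgeResult",
    "default_rules",
    "load_rules",
    "assemble_label",
    "parse_label",
    "make_logical_definition",
    "extract_logical_definitions",
    "bridge_ontologies",
    "containing_compound_rename",
    "generate_term",
]

_REGULATION_PREFIXES = (
    "regulation of ",
    "positive regulation of ",
    "negative regulation of ",
)


@dataclass(frozen=True)
class TemplateRule:
    id: str
    pattern: str  # contains exactly one {X}
    genus: str
    relation: str
    definition: str  # textual-definition template with {X}
    priority: int
    extension: bool = False

    def __post_init__(self):
        if self.pattern.count("{X}") != 1:
            raise ConfigurationError(
                f"rule {self.id}: pattern must contain exactly one {{X}}"
            )

    @property
    def head(self) -> str:
        return self.pattern.split("{X}")[0]

    @property
    def tail(self) -> str:
        return self.pattern.split("{X}")[1]


@dataclass(frozen=True)
class ParsedLabel:
    rule: TemplateRule
    chemical_string: str


@dataclass(frozen=True, order=True)
class LogicalDefinition:
    """One genus plus (relation, chemical filler) differentia."""

    defined: str
    genus: str
    differentia: tuple[tuple[str, str], ...]

    def to_axiom(self, provenance: str = "bridge") -> Axiom:
        parts = [Named(self.genus)]
        parts += [Existential(r, Named(f)) for r, f in self.differentia]
        return equivalent_classes(
            Named(self.defined), Intersection(tuple(parts)), provenance
        )


def load_rules(path: str | Path | None = None) -> list[TemplateRule]:
    """Load template rules from YAML; defaults to the shipped table."""
    if path is None:
        text = resources.files("gochem.data").joinpath("rules.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    rules = [
        TemplateRule(
            id=r["id"],
            pattern=r["pattern"],
            genus=r["genus"],
            relation=r["relation"],
            definition=r["definition"],
            priority=int(r["priority"]),
            extension=bool(r.get("extension", False)),
        )
        for r in data["rules"]
    ]
    return sorted(rules, key=lambda r: -r.priority)


def default_rules() -> list[TemplateRule]:
    """The shipped rule table, in decreasing priority order."""
    return load_rules()


def assemble_label(rule: TemplateRule, chemical_string: str) -> str:
    return rule.pattern.replace("{X}", chemical_string)


def parse_label(
    label: str, rules: list[TemplateRule] | None = None
) -> ParsedLabel | None:
    """First matching rule by priority wins; the chemical string is the
    maximal capture. Regulation-of labels are out of scope and return None."""
    if rules is None:
        rules = default_rules()
    if any(label.startswith(p) for p in _REGULATION_PREFIXES):
        return None
    for rule in rules:
        head, tail = rule.head, rule.tail
        if (
            label.startswith(head)
            and label.endswith(tail)
            and len(label) > len(head) + len(tail)
        ):
            x = label[len(head): len(label) - len(tail)]
            return ParsedLabel(rule, x)
    return None


def make_logical_definition(
    term: str, parsed: ParsedLabel, match: MatchResult
) -> tuple[LogicalDefinition, Axiom]:
    """Equivalence axiom for one parsed label. Temporary (GOCHE) fillers
    propagate their provisional status into the axiom provenance."""
    if match.matched is None:
        raise ValueError(f"cannot define {term}: no matched chemical")
    ld = LogicalDefinition(
        defined=term,
        genus=parsed.rule.genus,
        differentia=((parsed.rule.relation, match.matched),),
    )
    provenance = (
        "temporary"
        if match.match_kind == "temporary"
        or match.matched.startswith("GOCHE:")
        else "bridge"
    )
    return ld, ld.to_axiom(provenance)


def extract_logical_definitions(ont: Ontology) -> list[LogicalDefinition]:
    """Read genus-differentia definitions back out of equivalence axioms."""
    out = []
    for ax in ont.axioms:
        if ax.kind != "equivalent_classes":
            continue
        named = next((x for x in (ax.a, ax.b) if isinstance(x, Named)), None)
        inter = next(
            (x for x in (ax.a, ax.b) if isinstance(x, Intersection)), None
        )
        if named is None or inter is None:
            continue
        genus = [p for p in inter.parts if isinstance(p, Named)]
        diffs = [
            p
            for p in inter.parts
            if isinstance(p, Existential) and isinstance(p.filler, Named)
        ]
        if len(genus) != 1 or len(diffs) + 1 != len(inter.parts):
            continue
        out.append(
            LogicalDefinition(
                named.id,
                genus[0].id,
                tuple(sorted((d.relation, d.filler.id) for d in diffs)),
            )
        )
    return out


@dataclass
class BridgeResult:
    """Output of a full bridging pass over a process/function ontology."""

    axioms: list[Axiom] = field(default_factory=list)
    definitions: list[LogicalDefinition] = field(default_factory=list)
    unmatched: list[tuple[str, str]] = field(default_factory=list)
    ambiguous: list[tuple[str, str, tuple[str, ...]]] = field(
        default_factory=list
    )
    counts: dict[str, int] = field(default_factory=dict)

    def unmatched_tsv(self) -> str:
        lines = ["term\tchemical_string"]
        lines += [f"{t}\t{c}" for t, c in self.unmatched]
        return "\n".join(lines) + "\n"

    def ambiguous_tsv(self) -> str:
        lines = ["term\tchemical_string\tcandidates"]
        lines += [
            f"{t}\t{c}\t{'|'.join(cands)}" for t, c, cands in self.ambiguous
        ]
        return "\n".join(lines) + "\n"

    def counts_tsv(self) -> str:
        lines = ["family\tdefined_terms"]
        lines += [f"{fam}\t{n}" for fam, n in sorted(self.counts.items())]
        return "\n".join(lines) + "\n"


def bridge_ontologies(
    go: Ontology,
    chem: Ontology,
    rules: list[TemplateRule] | None = None,
    registry: GocheRegistry | None = None,
    index: NameIndex | None = None,
) -> BridgeResult:
    """Apply parse + match + define to every non-obsolete process term.

    When a :class:`GocheRegistry` is supplied, unmatched chemical strings are
    minted as provisional terms and still reported in the unmatched ledger
    (they are the submission queue for the chemical ontology). Output order
    is deterministic (terms processed in id order).
    """
    if rules is None:
        rules = default_rules()
    if index is None:
        index = build_index(chem)
    genus_ids = {r.genus for r in rules}
    result = BridgeResult(counts={r.id: 0 for r in rules})
    for tid in sorted(go.terms):
        term = go.terms[tid]
        if term.obsolete or tid in genus_ids:
            continue
        parsed = parse_label(term.label, rules)
        if parsed is None:
            continue
        effective_index = index
        if registry is not None:
            effective_index = index.merged_with(registry.index())
        match = match_chemical(parsed.chemical_string, effective_index)
        if match.ambiguous_with:
            result.ambiguous.append(
                (tid, parsed.chemical_string, match.ambiguous_with)
            )
            continue
        if match.matched is None:
            result.unmatched.append((tid, parsed.chemical_string))
            if registry is None:
                continue
            minted = registry.mint(parsed.chemical_string, tid)
            match = MatchResult(
                parsed.chemical_string, minted.id, "temporary"
            )
        ld, ax = make_logical_definition(tid, parsed, match)
        result.definitions.append(ld)
        result.axioms.append(ax)
        result.counts[parsed.rule.id] += 1
    return result


def containing_compound_rename(term_label: str, chemical_label: str) -> str:
    """Rename a CLASS-reading label to the "X-containing compound" form.

    ``chemical_label`` is the label of the matched chemical family. When it
    is the plural of the chemical token in the term label (the CLASS
    reading), the token is replaced by "<token>-containing compound"; EXACT
    readings pass through unchanged.
    """
    parsed = parse_label(term_label)
    if parsed is None:
        raise ValueError(f"label has no chemical token: {term_label!r}")
    token = parsed.chemical_string
    norm_token = normalize_name(token)
    norm_family = normalize_name(chemical_label)
    if norm_family == norm_token:
        return term_label  # EXACT reading: one specific molecule
    if norm_family not in (norm_token + "s", norm_token + "es"):
        raise ValueError(
            f"chemical family {chemical_label!r} is not the plural of "
            f"{token!r}; flag for manual review"
        )
    return assemble_label(parsed.rule, f"{token}-containing compound")


@dataclass
class NewTermRecord:
    term: Term
    logical_definition: LogicalDefinition
    axiom: Axiom
    placement: tuple[str, ...] = ()


def _next_new_id(go: Ontology) -> str:
    used = {
        int(t.split(":")[1])
        for t in go.terms
        if t.startswith("GONEW:")
    }
    return f"GONEW:{max(used, default=0) + 1:07d}"


def generate_term(
    rule: TemplateRule,
    chemical: str,
    go: Ontology,
    chem: Ontology,
    gcis: list[Axiom] | None = None,
    bridge_axioms: list[Axiom] | None = None,
) -> NewTermRecord:
    """Template-based term generation with automatic placement.

    The label, EXACT synonyms and textual definition are derived from the
    rule grammar and the chemical's own names; the term is placed under its
    most specific entailed superclasses by the reasoner. The chemical must
    already exist in the chemical ontology — provisional chemistry has to be
    requested there first.
    """
    from .pipeline import classify_pipeline  # local import: avoid cycle

    if chemical not in chem.terms:
        raise MissingChemicalError(
            f"request missing chemical before generating the term: {chemical}"
        )
    chem_term = chem.terms[chemical]
    label = assemble_label(rule, chem_term.label)
    if go.term_by_label(label) is not None:
        raise DuplicateTermError(f"label already present: {label!r}")
    new_id = _next_new_id(go)
    synonyms = tuple(
        Synonym(assemble_label(rule, s.text), "EXACT")
        for s in chem_term.synonyms
        if s.scope == "EXACT"
    )
    term = Term(
        id=new_id,
        label=label,
        synonyms=synonyms,
        textual_definition=rule.definition.replace("{X}", chem_term.label),
    )
    ld = LogicalDefinition(new_id, rule.genus, ((rule.relation, chemical),))
    axiom = ld.to_axiom("bridge")

    scratch = go.copy()
    scratch.add_term(term)
    scratch.add_axiom(axiom)
    extra = list(gcis or [])
    if bridge_axioms:
        for ax in bridge_axioms:
            scratch.add_axiom(ax)
    res = classify_pipeline(scratch, chem, gcis=extra)
    placement = tuple(
        sorted(
            d
            for d in res.direct_superclasses(new_id)
            if d in go.terms
        )
    )
    return NewTermRecord(term, ld, axiom, placement)
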