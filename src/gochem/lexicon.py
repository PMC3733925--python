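"""Chemical-name matching between ontologies.

Chemical strings extracted from process/function labels are looked up
against the chemical ontology's labels and synonyms under a shared
normalization. Misses can be minted as provisional GOCHE-prefixed terms,
recorded in a request ledger for later submission to the chemical ontology.

Normalization deliberately performs NO plural stemming: a plural chemical
name denotes a structural family (the CLASS reading, e.g. "pyridines"),
a singular name one molecule (the EXACT reading, "pyridine"); collapsing
them would conflate distinct classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .model import Ontology, Term

__all__ = [
    "normalize_name",
    "NameIndex",
    "build_index",
    "MatchResult",
    "match_chemical",
    "GocheRegistry",
    "mint_temporary",
    "greek_map",
]

GOCHE_PREFIX = "GOCHE"

_greek_cache: dict[str, str] | None = None


def greek_map(path: str | Path | None = None) -> dict[str, str]:
    """Greek letter -> spelled-out name, from the editable config table."""
    global _greek_cache
    if path is not None:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return {v: k for k, v in data.items()}
    if _greek_cache is None:
        text = (
            resources.files("gochem.data").joinpath("greek.yaml").read_text()
        )
        _greek_cache = {v: k for k, v in yaml.safe_load(text).items()}
    return _greek_cache


def normalize_name(s: str) -> str:
    """Case-fold, collapse whitespace, drop spaces around hyphens, and spell
    out Greek letters. Idempotent; never stems plurals."""
    s = s.strip().casefold()
    for letter, name in greek_map().items():
        s = s.replace(letter, name)
    s = re.sub(r"\s+", " ", s)
    s = re.sub(r"\s*-\s*", "-", s)
    return s


@dataclass
class NameIndex:
    """normalized string -> [(term id, source)] with source in
    {label, exact_synonym, other_synonym}."""

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def add(self, name: str, term_id: str, source: str) -> None:
        key = normalize_name(name)
        bucket = self.entries.setdefault(key, [])
        if (term_id, source) not in bucket:
            bucket.append((term_id, source))
            bucket.sort()

    def get(self, name: str) -> list[tuple[str, str]]:
        return self.entries.get(normalize_name(name), [])

    def merged_with(self, other: "NameIndex") -> "NameIndex":
        out = NameIndex()
        for idx in (self, other):
            for key, bucket in idx.entries.items():
                for term_id, source in bucket:
                    out.entries.setdefault(key, [])
                    if (term_id, source) not in out.entries[key]:
                        out.entries[key].append((term_id, source))
        for bucket in out.entries.values():
            bucket.sort()
        return out


def build_index(chem: Ontology) -> NameIndex:
    """Index every non-obsolete label and synonym of a chemical ontology."""
    idx = NameIndex()
    for term in chem.terms.values():
        if term.obsolete:
            continue
        if term.label:
            idx.add(term.label, term.id, "label")
        for syn in term.synonyms:
            source = "exact_synonym" if syn.scope == "EXACT" else "other_synonym"
            idx.add(syn.text, term.id, source)
    return idx


@dataclass
class MatchResult:
    query: str
    matched: str | None = None
    match_kind: str = "none"  # label|exact_synonym|other_synonym|temporary|none
    ambiguous_with: tuple[str, ...] = ()


_TIERS = ("label", "exact_synonym", "other_synonym")


def match_chemical(query: str, index: NameIndex) -> MatchResult:
    """Look a chemical string up with precedence label > EXACT synonym >
    other synonym. Multiple hits in the winning tier are surfaced as an
    ambiguity (a manual-review signal), never auto-resolved."""
    entries = index.get(query)
    for tier in _TIERS:
        hits = sorted({tid for tid, source in entries if source == tier})
        if len(hits) == 1:
            return MatchResult(query, hits[0], tier)
        if len(hits) > 1:
            return MatchResult(query, None, "none", tuple(hits))
    return MatchResult(query)


@dataclass
class LedgerEntry:
    query: str
    normalized: str
    minted_id: str
    source_term: str = ""


class GocheRegistry:
    """Provisional chemical terms minted under the GOCHE prefix.

    Minting the same normalized query twice returns the existing term; every
    first mint is recorded in a request ledger (the set of chemicals to be
    submitted to the chemical ontology).
    """

    def __init__(self, ontology: Ontology | None = None):
        self.ontology = ontology or Ontology("goche")
        self.ledger: list[LedgerEntry] = []
        self._by_norm: dict[str, str] = {}
        for term in self.ontology.terms.values():
            if term.id.startswith(GOCHE_PREFIX + ":"):
                self._by_norm[normalize_name(term.label)] = term.id

    def _next_id(self) -> str:
        used = {
            int(t.split(":")[1])
            for t in self.ontology.terms
            if t.startswith(GOCHE_PREFIX + ":")
        }
        n = max(used, default=0) + 1
        return f"{GOCHE_PREFIX}:{n:07d}"

    def mint(self, query: str, source_term: str = "") -> Term:
        norm = normalize_name(query)
        if norm in self._by_norm:
            return self.ontology.terms[self._by_norm[norm]]
        term = Term(id=self._next_id(), label=query)
        self.ontology.add_term(term)
        self._by_norm[norm] = term.id
        self.ledger.append(LedgerEntry(query, norm, term.id, source_term))
        return term

    def index(self) -> NameIndex:
        return build_index(self.ontology)

    def ledger_tsv(self) -> str:
        lines = ["query\tnormalized\tminted_id\tfirst_seen_source_term"]
        for e in self.ledger:
            lines.append(
                f"{e.query}\t{e.normalized}\t{e.minted_id}\t{e.source_term}"
            )
        return "\n".join(lines) + "\n"


def mint_temporary(
    query: str, registry: GocheRegistry, source_term: str = ""
) -> Term:
    """Mint (or fetch) the provisional term for an unmatched chemical string."""
    return registry.mint(query, source_term)
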