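# Methods

## The model

The package treats a process/function ontology and a chemical ontology as
EL terminologies: named classes, existential restrictions and
intersections, related by SubClassOf and EquivalentClasses axioms. Every
axiom carries a provenance tag from `{asserted, bridge, gci, inferred,
temporary}`:

* `asserted` — curated content; never modified by any operation;
* `bridge` — genus-differentia equivalence axioms generated from labels;
* `temporary` — bridge axioms whose chemical filler is a provisional
  `GOCHE:` class awaiting adoption by the chemical ontology;
* `gci` — the conjugate acid/base overlay;
* `inferred` — is_a links asserted by the sync protocol on the reasoner's
  behalf.

Keeping provenance on the axiom (rather than in separate files) lets every
overlay be stripped exactly and makes "never touch curated content" a
checkable invariant rather than a convention.

### Label templates

A label is matched against template rules in strictly decreasing priority
(catabolic > biosynthetic > metabolic > transporter activity > transport >
secretion > homeostasis > binding > response-to). The order matters because
tails nest: "x biosynthetic process" must bind the biosynthetic rule, not
the metabolic rule with chemical string "x biosynthetic". The chemical
string is the maximal capture. `regulation of ...` labels (and the
positive/negative variants) are deliberately out of scope: a regulation
term is about a process, not about a chemical participant. Terms that are
themselves the genus of a rule ("chemical homeostasis", "response to
stimulus") are skipped during bridging — they anchor their family rather
than reference a chemical.

The metabolic rule uses `has_participant`; biosynthesis uses `has_output`;
catabolism and binding and response-to use `has_input`; transport uses
`transports_or_maintains_localization_of`. Three families (secretion,
homeostasis, transporter activity) are template-defined in practice but
have no canonical relation in the core table; the shipped config flags them
as extensions with analogical defaults (secretion and transporter activity
reuse the transport relation; homeostasis uses `regulates_levels_of`).
They are config entries precisely so downstream users can re-point them
without code changes.

### Name matching

Matching is deliberately conservative string matching, not cheminformatics:
case-folding, whitespace collapsing, hyphen-spacing normalization, and a
config-driven Greek-letter table (β → beta). Two things it never does:

* **no plural stemming** — a plural chemical name is a CLASS reading (a
  structural family: "pyridines") and the singular an EXACT reading (one
  molecule: "pyridine"); collapsing them would merge distinct classes;
* **no ambiguity resolution** — several equally-ranked hits produce an
  explicit ambiguity record for manual curation, never a guess.

Precedence is label > EXACT synonym > other synonym, a tiering convention
of this package (the curation practice it models resolves ties manually
anyway, so only unique winners are auto-accepted).

### Conjugate acid/base overlay

For each *asserted* conjugate pair the overlay emits `∃R.X ≡ ∃R.Y` for the
four relations `has_participant, transports, has_input, has_output`
(`generate_gcis` validates any caller-supplied alternative list against a
relation catalog). Chains are not materialized into pairs: equivalence
along a deprotonation chain of length k falls out of reasoning, which the
test suite verifies up to k = 5. `transports` is registered as a
sub-relation of `transports_or_maintains_localization_of`, and an extended
relation list including both is available for callers that want the
transport-family definitions covered directly. Tautomer links
(`is_tautomer_of`) are intentionally not equated, and stereoisomers/salts
are untouched: those distinctions do not get conflated in practice, so
equating them would only weaken the chemistry.

### Reasoning

The reasoner implements EL with GCIs and a simple relation hierarchy — no
role composition, no disjointness, no nominals, because nothing in the
bridging axioms needs them. Consequently unsatisfiability cannot arise;
modeling conflicts are surfaced by the audit module as data instead.
Normalization introduces fresh names derived from a hash of the canonical
rendering of the expression they replace, so normal forms are identical
across runs and processes. Classification is worklist saturation of the
standard completion rules; its contract is the least fixpoint, checked
against an independent full-pass re-saturation oracle on 200 seeded random
ontologies per run, plus monotonicity and idempotence property suites.

`direct_superclasses` filters fresh names, reports equivalence groups
together, and returns subsumers with no strictly intermediate subsumer —
the placement operation used by term generation and sync.

### The recapitulation basis

Whether an asserted is_a link is "recapitulated by reasoning" is only a
meaningful question if that link is not itself part of the reasoner input.
All placement reasoning therefore runs on the *recapitulation basis*: the
chemical ontology, the logical definitions, the GCI overlay, and only
those process-ontology is_a links whose subclass has no logical definition
(the hand-built genus scaffold). This single basis serves three consumers:
the entailment audit, the sync protocol, and new-term placement.

### Sync protocol

Given a classification, the sync computes: additions (entailed direct
superclasses of defined terms not already asserted directly or
transitively, tagged `inferred`), removals (previously inferred-tagged
links no longer entailed), and warnings (asserted links that cannot be
re-derived — these go to curators, never to deletion). Additions are judged
on the hierarchy *minus* the simultaneous removals, so a single pass
reaches the fixed point: apply-then-recompute is empty, which the suite
asserts.

## File formats

OBO 1.2 is the working format. Logical definitions round-trip through
paired `intersection_of` lines and are read as full equivalences (the
definitions are equivalence axioms, not mere necessary conditions).
Provenance survives round-trips via trailing modifiers
(`{is_inferred="true"}` on inferred is_a lines, `{provenance="..."}`
otherwise). Axioms OBO cannot host — GCIs between unnamed expressions — go
to a `*.gci.txt` sidecar, one canonical rendering per line, which
round-trips bit-exactly. Unsupported tags are preserved verbatim and
queryable, so foreign files are not silently stripped. A would-be logical
definition whose filler is an anonymous intersection is a write error
(name the inner class) rather than a silent relocation to the sidecar.

## The fixture bundle

`worked_example()` builds a mini chemical ontology (25 classes) and a mini
process ontology (9 genus terms + 18 chemical-referencing terms, one of
which names a chemical the chemical ontology lacks) embedding the
canonical trouble cases: the glucose-6-phosphate transport vs
transporter-activity asymmetry, the nitrilotriacetate/nitrilotriacetic-acid
conflation with its conjugate link, the citric-acid deprotonation chain
(one pair asserted in both directions, to exercise deduplication),
pyridine vs pyridines, butyric acid with EXACT synonym "butanoic acid",
xanthine under purine, and the aldoxime/oxime coverage gap. Famous classes
keep their canonical CURIEs; invented ones use the `FIX:` prefix.

What the bundle emulates is the *structure* of the real integration
problem — template-parseable labels, synonym misses, family asymmetries,
conjugate chains, release-driven movement — at a scale where every
expected output can be hand-enumerated (the bundle ships that enumeration
and the tests re-derive it). What it does not emulate: the scale of real
ontologies (tens of thousands of classes), label noise beyond the encoded
cases (bracketed qualifiers, chirality prefixes at arbitrary positions),
multi-differentia definitions, and the role/disposition classification
axes. Green tests therefore demonstrate the machinery's correctness on the
specified behaviours, not recall statistics on a real GO/ChEBI release
pair; on real inputs the match/miss/ambiguity split shifts but the
contracts (determinism, provenance separation, closure-aware audits,
sync fixed point) are input-independent.

`random_ontology(n, k, density, seed)` generates an acyclic is_a core
(edges only from higher to lower index) plus EL-normal-form-shaped axioms
and optional conjugate chains — enough surface to exercise the parser,
writer and reasoner, with validity guaranteed by construction.

## Problem sizes and numerical choices

The property suites run at deliberately small scale — random ontologies of
at most 40 classes and 3 relations, 200 instances for oracle agreement,
100 each for monotonicity/idempotence, 100 round-trip instances — sizes at
which the naive oracle is still exact and the whole suite completes in
seconds while sweeping axiom density across (0.1, 0.9). There is no
floating point anywhere; all comparisons are exact set equality.
Determinism choices worth knowing: intersections are deduplicated and
sorted by rendering; EquivalentClasses operands are order-normalized;
`GOCHE:` and `GONEW:` identifiers are sequential from the first free
number; stanza and tag order in written OBO is canonical, so identical
inputs give byte-identical outputs.

## Known limitations

* Labels that deviate from the template grammar (extra qualifiers,
  non-suffix tails) parse as misses, by design — there is no fuzzy
  matching.
* The CLASS-reading detector in the rename operation accepts only a plain
  plural of the matched token ("phenol"/"phenols"); anything else is
  routed to manual review.
* Whether the import subset should contain conjugate partners of used
  terms is a judgment call; they are included so the GCIs over the subset
  remain meaningful.
* OBO output drops line comments (`! ...`) and normalizes tag order;
  round-trip guarantees are structural plus canonical-text, not
  byte-preservation of arbitrary third-party formatting.
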