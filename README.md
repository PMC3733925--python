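# gochem

Tooling for dovetailing a process/function ontology (GO-style) with a
chemical ontology (ChEBI-style).

Thousands of biological-process and molecular-function terms mention a
chemical in their label — "xanthine biosynthetic process", "carbohydrate
binding", "glucose-6-phosphate transport". Each such label hides two
claims: a *genus* (the broad process family) and a *differentia* (the
chemical involved). Left implicit, these claims drift: the same chemical
gets contradictory parentages in different sub-hierarchies, acids are
conflated with their conjugate bases, and chemicals referenced by process
terms may not exist in the chemical ontology at all. `gochem` makes the
chemistry explicit, audits it, and keeps the process hierarchy synchronized
with what it logically entails.

## What the package does

1. **Logical definitions** (`gochem.defgen`). Labels are parsed against a
   priority-ordered template table ("`{X} biosynthetic process`",
   "`response to {X}`", ...) and each match becomes an equivalence axiom

   ```
   <term>  EquivalentTo:  <genus>  and  <relation> some <chemical>
   ```

   e.g. `'xanthine biosynthetic process' ≡ 'biosynthetic process' ⊓
   ∃has_output.'xanthine'`. Chemical strings are resolved against the
   chemical ontology's labels and synonyms (`gochem.lexicon`), with
   precedence label > EXACT synonym > other synonym; misses can be minted
   as provisional `GOCHE:` terms and queued for submission. Plural-named
   chemical families ("phenols") get the `X-containing compound` renaming
   convention; a TermGenie-style generator builds new, reasoner-placed
   terms from a rule plus a chemical.

2. **Implicit chemical ontology and audits** (`gochem.implicit`). Every
   is_a link between two defined terms of one family implies a link between
   their chemicals. The union of these projections is a stand-alone
   chemical ontology that can be checked for cross-family contradictions
   (a chemical pair linked in the transport hierarchy but not in the
   transporter-activity hierarchy) and diffed against the reference
   chemical ontology.

3. **Conjugate acid/base equivalence** (`gochem.biochebi`). For every
   asserted conjugate pair {X, Y} the overlay adds four general concept
   inclusions `∃R.X ≡ ∃R.Y` for R ∈ {has_participant, transports,
   has_input, has_output}, so a process over citric acid is equivalent to
   the same process over citrate(1-), citrate(2-), ... without minting
   grouping classes.

4. **EL reasoning** (`gochem.reasoner`). Axioms — including the GCIs — are
   normalized to the EL normal forms (A⊑B, A1⊓A2⊑B, A⊑∃r.B, ∃r.A⊑B) and
   saturated with the standard completion rules under a simple relation
   hierarchy. An independent naive fixpoint implementation serves as a
   test oracle.

5. **Hierarchy sync** (`gochem.sync`). Entailed direct superclasses are
   asserted with an `{is_inferred="true"}` tag; tagged links that stop
   being entailed after a chemical-ontology release are retracted;
   curator-asserted links are never deleted, only reported when the
   reasoner cannot recapitulate them.

I/O is OBO 1.2 (`gochem.obo`) with a plain-text `*.gci.txt` sidecar for
axioms OBO cannot host. `gochem.fixtures` generates a worked-example
mini-ontology pair and seeded random ontologies, so everything is testable
offline.

## Worked example

```
$ gochem fixtures --out fx
fixtures: wrote mini_go.obo, mini_chebi.obo
$ gochem bridge --go fx/mini_go.obo --chem fx/mini_chebi.obo --out out --mint
bridge: 18 definitions, 1 unmatched, 0 ambiguous
$ gochem audit --go fx/mini_go.obo --chem fx/mini_chebi.obo --out out
audit: 1 conflicts, 4 discrepancies
$ gochem gci --chem fx/mini_chebi.obo --out out --used FIX:carboxylic_acid
gci: 4 conjugate pairs, 16 GCI axioms
$ gochem sync --go fx/mini_go.obo --chem fx/mini_chebi.obo --out out --apply
sync: +0 -0 (1 warnings)
```

Reading the numbers: 18 definitions = 17 labels resolved against the
chemical ontology plus one ("aldoxime metabolic process") resolved by
minting `GOCHE:0000001`, which is also the 1 unmatched entry in
`out/unmatched.tsv`. The 1 conflict is glucose-6-phosphate sitting under
glucose in the transport hierarchy but not in the transporter-activity
hierarchy; the 4 discrepancies include that edge (not entailed by the
chemical ontology, where glucose-6-phosphate is a hexose phosphate but not
a glucose) and the minted chemical missing from the reference. The 4
conjugate pairs (nitrilotriacetic acid/nitrilotriacetate plus the
citric-acid chain) generate 4 x 4 = 16 GCIs. The sync report is empty —
the fixture hierarchy already matches its entailments — with one warning
for the asserted transport link the reasoner cannot recapitulate.

```
$ gochem termgen --go fx/mini_go.obo --chem fx/mini_chebi.obo \
    --rule catabolic --chemical FIX:citric_acid
[Term]
id: GONEW:0000001
name: citric acid catabolic process
def: "The chemical reactions and pathways resulting in the breakdown of citric acid." []
intersection_of: GO:0009056
intersection_of: has_input FIX:citric_acid
is_a: GO:0009056 {is_inferred="true"}
```

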