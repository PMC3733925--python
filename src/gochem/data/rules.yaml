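# Label-template rules for genus-differentia logical definitions.
#
# Each rule parses a chemical-referencing label into a chemical string {X}
# and supplies the genus class and the relation used in the equivalence
# axiom  <term> EquivalentTo: <genus> and <relation> some <chemical>.
#
# Priority order matters: longer, more specific tails must win over
# substring tails ("x biosynthetic process" must not parse as the metabolic
# rule with X = "x biosynthetic"). Rules flagged `extension: true` cover
# term families whose relation is not part of the initial rule table; their
# relation choices are analogical defaults and can be edited here.
rules:
  - id: catabolic
    pattern: "{X} catabolic process"
    genus: GO:0009056
    relation: has_input
    definition: "The chemical reactions and pathways resulting in the breakdown of {X}."
    priority: 90
  - id: biosynthetic
    pattern: "{X} biosynthetic process"
    genus: GO:0009058
    relation: has_output
    definition: "The chemical reactions and pathways resulting in the formation of {X}."
    priority: 80
  - id: metabolic
    pattern: "{X} metabolic process"
    genus: GO:0008152
    relation: has_participant
    definition: "The chemical reactions and pathways involving {X}."
    priority: 70
  - id: transporter_activity
    pattern: "{X} transporter activity"
    genus: GO:0005215
    relation: transports_or_maintains_localization_of
    definition: "Enables the directed movement of {X} into, out of or within a cell, or between cells."
    priority: 60
    extension: true
  - id: transport
    pattern: "{X} transport"
    genus: GO:0006810
    relation: transports_or_maintains_localization_of
    definition: "The directed movement of {X} into, out of or within a cell, or between cells, by means of some agent such as a transporter or pore."
    priority: 50
  - id: secretion
    pattern: "{X} secretion"
    genus: GO:0046903
    relation: transports_or_maintains_localization_of
    definition: "The controlled release of {X} from a cell."
    priority: 40
    extension: true
  - id: homeostasis
    pattern: "{X} homeostasis"
    genus: GO:0048878
    relation: regulates_levels_of
    definition: "Any process involved in the maintenance of an internal steady state of {X} within an organism or cell."
    priority: 30
    extension: true
  - id: binding
    pattern: "{X} binding"
    genus: GO:0005488
    relation: has_input
    definition: "Binding to {X}."
    priority: 20
  - id: response_to
    pattern: "response to {X}"
    genus: GO:0050896
    relation: has_input
    definition: "Any process that results in a change in state or activity of a cell or an organism as a result of a {X} stimulus."
    priority: 10
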