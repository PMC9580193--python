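# Methods

This note documents the models and procedures implemented in `vaxalign`,
the choices made where the design was genuinely open, and what the bundled
fixtures and synthetic benchmarks do and do not demonstrate.

## The ontology model and its logic fragment

The ontology is restricted to the EL-with-chains fragment: named classes,
conjunction, existential restriction, subclass axioms, existential
assertions (`subject ⊑ ∃p.filler`), and *binary* property chains
(`p1 ∘ p2 ⇒ p`).  This is exactly the fragment vaccine descriptions need —
every construct used in practice (group membership, property attribution,
ingredient containment, causal unification) lives in it — and it admits a
polynomial-time completion procedure.  Negation, disjunction, cardinality,
and ABox individuals are deliberately absent; residual categories such as
"other viral vaccines" are therefore not representable, which is a known
limitation of description-based alignment rather than of this
implementation.  Chains longer than two properties are rejected at load
time with a clear error.

Every class must reach exactly one of the seven fundamental roots
(*vaccine, valence, route, ingredient, strategy, disease, pathogen*) via
its parent links; the roots are fixed identifiers because the compilation
rules dispatch on them.  Validation checks referential integrity,
acyclicity (reporting the offending cycle), and root uniqueness.

The canonical serialization is a four-section YAML document (classes with
`term@lang` labels, properties with domain/ranges, chains, assertions)
written in sorted order, so load→save round-trips are byte-stable.  An
OWL2 functional-syntax exporter is provided for interoperability; OWL
import is out of scope.

## The reasoner

`classify` computes the closure over named classes with an indexed
worklist: reflexive-transitive subclass closure, inheritance of
existential axioms to subclasses, filler generalization, and chain
application, to fixpoint.  Compound expressions are handled by
*internalization*: each conjunction/existential tree receives a fresh
named class axiomatized by its conjuncts, the closure is extended, and
subsumption of a compound on the right-hand side reduces to a structural
check against the closure.  This keeps the reasoner one algorithm; batch
entry points (`SubsumptionIndex.extend`,
`compiler.property_values_batch`) internalize all codes of a coding
system in a single extension so alignment costs one closure, not one per
pair.  The test suite checks the closure against an independently written
brute-force fixpoint oracle on hundreds of random ontologies.

## Tagging and normalization choices

* Tokenization lower-cases, folds accents (NFKD), and splits on
  non-alphanumeric characters, preserving digits ("3-valent" → `3`,
  `valent`).
* Tagging is greedy longest-match, left-to-right, non-overlapping —
  standard dictionary-tagger semantics.
* Matches of the seven root classes (the bare word "vaccine" in any
  language) are dropped from C(t): the compilation adds the vaccine root
  implicitly, and root matches would make every pair of codes overlap.
* Ambiguous terms yield *all* their classes, with a logged warning:
  surfacing both readings is the least lossy policy for descriptors whose
  dictionary is known to be imperfect.
* P(t) excludes the seven roots from the reported fillers by default
  (`exclude_roots`), and reports **all** entailed non-root fillers — both a
  pathogen and its disease when a causal link plus chain exists — not only
  the most specific ones; Jaccard over the richer set remains well defined.
* An empty C(t) compiles to the bare vaccine root and is flagged
  *uninformative*; uninformative codes score 0 against everything under the
  ontology-based methods, so unparseable descriptors never spuriously align
  to each other.
* Valence is matched only when textually present (directly or through a
  defining axiom such as IIV3's); it is never inferred from the number of
  immunization targets.

## Similarity and assignment

The `properties` method gates on the immunizes-against values: by default
the gate fires on *strict set inequality* (the literal reading of "the
values differed"); a `targets_gate: overlap` configuration switches to the
weaker disjointness reading, since the stricter reading is an
interpretation.  The graded overlap is the Jaccard coefficient over
(property, filler) pairs pooled across all vaccine properties, which keeps
properties commensurable without fixing per-property weights.

The threshold comparison is strict (`score > θ`), default θ = 0.1.  Ties at
the maximum are all assigned unless the target system is hierarchical, in
which case only the most general tied targets survive — defined minimally
as "no proper ancestor within the tied set".  Raising the threshold can
only shrink the assignment set, which makes sweep recall columns
non-increasing (asserted by tests).

An external concept tagger (e.g. a UMLS English tagger) can be registered
as an additional method (`register_external_method`): the descriptor is
mapped to a set of opaque concept ids and scored by Jaccard.  No such
tagger ships with the package.

## Evaluation conventions

TP/FP/FN count pairs literally: when a tie yields several targets and the
reference holds one, the match is a TP and the rest are FP.  Measures with
empty denominators are 0, keeping macro averages defined.  Macro averages
are unweighted means over source coding systems; micro averages pool the
counts first.

## The synthetic benchmark

`generate_benchmark` emulates the heterogeneity real vaccine coding
systems exhibit: the same underlying vaccine groups named via pathogen,
disease, abbreviation, or product, with optional strategy/route/valence
qualifiers, in different languages (en/es/it/ca, from small hand-written
synthetic lexicons — no machine translation), with seeded noise (per-token
dropout, distractor insertion, out-of-dictionary synonym substitution) and
an optional two-level target hierarchy whose gold alignment points at the
most specific representable child.

The default conditions — 20 groups, disease+strategy descriptors in
Spanish against disease+valence descriptors in English, noise-free — are
the canonical hard case: lexically disjoint, style-mismatched, but
semantically identical per group.  Both causal directions are asserted for
every synthetic pathogen/disease pair so that pathogen- and disease-style
names normalize to the same immunization targets.  Problem sizes
(20 groups, 5 seeds, 200 random ontologies for the oracle check) keep the
full suite and the acceptance script in the low seconds while leaving no
discreteness artifacts in the measured rates.

What passing these benchmarks shows: the pipeline's representations are
complete and discriminating for descriptors whose vocabulary the ontology
covers, and the method ordering (properties ≥ classes ≥ tokens on
multilingual, style-mismatched input) is a structural property of the
approach.  What it does not show: robustness to real-world dictionary
incompleteness, contextual knowledge (e.g. which vaccines are actually
authorized), or residual/combination codes without specific properties —
the documented error sources of description-based alignment.

## The curated mini ontology

`build_mini_ontology` contains seven pathogens and diseases with causal
links, five strategies, routes, valences 1–4, abbreviation classes (DTwP,
DTaP, IIV3) defined by existential assertions, and two products with
ingredient assertions, plus small es/it/ca term sets.  Its causal
assertions are deliberately asymmetric: the flu and DTP families declare
only pathogen→disease `causes` links, so abbreviation descriptors
normalize to diseases only, while the HPV/cervical-cancer pair declares
both directions and is fully interchangeable.  Both unification chains
are declared in the standard chain set; because chains are individually
declarable in the ontology file, either behaviour can be reproduced in
user ontologies.

## Known limitations

* One descriptor language per code (or a global language filter); no
  cross-lingual string similarity.
* No probabilistic or learned alignment; scores are set overlaps.
* The reasoner handles binary chains only (sufficient for the standard
  chain set).
* The `properties` gate makes immunization-target sets all-or-nothing;
  partially overlapping combination vaccines score 0 under the default
  gate (use `targets_gate: overlap` to soften).
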