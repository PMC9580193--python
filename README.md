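# vaxalign

Ontology-based alignment of vaccine coding systems from multilingual
free-text code descriptors.

Vaccine exposure in European electronic health record databases is recorded
with many different coding systems — clinical terminologies, drug
classifications, and database-specific custom code lists, often with
non-English descriptors.  Reusing such data in multi-database vaccine
benefit–risk studies requires *aligning* the coding systems: assigning each
source code to its closest corresponding target code.  Plain lexical
matching fails across languages and across conceptualizations ("Flu
vaccine" vs. "Influenza virus vaccine" vs. "IIV3"), so `vaxalign`
represents each descriptor as a logical statement about entities in a
vaccine ontology and compares codes through what the ontology *entails*
about them.

## The method

For a descriptor *t* the pipeline computes three representations of
increasing abstraction:

1. **C(t)** — the set of ontology classes referenced in *t*, found by a
   greedy longest-match scan of the multilingual ontology dictionary (every
   (term, language) label of every class).
2. **V(t) = ⟦C(t)⟧** — the compiled vaccine class, an EL
   description-logic expression.  Each identified class *c* compiles by its
   property category: *c* itself if *c* is a vaccine; `Vaccine ⊓
   ∃has-strategy.c` if a strategy; `Vaccine ⊓ ∃immunizes-against.c` if a
   pathogen or disease; analogously for ingredients, valences, and routes.
   A set of classes compiles to the conjunction.
3. **P(t)** — the normalized property values: for each vaccine property
   *p*, all classes *c* in range(*p*) with `V(t) ⊑ Vaccine ⊓ ∃p.c` under
   the ontology.  Entailment is computed by a built-in subsumption reasoner
   for the EL-with-chains fragment (subclass axioms, conjunction,
   existential restriction, binary property chains).  Property chains such
   as `has-ingredient ∘ immunizes-against ⇒ immunizes-against` and
   `immunizes-against ∘ causes ⇒ immunizes-against` propagate targets from
   ingredients to products and make causally linked pathogens and diseases
   interchangeable immunization targets.

Codes are then scored by one of four similarity methods — `tokens`
(Jaccard of descriptor tokens), `classes` (Jaccard of C), `equivalence`
(1 iff the V's are mutually subsumed), `properties` (0 unless the
immunizes-against values agree, else Jaccard of the pooled (property,
value) pairs) — and each source code is assigned every target code
attaining the maximal score, provided it strictly exceeds the threshold
(default 0.1).  Ties in a hierarchical target system keep only the most
general tied codes.  Alignments are evaluated against reference alignments
by precision, recall, and F-score (macro and micro averages, threshold
sweeps).

## Worked example

```python
from vaxalign import (build_mini_ontology, build_dictionary, classify,
                      property_values)

onto = build_mini_ontology()
index = classify(onto)
d = build_dictionary(onto)
pv = property_values("DTwP", onto, index, dictionary=d)
print({p: sorted(v) for p, v in pv.values.items() if v})
```

prints

```
{'has-strategy': ['inactivated'], 'immunizes-against': ['diphtheria', 'pertussis', 'tetanus']}
```

i.e. the abbreviation "DTwP" is recognized as a combination vaccine against
diphtheria, tetanus, and pertussis with an inactivated (whole-cell)
strategy.  Running `python examples/align_coding_systems.py` aligns two
synthetic coding systems that name the same 20 vaccine groups by disease +
strategy in Spanish and by disease + valence in English:

```
method       precision  recall      F
tokens           0.000   0.000  0.000
classes          1.000   1.000  1.000
equivalence      0.000   0.000  0.000
properties       1.000   1.000  1.000
```

The lexical baseline cannot cross the language gap, the strict equivalence
test is defeated by the differing qualifiers, while the normalized
property values recover the gold alignment exactly.  The other scripts in
`examples/` demonstrate descriptor analysis, threshold sweeps, and writing
benchmark files for the CLI (`vaxalign analyse|align|evaluate|sweep|make-benchmark`).

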