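"""Analyse free-text vaccine descriptors against the bundled mini ontology.

For each descriptor the pipeline identifies ontology classes (C), compiles
them into a description-logic vaccine class (V), and normalizes V to property
values (P) with the subsumption reasoner.  Descriptors phrased via a disease,
its pathogen, an abbreviation, or a product name all normalize to the same
immunization target — the key idea behind the properties similarity method.
"""

from vaxalign import (
    build_dictionary,
    build_mini_ontology,
    classify,
    format_expression,
    property_values,
    vaccine_class,
)

ontology = build_mini_ontology()
index = classify(ontology)
dictionary = build_dictionary(ontology)

for text in [
    "Live/attenuated influenza vaccine",
    "DTwP",
    "Flu vaccine",
    "Influenza virus vaccine",
    "IIV3",
    "Influvac",
]:
    vc = vaccine_class(text, ontology, dictionary)
    pv = property_values(vc, ontology, index)
    print(f"descriptor : {text}")
    print(f"  C (classes)    : {sorted(vc.class_ids)}")
    print(f"  V (expression) : {format_expression(vc.expression)}")
    nonempty = {p: sorted(v) for p, v in sorted(pv.values.items()) if v}
    print(f"  P (values)     : {nonempty}")
    print()

print(
    "Note how the last four descriptors — disease name, pathogen phrase,\n"
    "abbreviation, and product — all normalize to immunizes-against =\n"
    "['influenza'], although their token and class sets barely overlap."
)
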