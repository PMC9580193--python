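"""Compilation of identified classes into vaccine class expressions and
normalization to property values.

A class found in a descriptor is compiled according to its property category:
a vaccine class stands for itself, every other category becomes an existential
restriction on the corresponding vaccine property (a strategy ``c`` becomes
``Vaccine and (has-strategy some c)``, a pathogen or disease becomes
``Vaccine and (immunizes-against some c)``, and so on).  A set of identified
classes compiles to the conjunction of the individual compilations; the empty
set compiles to the bare vaccine root and is flagged uninformative.

Normalization then asks the reasoner, for each vaccine property, for every
entailed filler class — making descriptions that differ in surface form
(pathogen vs. disease, product vs. group, abbreviation vs. phrase) comparable
as plain sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .errors import UnknownIdentifierError, ValidationError
from .expressions import And, ClassExpression, Named, Some
from .ontology import Ontology, VACCINE_ROOT
from .reasoner import SubsumptionIndex, entailed_fillers
from .tagger import Dictionary, TagResult, tag

#: Property category -> vaccine property used in compilation.
ROOT_PROPERTY: dict[str, str] = {
    "strategy": "has-strategy",
    "pathogen": "immunizes-against",
    "disease": "immunizes-against",
    "ingredient": "has-ingredient",
    "valence": "has-valence",
    "route": "has-route",
}


def vaccine_domain_properties(ontology: Ontology) -> tuple[str, ...]:
    """The properties whose domain is the vaccine root, in id order."""
    return tuple(
        sorted(p.id for p in ontology.properties.values() if p.domain_id == VACCINE_ROOT)
    )


def compile_class(class_id: str, ontology: Ontology) -> ClassExpression:
    """Compile one identified class into a vaccine class expression."""
    root = ontology.fundamental_root(class_id)
    if root == VACCINE_ROOT:
        return Named(class_id)
    prop = ROOT_PROPERTY.get(root)
    if prop is None:  # unreachable for a validated ontology
        raise ValidationError(f"class {class_id!r} has undeterminable category {root!r}")
    if prop not in ontology.properties:
        raise UnknownIdentifierError(prop, kind="vaccine property")
    return And((Named(VACCINE_ROOT), Some(prop, Named(class_id))))


def compile_set(class_ids: Iterable[str], ontology: Ontology) -> ClassExpression:
    """Conjunction of the compiled classes, in deterministic (sorted) order.

    The empty set compiles to the bare vaccine root.
    """
    ids = sorted(set(class_ids))
    if not ids:
        return Named(VACCINE_ROOT)
    operands: list[ClassExpression] = []
    restrictions: list[ClassExpression] = []
    needs_root = False
    for cid in ids:
        compiled = compile_class(cid, ontology)
        if isinstance(compiled, Named):
            operands.append(compiled)
        else:  # Vaccine and (p some c): pool the restriction, share one root conjunct
            needs_root = True
            restrictions.append(compiled.operands[1])
    if needs_root:
        operands.insert(0, Named(VACCINE_ROOT))
    operands.extend(restrictions)
    if len(operands) == 1:
        return operands[0]
    return And(tuple(operands))


@dataclass(frozen=True)
class VaccineClass:
    """The compiled representation V(t) of one descriptor."""

    expression: ClassExpression
    class_ids: frozenset[str]
    uninformative: bool  # no dictionary class was found in the text
    text: Optional[str] = None


def vaccine_class(
    text: str,
    ontology: Ontology,
    dictionary: Dictionary,
    languages: Optional[Iterable[str]] = None,
) -> VaccineClass:
    """Tag the text and compile the identified classes."""
    result: TagResult = tag(text, dictionary, languages=languages)
    return VaccineClass(
        expression=compile_set(result.class_ids, ontology),
        class_ids=result.class_ids,
        uninformative=not result.class_ids,
        text=text,
    )


@dataclass(frozen=True)
class PropertyValues:
    """The normalized representation P(t): property -> entailed filler classes."""

    values: Mapping[str, frozenset[str]]
    uninformative: bool = False

    def pairs(self) -> frozenset[tuple[str, str]]:
        """Pooled (property, filler) pairs across all properties."""
        return frozenset((p, c) for p, cs in self.values.items() for c in cs)

    def __getitem__(self, prop: str) -> frozenset[str]:
        return self.values[prop]


def property_values(
    source: Union[str, ClassExpression, VaccineClass],
    ontology: Ontology,
    index: SubsumptionIndex,
    dictionary: Optional[Dictionary] = None,
    languages: Optional[Iterable[str]] = None,
    exclude_roots: bool = True,
) -> PropertyValues:
    """Normalize a descriptor (or an already-compiled expression) to P(t)."""
    if isinstance(source, str):
        if dictionary is None:
            raise ValueError("a dictionary is required to normalize raw text")
        source = vaccine_class(source, ontology, dictionary, languages=languages)
    if isinstance(source, VaccineClass):
        expr = source.expression
        uninformative = source.uninformative
    else:
        expr = source
        uninformative = False
    values = {
        p: entailed_fillers(index, expr, p, exclude_roots=exclude_roots)
        for p in vaccine_domain_properties(ontology)
    }
    return PropertyValues(values=values, uninformative=uninformative)


def property_values_batch(
    compiled: Mapping[str, VaccineClass],
    ontology: Ontology,
    index: SubsumptionIndex,
    exclude_roots: bool = True,
) -> dict[str, PropertyValues]:
    """Normalize many compiled descriptors with a single closure extension."""
    names = {f"__code_{i}": key for i, key in enumerate(compiled)}
    extended = index.extend({n: compiled[k].expression for n, k in names.items()})
    props = vaccine_domain_properties(ontology)
    out: dict[str, PropertyValues] = {}
    for name, key in names.items():
        values = {
            p: entailed_fillers(extended, None, p, exclude_roots=exclude_roots, subject_id=name)
            for p in props
        }
        out[key] = PropertyValues(values=values, uninformative=compiled[key].uninformative)
    return out
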