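"""Vaccine-description ontology: model, validation, and serialization.

The ontology is a small EL-style knowledge base.  Classes sit under exactly one
of seven fundamental roots (the vaccine property categories), carry multilingual
terms, and are related by object properties, binary property chains, and
existential assertions ``subject SubClassOf (property some filler)``.

The canonical on-disk form is a YAML document with four sections (classes,
properties, chains, assertions); :func:`save_ontology` writes it in a canonical
sort order so that load→save round-trips are byte-stable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .errors import (
    CycleError,
    OntologyParseError,
    UnknownIdentifierError,
    ValidationError,
)

#: The seven fundamental property-category roots every class descends from.
FUNDAMENTAL_ROOTS: tuple[str, ...] = (
    "disease",
    "ingredient",
    "pathogen",
    "route",
    "strategy",
    "vaccine",
    "valence",
)

VACCINE_ROOT = "vaccine"


@dataclass(frozen=True)
class OntologyClass:
    """A named class with multilingual terms and parent links."""

    id: str
    parent_ids: tuple[str, ...] = ()
    labels: tuple[tuple[str, str], ...] = ()  # (term, language-tag) pairs


@dataclass(frozen=True)
class ObjectProperty:
    """An object property defined by its domain and range classes."""

    id: str
    domain_id: str
    range_ids: tuple[str, ...]


@dataclass(frozen=True)
class PropertyChain:
    """A binary chain axiom ``lhs[0] o lhs[1] => rhs``."""

    lhs: tuple[str, str]
    rhs: str


@dataclass(frozen=True)
class Assertion:
    """An existential axiom ``subject SubClassOf (property some filler)``."""

    subject_id: str
    property_id: str
    filler_id: str


class Ontology:
    """In-memory ontology with lookup helpers; validated on construction."""

    def __init__(
        self,
        classes: Iterable[OntologyClass],
        properties: Iterable[ObjectProperty] = (),
        chains: Iterable[PropertyChain] = (),
        assertions: Iterable[Assertion] = (),
        validate: bool = True,
    ):
        self.classes: dict[str, OntologyClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise ValidationError(f"duplicate class id: {cls.id!r}")
            self.classes[cls.id] = cls
        self.properties: dict[str, ObjectProperty] = {}
        for prop in properties:
            if prop.id in self.properties:
                raise ValidationError(f"duplicate property id: {prop.id!r}")
            self.properties[prop.id] = prop
        self.chains: tuple[PropertyChain, ...] = tuple(chains)
        self.assertions: tuple[Assertion, ...] = tuple(assertions)
        self._roots: dict[str, str] = {}
        if validate:
            self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity, acyclicity, and root uniqueness."""
        for root in FUNDAMENTAL_ROOTS:
            if root not in self.classes:
                raise ValidationError(f"fundamental root class missing: {root!r}")
            if self.classes[root].parent_ids:
                raise ValidationError(f"fundamental root {root!r} must not have parents")
        for cls in self.classes.values():
            for pid in cls.parent_ids:
                if pid not in self.classes:
                    raise UnknownIdentifierError(pid, kind=f"parent of class {cls.id!r}")
        self._check_acyclic()
        self._roots = {}
        for cid in self.classes:
            self._roots[cid] = self._resolve_root(cid)
        for prop in self.properties.values():
            if prop.domain_id not in self.classes:
                raise UnknownIdentifierError(prop.domain_id, kind=f"domain of property {prop.id!r}")
            if not prop.range_ids:
                raise ValidationError(f"property {prop.id!r} has an empty range")
            for rid in prop.range_ids:
                if rid not in self.classes:
                    raise UnknownIdentifierError(rid, kind=f"range of property {prop.id!r}")
        for chain in self.chains:
            if len(chain.lhs) != 2:
                raise ValidationError(
                    f"property chains must have exactly two left-hand properties, got {chain.lhs!r}"
                )
            for pid in (*chain.lhs, chain.rhs):
                if pid not in self.properties:
                    raise UnknownIdentifierError(pid, kind="property in chain")
        for a in self.assertions:
            if a.subject_id not in self.classes:
                raise UnknownIdentifierError(a.subject_id, kind="assertion subject")
            if a.property_id not in self.properties:
                raise UnknownIdentifierError(a.property_id, kind="assertion property")
            if a.filler_id not in self.classes:
                raise UnknownIdentifierError(a.filler_id, kind="assertion filler")

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {cid: WHITE for cid in self.classes}
        stack_path: list[str] = []

        def visit(cid: str) -> None:
            color[cid] = GREY
            stack_path.append(cid)
            for pid in self.classes[cid].parent_ids:
                if color[pid] == GREY:
                    i = stack_path.index(pid)
                    raise CycleError(stack_path[i:] + [pid])
                if color[pid] == WHITE:
                    visit(pid)
            stack_path.pop()
            color[cid] = BLACK

        for cid in self.classes:
            if color[cid] == WHITE:
                visit(cid)

    def _resolve_root(self, cid: str) -> str:
        roots = set()
        seen = set()
        stack = [cid]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            cls = self.classes[cur]
            if not cls.parent_ids:
                roots.add(cur)
            stack.extend(cls.parent_ids)
        roots_found = roots & set(FUNDAMENTAL_ROOTS)
        if roots != roots_found or len(roots_found) != 1:
            raise ValidationError(
                f"class {cid!r} must reach exactly one fundamental root, reaches {sorted(roots)}"
            )
        return next(iter(roots_found))

    # -- queries --------------------------------------------------------

    def fundamental_root(self, cid: str) -> str:
        """The fundamental root the class descends from."""
        if cid not in self.classes:
            raise UnknownIdentifierError(cid, kind="class")
        if cid not in self._roots:
            self._roots[cid] = self._resolve_root(cid)
        return self._roots[cid]

    def ancestors(self, cid: str, include_self: bool = True) -> set[str]:
        if cid not in self.classes:
            raise UnknownIdentifierError(cid, kind="class")
        out: set[str] = {cid} if include_self else set()
        stack = list(self.classes[cid].parent_ids)
        while stack:
            cur = stack.pop()
            if cur not in out:
                out.add(cur)
                stack.extend(self.classes[cur].parent_ids)
        return out

    def descendants(self, cid: str, include_self: bool = True) -> set[str]:
        children: dict[str, list[str]] = {}
        for cls in self.classes.values():
            for pid in cls.parent_ids:
                children.setdefault(pid, []).append(cls.id)
        out: set[str] = {cid} if include_self else set()
        stack = children.get(cid, [])[:]
        while stack:
            cur = stack.pop()
            if cur not in out:
                out.add(cur)
                stack.extend(children.get(cur, []))
        return out


# -- serialization ------------------------------------------------------


def _format_label(term: str, lang: str) -> str:
    return f"{term}@{lang}"


def _parse_label(raw: object, context: str) -> tuple[str, str]:
    if not isinstance(raw, str) or "@" not in raw:
        raise OntologyParseError(f"{context}: label must be 'term@lang', got {raw!r}")
    term, _, lang = raw.rpartition("@")
    if not term or not lang:
        raise OntologyParseError(f"{context}: label must be 'term@lang', got {raw!r}")
    return term, lang


def ontology_to_dict(onto: Ontology) -> dict:
    """Canonical plain-data form (sorted everywhere) used by the YAML writer."""
    return {
        "classes": [
            {
                "id": cls.id,
                "parents": sorted(cls.parent_ids),
                "labels": sorted(_format_label(t, l) for t, l in cls.labels),
            }
            for cls in sorted(onto.classes.values(), key=lambda c: c.id)
        ],
        "properties": [
            {"id": p.id, "domain": p.domain_id, "ranges": sorted(p.range_ids)}
            for p in sorted(onto.properties.values(), key=lambda p: p.id)
        ],
        "chains": sorted([c.lhs[0], c.lhs[1], c.rhs] for c in onto.chains),
        "assertions": sorted(
            [a.subject_id, a.property_id, a.filler_id] for a in onto.assertions
        ),
    }


def ontology_from_dict(data: Mapping) -> Ontology:
    if not isinstance(data, Mapping):
        raise OntologyParseError("ontology document must be a mapping with a 'classes' section")
    classes = []
    for i, rec in enumerate(data.get("classes") or []):
        ctx = f"classes[{i}]"
        if not isinstance(rec, Mapping) or "id" not in rec:
            raise OntologyParseError(f"{ctx}: expected a mapping with an 'id' field")
        labels = tuple(_parse_label(raw, ctx) for raw in rec.get("labels") or [])
        classes.append(
            OntologyClass(
                id=str(rec["id"]),
                parent_ids=tuple(str(p) for p in rec.get("parents") or []),
                labels=labels,
            )
        )
    properties = []
    for i, rec in enumerate(data.get("properties") or []):
        ctx = f"properties[{i}]"
        if not isinstance(rec, Mapping) or "id" not in rec or "domain" not in rec:
            raise OntologyParseError(f"{ctx}: expected mapping with 'id', 'domain', 'ranges'")
        properties.append(
            ObjectProperty(
                id=str(rec["id"]),
                domain_id=str(rec["domain"]),
                range_ids=tuple(str(r) for r in rec.get("ranges") or []),
            )
        )
    chains = []
    for i, rec in enumerate(data.get("chains") or []):
        if not isinstance(rec, Sequence) or isinstance(rec, str) or len(rec) != 3:
            raise OntologyParseError(
                f"chains[{i}]: expected [p1, p2, rhs] (chains longer than two are not supported)"
            )
        chains.append(PropertyChain(lhs=(str(rec[0]), str(rec[1])), rhs=str(rec[2])))
    assertions = []
    for i, rec in enumerate(data.get("assertions") or []):
        if not isinstance(rec, Sequence) or isinstance(rec, str) or len(rec) != 3:
            raise OntologyParseError(f"assertions[{i}]: expected [subject, property, filler]")
        assertions.append(
            Assertion(subject_id=str(rec[0]), property_id=str(rec[1]), filler_id=str(rec[2]))
        )
    return Ontology(classes, properties, chains, assertions)


def load_ontology(path: Union[str, Path]) -> Ontology:
    """Load and validate an ontology from its canonical YAML form."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise OntologyParseError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return ontology_from_dict(data or {})
    except OntologyParseError as exc:
        raise OntologyParseError(f"{path}: {exc}") from exc


def save_ontology(onto: Ontology, path: Union[str, Path]) -> None:
    """Write the canonical (sorted, hence byte-stable) YAML serialization."""
    buf = io.StringIO()
    yaml.safe_dump(ontology_to_dict(onto), buf, sort_keys=False, allow_unicode=True)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# -- OWL2 functional-syntax export (interoperability only) ---------------

_OWL_PREFIX = "https://example.org/vaxalign#"


def _iri(local: str) -> str:
    return ":" + local.replace(" ", "_")


def export_owl_functional(onto: Ontology) -> str:
    """Render the ontology as OWL2 functional syntax.

    Subclass axioms, SubObjectPropertyOf chains, existential assertions, and
    rdfs:label annotations with language tags are emitted.  Import of arbitrary
    OWL is deliberately not supported.
    """
    lines = [
        f"Prefix(:=<{_OWL_PREFIX}>)",
        "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
        f"Ontology(<{_OWL_PREFIX.rstrip('#')}>",
    ]
    for cls in sorted(onto.classes.values(), key=lambda c: c.id):
        lines.append(f"Declaration(Class({_iri(cls.id)}))")
    for prop in sorted(onto.properties.values(), key=lambda p: p.id):
        lines.append(f"Declaration(ObjectProperty({_iri(prop.id)}))")
    for cls in sorted(onto.classes.values(), key=lambda c: c.id):
        for pid in sorted(cls.parent_ids):
            lines.append(f"SubClassOf({_iri(cls.id)} {_iri(pid)})")
        for term, lang in sorted(cls.labels):
            lines.append(
                f'AnnotationAssertion(rdfs:label {_iri(cls.id)} "{term}"@{lang})'
            )
    for prop in sorted(onto.properties.values(), key=lambda p: p.id):
        lines.append(f"ObjectPropertyDomain({_iri(prop.id)} {_iri(prop.domain_id)})")
        if len(prop.range_ids) == 1:
            rng = _iri(prop.range_ids[0])
        else:
            rng = "ObjectUnionOf(" + " ".join(_iri(r) for r in sorted(prop.range_ids)) + ")"
        lines.append(f"ObjectPropertyRange({_iri(prop.id)} {rng})")
    for chain in sorted(onto.chains, key=lambda c: (c.lhs, c.rhs)):
        lines.append(
            "SubObjectPropertyOf(ObjectPropertyChain("
            + " ".join(_iri(p) for p in chain.lhs)
            + f") {_iri(chain.rhs)})"
        )
    for a in sorted(onto.assertions, key=lambda a: (a.subject_id, a.property_id, a.filler_id)):
        lines.append(
            f"SubClassOf({_iri(a.subject_id)} "
            f"ObjectSomeValuesFrom({_iri(a.property_id)} {_iri(a.filler_id)}))"
        )
    lines.append(")")
    return "\n".join(lines) + "\n"
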