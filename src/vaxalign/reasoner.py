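"""Subsumption reasoning for the EL-with-chains fragment.

:func:`classify` computes, once, the deductive closure of an ontology over
named classes: the subclass relation and every entailed existential triple
``A SubClassOf (p some B)``.  The closure is the least fixpoint of

  (i)   reflexivity and transitivity of the subclass relation,
  (ii)  inheritance of existential axioms along the subclass relation,
  (iii) filler generalization (from ``A ⊑ ∃p.B`` and ``B ⊑ B'`` infer
        ``A ⊑ ∃p.B'``), and
  (iv)  binary property chains (from ``A ⊑ ∃p1.B``, ``B ⊑ ∃p2.C`` and
        ``p1∘p2 ⇒ p`` infer ``A ⊑ ∃p.C``),

computed with an indexed worklist.  Compound expressions are handled by
internalization: each conjunction/existential tree is given a fresh named
class axiomatized by its conjuncts, the closure is recomputed, and queries
against the compound reduce to structural checks on the closure.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import UnknownIdentifierError, ValidationError
from .expressions import (
    And,
    ClassExpression,
    ExpressionLike,
    Named,
    Some,
    as_expression,
    conjuncts,
)
from .ontology import FUNDAMENTAL_ROOTS, Ontology, VACCINE_ROOT

Edge = Tuple[str, str]  # (child, parent)
Triple = Tuple[str, str, str]  # (subject, property, filler)


class SubsumptionIndex:
    """Queryable closure over named classes and existential entailments."""

    def __init__(
        self,
        ontology: Ontology,
        extra_class_ids: Sequence[str] = (),
        extra_edges: Sequence[Edge] = (),
        extra_assertions: Sequence[Triple] = (),
    ):
        self.ontology = ontology
        self._extra_class_ids = tuple(extra_class_ids)
        self._extra_edges = tuple(extra_edges)
        self._extra_assertions = tuple(extra_assertions)
        self._class_ids = set(ontology.classes) | set(extra_class_ids)
        self._compute_closure()

    # -- closure --------------------------------------------------------

    def _compute_closure(self) -> None:
        parents: dict[str, set[str]] = {cid: set() for cid in self._class_ids}
        for cls in self.ontology.classes.values():
            parents[cls.id].update(cls.parent_ids)
        for child, parent in self._extra_edges:
            parents[child].add(parent)

        # reflexive-transitive closure of the parent relation
        up: dict[str, frozenset[str]] = {}

        def ancestors(cid: str) -> frozenset[str]:
            cached = up.get(cid)
            if cached is not None:
                return cached
            out = {cid}
            for pid in parents[cid]:
                out.update(ancestors(pid))
            up[cid] = frozenset(out)
            return up[cid]

        for cid in self._class_ids:
            ancestors(cid)
        down: dict[str, set[str]] = {cid: set() for cid in self._class_ids}
        for cid, ancs in up.items():
            for a in ancs:
                down[a].add(cid)

        self._up = up
        self._down = down

        chains_as_first: dict[str, list[tuple[str, str]]] = {}
        chains_as_second: dict[str, list[tuple[str, str]]] = {}
        for chain in self.ontology.chains:
            p1, p2 = chain.lhs
            chains_as_first.setdefault(p1, []).append((p2, chain.rhs))
            chains_as_second.setdefault(p2, []).append((p1, chain.rhs))

        triples: set[Triple] = set()
        by_subject: dict[tuple[str, str], set[str]] = {}
        by_filler: dict[tuple[str, str], set[str]] = {}
        queue: deque[Triple] = deque()

        def add(a: str, p: str, b: str) -> None:
            t = (a, p, b)
            if t not in triples:
                triples.add(t)
                by_subject.setdefault((p, a), set()).add(b)
                by_filler.setdefault((p, b), set()).add(a)
                queue.append(t)

        for a in self.ontology.assertions:
            add(a.subject_id, a.property_id, a.filler_id)
        for s, p, f in self._extra_assertions:
            add(s, p, f)

        while queue:
            a, p, b = queue.popleft()
            for d in down[a]:  # (ii) inheritance to subclasses of the subject
                add(d, p, b)
            for b2 in up[b]:  # (iii) filler generalization
                add(a, p, b2)
            for p2, rhs in chains_as_first.get(p, ()):  # (iv) as left premise
                for c in by_subject.get((p2, b), ()):
                    add(a, rhs, c)
            for p1, rhs in chains_as_second.get(p, ()):  # (iv) as right premise
                for x in by_filler.get((p1, a), ()):
                    add(x, rhs, b)

        self._triples = triples
        self._by_subject = by_subject

    # -- queries --------------------------------------------------------

    def has_class(self, cid: str) -> bool:
        return cid in self._class_ids

    def is_subclass(self, a: str, b: str) -> bool:
        """Whether ``a ⊑ b`` for named classes."""
        self._require(a)
        self._require(b)
        return b in self._up[a]

    def relation_holds(self, a: str, p: str, b: str) -> bool:
        """Whether ``a ⊑ ∃p.b`` is entailed."""
        return (a, p, b) in self._triples

    def fillers(self, a: str, p: str) -> frozenset[str]:
        """All named classes ``b`` with ``a ⊑ ∃p.b``."""
        return frozenset(self._by_subject.get((p, a), ()))

    def subsumers(self, a: str) -> frozenset[str]:
        self._require(a)
        return self._up[a]

    def triples(self) -> frozenset[Triple]:
        """The full set of entailed existential triples (diagnostics/tests)."""
        return frozenset(self._triples)

    def _require(self, cid: str) -> None:
        if cid not in self._class_ids:
            raise UnknownIdentifierError(cid, kind="class")

    # -- internalization ------------------------------------------------

    def extend(self, expressions: Mapping[str, ClassExpression]) -> "SubsumptionIndex":
        """Return a new index whose closure also covers the given compounds.

        Each entry names a fresh class axiomatized to be subsumed by exactly
        the expression's conjuncts; queries about the expression become
        queries about the fresh name.
        """
        extra_ids = list(self._extra_class_ids)
        extra_edges = list(self._extra_edges)
        extra_assertions = list(self._extra_assertions)
        counter = [len(extra_ids)]

        def fresh() -> str:
            counter[0] += 1
            return f"__x{counter[0]}"

        def axiomatize(name: str, expr: ClassExpression) -> None:
            for op in conjuncts(expr):
                if isinstance(op, Named):
                    if op.id not in self._class_ids and op.id not in extra_ids:
                        raise UnknownIdentifierError(op.id, kind="class")
                    extra_edges.append((name, op.id))
                elif isinstance(op, Some):
                    if op.prop not in self.ontology.properties:
                        raise UnknownIdentifierError(op.prop, kind="property")
                    extra_assertions.append((name, op.prop, intern(op.filler)))
                else:  # nested And unreachable via conjuncts, defensive
                    extra_edges.append((name, intern(op)))

        def intern(expr: ClassExpression) -> str:
            if isinstance(expr, Named):
                if expr.id not in self._class_ids and expr.id not in extra_ids:
                    raise UnknownIdentifierError(expr.id, kind="class")
                return expr.id
            name = fresh()
            extra_ids.append(name)
            axiomatize(name, expr)
            return name

        for name, expr in expressions.items():
            if name in self._class_ids or name in extra_ids:
                raise ValidationError(f"expression name collides with existing class: {name!r}")
            extra_ids.append(name)
            axiomatize(name, as_expression(expr))

        return SubsumptionIndex(
            self.ontology,
            extra_class_ids=extra_ids,
            extra_edges=extra_edges,
            extra_assertions=extra_assertions,
        )


def classify(ontology: Ontology) -> SubsumptionIndex:
    """Validate the ontology and compute its subsumption/entailment closure."""
    ontology.validate()
    return SubsumptionIndex(ontology)


def _holds(index: SubsumptionIndex, subject: str, expr: ClassExpression) -> bool:
    """Structural check of ``subject ⊑ expr`` against the closure."""
    if isinstance(expr, Named):
        return index.is_subclass(subject, expr.id)
    if isinstance(expr, And):
        return all(_holds(index, subject, op) for op in expr.operands)
    if isinstance(expr, Some):
        if expr.prop not in index.ontology.properties:
            raise UnknownIdentifierError(expr.prop, kind="property")
        return any(_holds(index, c, expr.filler) for c in index.fillers(subject, expr.prop))
    raise TypeError(f"not a class expression: {expr!r}")


def is_subsumed(index: SubsumptionIndex, a: ExpressionLike, b: ExpressionLike) -> bool:
    """Whether the ontology entails ``a ⊑ b`` for arbitrary EL expressions."""
    a = as_expression(a)
    b = as_expression(b)
    if isinstance(a, Named):
        idx, sid = index, a.id
        idx._require(sid)
    else:
        idx = index.extend({"__lhs": a})
        sid = "__lhs"
    return _holds(idx, sid, b)


def equivalent(index: SubsumptionIndex, a: ExpressionLike, b: ExpressionLike) -> bool:
    """Mutual subsumption of two expressions."""
    return is_subsumed(index, a, b) and is_subsumed(index, b, a)


def entailed_fillers(
    index: SubsumptionIndex,
    expr: ExpressionLike,
    p: str,
    exclude_roots: bool = True,
    subject_id: Optional[str] = None,
) -> frozenset[str]:
    """All named classes ``c`` under ``range(p)`` with ``expr ⊑ Vaccine ⊓ ∃p.c``.

    ``subject_id`` lets callers that batch-internalized many expressions pass
    the fresh name directly and skip re-internalization.
    """
    onto = index.ontology
    if p not in onto.properties:
        raise UnknownIdentifierError(p, kind="property")
    if subject_id is None:
        expr = as_expression(expr)
        if isinstance(expr, Named):
            idx, sid = index, expr.id
            idx._require(sid)
        else:
            idx = index.extend({"__q": expr})
            sid = "__q"
    else:
        idx, sid = index, subject_id
    if not idx.is_subclass(sid, VACCINE_ROOT):
        return frozenset()
    candidates: set[str] = set()
    for rid in onto.properties[p].range_ids:
        candidates.update(onto.descendants(rid))
    out = idx.fillers(sid, p) & candidates
    if exclude_roots:
        out = out - set(FUNDAMENTAL_ROOTS)
    return frozenset(out)
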