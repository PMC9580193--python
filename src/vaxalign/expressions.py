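"""Class expressions of the EL description-logic fragment.

The only connectives needed to describe vaccines are conjunction and
existential restriction over named classes, e.g.::

    Vaccine and (immunizes-against some Influenza) and (has-strategy some Attenuated)

Expressions are immutable and compare structurally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Union


class ClassExpression:
    """Base class; concrete nodes are :class:`Named`, :class:`Some`, :class:`And`."""

    __slots__ = ()


@dataclass(frozen=True)
class Named(ClassExpression):
    """Reference to a named ontology class."""

    id: str


@dataclass(frozen=True)
class Some(ClassExpression):
    """Existential restriction ``prop some filler``."""

    prop: str
    filler: "ClassExpression"


@dataclass(frozen=True)
class And(ClassExpression):
    """Conjunction of two or more operands."""

    operands: tuple[ClassExpression, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("conjunction requires at least two operands")


def conjunction(operands: Iterable[ClassExpression]) -> ClassExpression:
    """Build a conjunction, flattening nested And nodes and dropping duplicates.

    A single remaining operand is returned as-is (a one-element conjunction is
    just its operand); an empty iterable is an error — the caller decides what
    the empty case means.
    """
    flat: list[ClassExpression] = []
    seen: set[ClassExpression] = set()
    for op in _iter_flat(operands):
        if op not in seen:
            seen.add(op)
            flat.append(op)
    if not flat:
        raise ValueError("empty conjunction has no canonical meaning here")
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def _iter_flat(operands: Iterable[ClassExpression]) -> Iterator[ClassExpression]:
    for op in operands:
        if isinstance(op, And):
            yield from _iter_flat(op.operands)
        else:
            yield op


def conjuncts(expr: ClassExpression) -> tuple[ClassExpression, ...]:
    """Top-level conjuncts of an expression (itself, if not a conjunction)."""
    if isinstance(expr, And):
        return expr.operands
    return (expr,)


def named_ids(expr: ClassExpression) -> set[str]:
    """All named-class identifiers mentioned anywhere in the expression."""
    out: set[str] = set()
    _collect(expr, out)
    return out


def _collect(expr: ClassExpression, out: set[str]) -> None:
    if isinstance(expr, Named):
        out.add(expr.id)
    elif isinstance(expr, Some):
        _collect(expr.filler, out)
    elif isinstance(expr, And):
        for op in expr.operands:
            _collect(op, out)


def format_expression(expr: ClassExpression) -> str:
    """Human-readable rendering, ``A and (p some B)`` style."""
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Some):
        return f"({expr.prop} some {format_expression(expr.filler)})"
    if isinstance(expr, And):
        return " and ".join(format_expression(op) for op in expr.operands)
    raise TypeError(f"not a class expression: {expr!r}")


ExpressionLike = Union[str, ClassExpression]


def as_expression(value: ExpressionLike) -> ClassExpression:
    """Coerce a bare class id to a :class:`Named` node."""
    if isinstance(value, ClassExpression):
        return value
    return Named(value)
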