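"""Alignment of a source coding system to a target coding system.

Four similarity methods are built in:

* ``tokens`` — Jaccard coefficient of the normalized descriptor token sets
  (a lexical baseline, blind to the ontology);
* ``classes`` — Jaccard coefficient of the sets of ontology classes
  identified in the two descriptors;
* ``equivalence`` — 1 if the compiled vaccine class expressions are mutually
  subsumed under the ontology, else 0;
* ``properties`` — 0 if the two immunizes-against value sets differ,
  otherwise the Jaccard coefficient of the pooled (property, filler) pairs
  of the normalized property values.

Each source code is assigned every target code attaining the maximal score,
provided that score strictly exceeds the threshold; among tied targets of a
hierarchical target system only the most general (those with no proper
ancestor inside the tie) are kept.  External concept taggers (e.g. a UMLS
tagger) can be registered as additional Jaccard-over-concept-set methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import Code, CodingSystem
from .compiler import (
    PropertyValues,
    VaccineClass,
    property_values_batch,
    vaccine_class,
)
from .errors import ConfigurationError, ValidationError
from .ontology import Ontology
from .reasoner import SubsumptionIndex, classify
from .tagger import Dictionary, build_dictionary, normalize, tag

logger = logging.getLogger(__name__)

BUILTIN_METHODS = ("tokens", "classes", "equivalence", "properties")
TARGET_PROPERTY = "immunizes-against"

#: Registered external taggers: name -> (descriptor -> set of concept ids).
_EXTERNAL_TAGGERS: dict[str, Callable[[str], set[str]]] = {}


def register_external_method(name: str, tagger: Callable[[str], set[str]]) -> None:
    """Register a similarity method backed by an external concept tagger.

    The tagger maps a descriptor to a set of opaque concept identifiers; the
    similarity of two codes is the Jaccard coefficient of their concept sets.
    """
    if name in BUILTIN_METHODS:
        raise ConfigurationError(f"cannot shadow built-in method {name!r}")
    _EXTERNAL_TAGGERS[name] = tagger


def available_methods() -> tuple[str, ...]:
    return BUILTIN_METHODS + tuple(sorted(_EXTERNAL_TAGGERS))


def jaccard(s: frozenset, t: frozenset) -> float:
    """|s ∩ t| / |s ∪ t|, defined as 0 when both sets are empty."""
    if not s and not t:
        return 0.0
    return len(s & t) / len(s | t)


@dataclass(frozen=True)
class AlignmentConfig:
    """Tunable alignment behaviour.

    ``targets_gate`` selects how the properties method reads "the
    immunizes-against values differed": ``equal`` (the default) zeroes the
    similarity unless the two sets are identical; ``overlap`` only zeroes it
    when they are disjoint.
    """

    method: str = "properties"
    threshold: float = 0.1
    languages: Optional[tuple[str, ...]] = None
    targets_gate: str = "equal"
    exclude_roots: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.targets_gate not in ("equal", "overlap"):
            raise ConfigurationError(
                f"targets_gate must be 'equal' or 'overlap', got {self.targets_gate!r}"
            )


@dataclass(frozen=True)
class Alignment:
    """Assignments of source codes to their closest target codes."""

    assignments: tuple[tuple[str, str, float], ...]
    unassigned: frozenset[str]
    method: str
    threshold: float
    source_name: str = ""
    target_name: str = ""

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((s, t) for s, t, _ in self.assignments)

    def source_codes(self) -> frozenset[str]:
        return frozenset(s for s, _, _ in self.assignments) | self.unassigned


# -- per-method similarity primitives -----------------------------------


def similarity_tokens(a: Code, b: Code) -> float:
    """Jaccard coefficient of the normalized descriptor token sets."""
    return jaccard(frozenset(normalize(a.descriptor)), frozenset(normalize(b.descriptor)))


def similarity_classes(classes_a: frozenset[str], classes_b: frozenset[str]) -> float:
    """Jaccard of identified class sets; 0 if either is empty."""
    if not classes_a or not classes_b:
        return 0.0
    return jaccard(classes_a, classes_b)


def similarity_equivalence(a: VaccineClass, b: VaccineClass, index: SubsumptionIndex) -> float:
    """1 iff the compiled expressions are mutually subsumed and both informative."""
    if a.uninformative or b.uninformative:
        return 0.0
    from .reasoner import equivalent

    return 1.0 if equivalent(index, a.expression, b.expression) else 0.0


def similarity_properties(
    a: PropertyValues, b: PropertyValues, targets_gate: str = "equal"
) -> float:
    """Gated overlap of normalized property values.

    Zero when both codes are uninformative or when the immunizes-against
    value sets "differ" under the configured gate reading; otherwise the
    Jaccard coefficient of the pooled (property, filler) pairs.
    """
    if a.uninformative and b.uninformative:
        return 0.0
    ta, tb = a[TARGET_PROPERTY], b[TARGET_PROPERTY]
    if targets_gate == "equal":
        if ta != tb:
            return 0.0
    else:  # overlap reading: gate fires only on disjoint non-identical sets
        if not (ta & tb) and (ta or tb):
            return 0.0
    return jaccard(a.pairs(), b.pairs())


# -- similarity matrices ------------------------------------------------


@dataclass
class _OntologyContext:
    ontology: Ontology
    index: SubsumptionIndex
    dictionary: Dictionary

    @classmethod
    def build(
        cls,
        ontology: Optional[Ontology],
        index: Optional[SubsumptionIndex] = None,
        dictionary: Optional[Dictionary] = None,
    ) -> "_OntologyContext":
        if ontology is None:
            raise ConfigurationError("this similarity method requires an ontology")
        return cls(
            ontology=ontology,
            index=index if index is not None else classify(ontology),
            dictionary=dictionary if dictionary is not None else build_dictionary(ontology),
        )


def _code_languages(code: Code, config: AlignmentConfig) -> Optional[tuple[str, ...]]:
    if code.language:
        return (code.language,)
    return config.languages


def _tag_codes(
    system: CodingSystem, ctx: _OntologyContext, config: AlignmentConfig
) -> dict[str, frozenset[str]]:
    return {
        c.code: tag(c.descriptor, ctx.dictionary, languages=_code_languages(c, config)).class_ids
        for c in system
    }


def _compile_codes(
    system: CodingSystem, ctx: _OntologyContext, config: AlignmentConfig
) -> dict[str, VaccineClass]:
    return {
        c.code: vaccine_class(
            c.descriptor, ctx.ontology, ctx.dictionary, languages=_code_languages(c, config)
        )
        for c in system
    }


def similarity_matrix(
    source: CodingSystem,
    target: CodingSystem,
    method: str,
    ontology: Optional[Ontology] = None,
    index: Optional[SubsumptionIndex] = None,
    dictionary: Optional[Dictionary] = None,
    config: Optional[AlignmentConfig] = None,
) -> pd.DataFrame:
    """Score every source code against every target code.

    Returns a DataFrame indexed by source codes with target codes as columns.
    """
    config = config or AlignmentConfig(method=method)
    s_codes = [c.code for c in source]
    t_codes = [c.code for c in target]
    scores = np.zeros((len(s_codes), len(t_codes)))

    if method == "tokens":
        s_tok = {c.code: frozenset(normalize(c.descriptor)) for c in source}
        t_tok = {c.code: frozenset(normalize(c.descriptor)) for c in target}
        for i, sc in enumerate(s_codes):
            for j, tc in enumerate(t_codes):
                scores[i, j] = jaccard(s_tok[sc], t_tok[tc])
    elif method in _EXTERNAL_TAGGERS:
        tagger = _EXTERNAL_TAGGERS[method]
        s_con = {c.code: frozenset(tagger(c.descriptor)) for c in source}
        t_con = {c.code: frozenset(tagger(c.descriptor)) for c in target}
        for i, sc in enumerate(s_codes):
            for j, tc in enumerate(t_codes):
                scores[i, j] = jaccard(s_con[sc], t_con[tc])
    elif method == "classes":
        ctx = _OntologyContext.build(ontology, index, dictionary)
        s_cls = _tag_codes(source, ctx, config)
        t_cls = _tag_codes(target, ctx, config)
        for i, sc in enumerate(s_codes):
            for j, tc in enumerate(t_codes):
                scores[i, j] = similarity_classes(s_cls[sc], t_cls[tc])
    elif method == "equivalence":
        ctx = _OntologyContext.build(ontology, index, dictionary)
        s_vc = _compile_codes(source, ctx, config)
        t_vc = _compile_codes(target, ctx, config)
        names = {f"__s_{i}": c for i, c in enumerate(s_codes)}
        names.update({f"__t_{j}": c for j, c in enumerate(t_codes)})
        exprs = {}
        for name, code in names.items():
            vc = s_vc[code] if name.startswith("__s_") else t_vc[code]
            exprs[name] = vc.expression
        extended = ctx.index.extend(exprs)
        t_conjuncts = {c: t_vc[c].expression for c in t_codes}
        s_conjuncts = {c: s_vc[c].expression for c in s_codes}
        from .reasoner import _holds  # structural check against the closure

        for i, sc in enumerate(s_codes):
            if s_vc[sc].uninformative:
                continue
            for j, tc in enumerate(t_codes):
                if t_vc[tc].uninformative:
                    continue
                forward = _holds(extended, f"__s_{i}", t_conjuncts[tc])
                backward = forward and _holds(extended, f"__t_{j}", s_conjuncts[sc])
                scores[i, j] = 1.0 if (forward and backward) else 0.0
    elif method == "properties":
        ctx = _OntologyContext.build(ontology, index, dictionary)
        s_vc = _compile_codes(source, ctx, config)
        t_vc = _compile_codes(target, ctx, config)
        compiled = {f"s::{c}": s_vc[c] for c in s_codes}
        compiled.update({f"t::{c}": t_vc[c] for c in t_codes})
        pv = property_values_batch(
            compiled, ctx.ontology, ctx.index, exclude_roots=config.exclude_roots
        )
        for i, sc in enumerate(s_codes):
            for j, tc in enumerate(t_codes):
                scores[i, j] = similarity_properties(
                    pv[f"s::{sc}"], pv[f"t::{tc}"], targets_gate=config.targets_gate
                )
    else:
        raise ConfigurationError(
            f"unknown similarity method {method!r}; available: {', '.join(available_methods())}"
        )

    return pd.DataFrame(scores, index=s_codes, columns=t_codes)


# -- assignment ---------------------------------------------------------


def assignment_from_matrix(
    matrix: pd.DataFrame,
    source: CodingSystem,
    target: CodingSystem,
    method: str,
    threshold: float,
) -> Alignment:
    """Turn a similarity matrix into an alignment at the given threshold.

    The comparison with the threshold is strict (``score > threshold``); ties
    at the maximum are all kept unless the target system is hierarchical, in
    which case tied targets with a proper ancestor inside the tie are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    assignments: list[tuple[str, str, float]] = []
    unassigned: set[str] = set()
    tie_events = 0
    if len(target) == 0:
        logger.warning("empty target coding system %r: every source code is unassigned", target.name)
        return Alignment(
            assignments=(),
            unassigned=frozenset(matrix.index),
            method=method,
            threshold=threshold,
            source_name=source.name,
            target_name=target.name,
        )
    for s_code in matrix.index:
        row = matrix.loc[s_code]
        best = float(row.max())
        if best > threshold:
            tied = [t for t in matrix.columns if row[t] == best]
            if len(tied) > 1:
                tie_events += 1
                if target.has_hierarchy:
                    tied_set = set(tied)
                    tied = [
                        t for t in tied if not (target.ancestors(t) & tied_set)
                    ]
            for t_code in tied:
                assignments.append((s_code, t_code, best))
        else:
            unassigned.add(s_code)
    if tie_events:
        logger.info("%d source code(s) had tied maximal targets", tie_events)
    return Alignment(
        assignments=tuple(assignments),
        unassigned=frozenset(unassigned),
        method=method,
        threshold=threshold,
        source_name=source.name,
        target_name=target.name,
    )


def align(
    source: CodingSystem,
    target: CodingSystem,
    method: str = "properties",
    threshold: float = 0.1,
    ontology: Optional[Ontology] = None,
    index: Optional[SubsumptionIndex] = None,
    dictionary: Optional[Dictionary] = None,
    config: Optional[AlignmentConfig] = None,
) -> Alignment:
    """Assign each source code to its closest target code(s)."""
    config = config or AlignmentConfig(method=method, threshold=threshold)
    matrix = similarity_matrix(
        source, target, method, ontology=ontology, index=index,
        dictionary=dictionary, config=config,
    )
    return assignment_from_matrix(matrix, source, target, method, threshold)


# -- alignment IO -------------------------------------------------------


def write_alignment(alignment: Alignment, path: Union[str, Path]) -> None:
    """TSV with one row per assignment; unassigned codes get empty target/score."""
    rows = [
        {"source_code": s, "target_code": t, "score": f"{score:.6g}",
         "method": alignment.method, "threshold": alignment.threshold}
        for s, t, score in alignment.assignments
    ]
    rows.extend(
        {"source_code": s, "target_code": "", "score": "",
         "method": alignment.method, "threshold": alignment.threshold}
        for s in sorted(alignment.unassigned)
    )
    pd.DataFrame(
        rows, columns=["source_code", "target_code", "score", "method", "threshold"]
    ).to_csv(path, sep="\t", index=False)


def read_alignment(path: Union[str, Path]) -> Alignment:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"source_code", "target_code", "score"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: alignment file must have columns {sorted(required)}")
    assignments = []
    unassigned = set()
    method = frame["method"].iloc[0] if "method" in frame.columns and len(frame) else ""
    threshold = (
        float(frame["threshold"].iloc[0])
        if "threshold" in frame.columns and len(frame) and frame["threshold"].iloc[0]
        else 0.0
    )
    for rec in frame.itertuples(index=False):
        if rec.target_code:
            assignments.append((rec.source_code, rec.target_code, float(rec.score or 0.0)))
        else:
            unassigned.add(rec.source_code)
    return Alignment(
        assignments=tuple(assignments),
        unassigned=frozenset(unassigned),
        method=method,
        threshold=threshold,
    )
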