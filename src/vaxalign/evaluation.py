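"""Evaluation of generated alignments against reference alignments.

An assignment pair is a true positive when it appears in the reference, a
false positive otherwise; reference pairs never generated are false
negatives.  Tie-expanded generated pairs count individually.  Precision,
recall, and F-score follow the usual definitions with a measure-is-zero
convention for empty denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .align import Alignment, AlignmentConfig, assignment_from_matrix, similarity_matrix
from .coding import CodingSystem
from .errors import ValidationError
from .ontology import Ontology
from .reasoner import SubsumptionIndex
from .tagger import Dictionary


@dataclass(frozen=True)
class ReferenceAlignment:
    """Manually curated pairs; each source code has at most one target."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        sources = [s for s, _ in self.pairs]
        if len(sources) != len(set(sources)):
            dupes = sorted({s for s in sources if sources.count(s) > 1})
            raise ValidationError(f"reference assigns multiple targets to source code(s) {dupes}")

    def source_codes(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs)


def read_reference(path: Union[str, Path]) -> ReferenceAlignment:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"source_code", "target_code"} <= set(frame.columns):
        raise ValidationError(f"{path}: reference must have columns source_code, target_code")
    return ReferenceAlignment(
        frozenset((r.source_code, r.target_code) for r in frame.itertuples(index=False))
    )


def write_reference(reference: ReferenceAlignment, path: Union[str, Path]) -> None:
    pd.DataFrame(
        sorted(reference.pairs), columns=["source_code", "target_code"]
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvaluationResult":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        return cls(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_score=f)


def confusion(generated: Alignment, reference: ReferenceAlignment) -> tuple[int, int, int]:
    """(TP, FP, FN) of a generated alignment against the reference."""
    missing = reference.source_codes() - generated.source_codes()
    if missing:
        raise ValidationError(
            "reference mentions source codes absent from the alignment: "
            + ", ".join(sorted(missing)[:10])
        )
    gen = generated.pairs()
    ref = reference.pairs
    tp = len(gen & ref)
    fp = len(gen - ref)
    fn = len(ref - gen)
    return tp, fp, fn


def evaluate(generated: Alignment, reference: ReferenceAlignment) -> EvaluationResult:
    return EvaluationResult.from_counts(*confusion(generated, reference))


@dataclass(frozen=True)
class AveragedResult:
    precision: float
    recall: float
    f_score: float


def macro_average(results: Sequence[EvaluationResult]) -> AveragedResult:
    """Unweighted mean of each measure over source coding systems."""
    if not results:
        raise ValueError("macro average of an empty result list")
    n = len(results)
    return AveragedResult(
        precision=sum(r.precision for r in results) / n,
        recall=sum(r.recall for r in results) / n,
        f_score=sum(r.f_score for r in results) / n,
    )


def micro_average(confusions: Sequence[tuple[int, int, int]]) -> EvaluationResult:
    """Pool the counts, then compute the measures."""
    if not confusions:
        raise ValueError("micro average of an empty confusion list")
    tp = sum(c[0] for c in confusions)
    fp = sum(c[1] for c in confusions)
    fn = sum(c[2] for c in confusions)
    return EvaluationResult.from_counts(tp, fp, fn)


DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(11))


def threshold_sweep(
    source: CodingSystem,
    target: CodingSystem,
    reference: ReferenceAlignment,
    method: str,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    ontology: Optional[Ontology] = None,
    index: Optional[SubsumptionIndex] = None,
    dictionary: Optional[Dictionary] = None,
    config: Optional[AlignmentConfig] = None,
) -> pd.DataFrame:
    """Evaluate one alignment per threshold, reusing one similarity matrix."""
    matrix = similarity_matrix(
        source, target, method, ontology=ontology, index=index,
        dictionary=dictionary, config=config,
    )
    rows = []
    for theta in thresholds:
        alignment = assignment_from_matrix(matrix, source, target, method, float(theta))
        result = evaluate(alignment, reference)
        rows.append(
            {
                "threshold": float(theta),
                "tp": result.tp,
                "fp": result.fp,
                "fn": result.fn,
                "precision": result.precision,
                "recall": result.recall,
                "f_score": result.f_score,
            }
        )
    return pd.DataFrame(rows)
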