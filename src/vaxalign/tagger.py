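"""Dictionary-based identification of ontology classes in free text.

Every (term, language) label on an ontology class becomes a dictionary entry;
tagging a descriptor is a greedy longest-match, left-to-right, non-overlapping
scan over its normalized tokens.  The set of classes a text refers to is the
basis of all downstream representations.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .ontology import FUNDAMENTAL_ROOTS, Ontology

logger = logging.getLogger(__name__)

_SPLIT = re.compile(r"[^0-9a-z]+")


def normalize(text: str) -> list[str]:
    """Lower-cased, accent-folded tokens split on non-alphanumeric characters.

    Digits are preserved ('3-valent' becomes ['3', 'valent']); empty tokens
    are dropped.
    """
    folded = unicodedata.normalize("NFKD", text)
    folded = "".join(ch for ch in folded if not unicodedata.combining(ch))
    return [tok for tok in _SPLIT.split(folded.casefold()) if tok]


@dataclass(frozen=True)
class DictionaryEntry:
    """One normalized term pointing at one class in one language."""

    normalized_term: tuple[str, ...]
    class_id: str
    language: str


@dataclass(frozen=True)
class TagResult:
    """Classes identified in a text, with matched spans for diagnostics."""

    class_ids: frozenset[str]
    spans: tuple[tuple[int, int, str], ...]  # (start-token, end-token-exclusive, class)


class Dictionary:
    """The ontology dictionary: normalized terms indexed for longest-match scans."""

    def __init__(self, entries: Iterable[DictionaryEntry]):
        self.entries: dict[tuple[str, ...], list[DictionaryEntry]] = {}
        for entry in entries:
            if not entry.normalized_term:
                raise ValueError("dictionary entry with empty normalized term")
            self.entries.setdefault(entry.normalized_term, []).append(entry)
        self.max_term_length = max((len(t) for t in self.entries), default=0)
        self.languages = frozenset(e.language for es in self.entries.values() for e in es)

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_dictionary(ontology: Ontology) -> Dictionary:
    """One entry per (label, language) pair across all classes.

    Distinct classes sharing a normalized term are all retained (a match
    yields every associated class); each such ambiguity is logged.
    """
    entries: list[DictionaryEntry] = []
    for cls in ontology.classes.values():
        for term, lang in cls.labels:
            tokens = tuple(normalize(term))
            if not tokens:
                logger.warning("label %r on class %r normalizes to nothing; skipped", term, cls.id)
                continue
            entries.append(DictionaryEntry(tokens, cls.id, lang))
    dictionary = Dictionary(entries)
    for term, es in dictionary.entries.items():
        classes = {e.class_id for e in es}
        if len(classes) > 1:
            logger.warning(
                "ambiguous term %r maps to multiple classes: %s",
                " ".join(term),
                ", ".join(sorted(classes)),
            )
    return dictionary


def tag(
    text: str,
    dictionary: Dictionary,
    languages: Optional[Iterable[str]] = None,
    drop_roots: bool = True,
) -> TagResult:
    """Identify ontology classes referenced in ``text``.

    Greedy longest-match, left-to-right, non-overlapping scan restricted to
    the requested languages (all languages when unset).  Matches of the seven
    fundamental root classes (e.g. the bare word "vaccine") are dropped by
    default: the compilation step adds the vaccine root implicitly and root
    matches carry no discriminating information.
    """
    lang_filter = frozenset(languages) if languages is not None else None
    tokens = normalize(text)
    spans: list[tuple[int, int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(dictionary.max_term_length, n - i), 0, -1):
            candidate = tuple(tokens[i : i + length])
            entries = dictionary.entries.get(candidate)
            if not entries:
                continue
            if lang_filter is not None:
                entries = [e for e in entries if e.language in lang_filter]
                if not entries:
                    continue
            for class_id in sorted({e.class_id for e in entries}):
                if drop_roots and class_id in FUNDAMENTAL_ROOTS:
                    continue
                spans.append((i, i + length, class_id))
            i += length
            matched = True
            break
        if not matched:
            i += 1
    return TagResult(
        class_ids=frozenset(cid for _, _, cid in spans),
        spans=tuple(spans),
    )
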