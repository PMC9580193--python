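"""Coding systems: codes with free-text descriptors and optional hierarchy.

On disk a coding system is a delimited UTF-8 table (TSV or CSV by extension)
with a header row and columns ``code, descriptor[, parent][, language]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class Code:
    code: str
    descriptor: str
    language: Optional[str] = None
    parent: Optional[str] = None


class CodingSystem:
    """An ordered collection of codes, unique by identifier."""

    def __init__(self, name: str, codes: Iterable[Code]):
        self.name = name
        self.codes: dict[str, Code] = {}
        for code in codes:
            if code.code in self.codes:
                raise ValidationError(f"{name}: duplicate code {code.code!r}")
            self.codes[code.code] = code
        for code in self.codes.values():
            if code.parent is not None and code.parent not in self.codes:
                raise ValidationError(
                    f"{name}: code {code.code!r} references unknown parent {code.parent!r}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in self.codes:
            seen = set()
            cur: Optional[str] = start
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"{self.name}: cycle in parent links at {cur!r}")
                seen.add(cur)
                cur = self.codes[cur].parent

    @property
    def has_hierarchy(self) -> bool:
        return any(c.parent is not None for c in self.codes.values())

    def ancestors(self, code: str, include_self: bool = False) -> set[str]:
        """Proper ancestors of a code via parent links (optionally inclusive)."""
        if code not in self.codes:
            raise ValidationError(f"{self.name}: unknown code {code!r}")
        out: set[str] = {code} if include_self else set()
        cur = self.codes[code].parent
        while cur is not None:
            out.add(cur)
            cur = self.codes[cur].parent
        return out

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes.values())


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_coding_system(path: Union[str, Path], name: Optional[str] = None) -> CodingSystem:
    """Read a coding system from a delimited table; header row required."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ValidationError(f"{path}: cannot parse coding system table: {exc}") from exc
    missing = {"code", "descriptor"} - set(frame.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            "header row 'code<TAB>descriptor[...]' is required"
        )
    codes = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        rec = row._asdict()
        code = rec["code"].strip()
        if not code:
            raise ValidationError(f"{path}: line {row_number}: empty code")
        codes.append(
            Code(
                code=code,
                descriptor=rec["descriptor"],
                language=(rec.get("language") or "").strip() or None,
                parent=(rec.get("parent") or "").strip() or None,
            )
        )
    return CodingSystem(name or path.stem, codes)


def write_coding_system(system: CodingSystem, path: Union[str, Path]) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "code": c.code,
                "descriptor": c.descriptor,
                "parent": c.parent or "",
                "language": c.language or "",
            }
            for c in system
        ],
        columns=["code", "descriptor", "parent", "language"],
    )
    frame.to_csv(path, sep=_sep_for(path), index=False)
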