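"""Signature-motif scanning and fingerprint-fraction scoring.

Patterns use a PROSITE-style grammar: elements joined by ``-``, where an
element is a residue literal, an alternation ``[ST]``, an exclusion
``{P}``, or the wildcard ``x``, optionally repeated with ``(n)`` or
``(n,m)``.  A motif is present when the compiled matcher hits at least
once; a family fingerprint is scored as the fraction of its motifs found.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .genome import SequenceRecord


class MotifError(ValueError):
    pass


_ELEMENT = re.compile(
    r"""
    (?P<body>
        [A-Za-z]            # literal residue or x wildcard
      | \[[A-Za-z]+\]       # alternation
      | \{[A-Za-z]+\}       # exclusion
    )
    (?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?   # optional repeat count/range
    $
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class MotifPattern:
    id: str
    family: str
    pattern: str
    regex: re.Pattern

    def find(self, residues: str) -> int | None:
        """Leftmost match position (1-based) or None."""
        m = self.regex.search(residues.upper())
        return m.start() + 1 if m else None


def compile_motif(pattern: str, motif_id: str = "", family: str = "") -> MotifPattern:
    """Compile a PROSITE-style pattern into a matcher.

    >>> compile_motif("G-Y-G").find("AAGYGA")
    3
    >>> compile_motif("[ST]-x(2)-D").find("TQLD")
    1
    """
    text = pattern.strip().rstrip(".")
    if not text:
        raise MotifError("empty pattern")
    parts = text.split("-")
    pieces: list[str] = []
    for part in parts:
        m = _ELEMENT.match(part.strip())
        if m is None:
            raise MotifError(f"bad pattern element {part!r} in {pattern!r}")
        body = m.group("body")
        if body.lower() == "x":
            piece = "."
        elif body.startswith("["):
            piece = "[" + body[1:-1].upper() + "]"
        elif body.startswith("{"):
            piece = "[^" + body[1:-1].upper() + "]"
        else:
            piece = re.escape(body.upper())
        lo, hi = m.group("lo"), m.group("hi")
        if lo is not None:
            piece += f"{{{lo},{hi}}}" if hi is not None else f"{{{lo}}}"
        pieces.append(piece)
    return MotifPattern(
        id=motif_id or text, family=family, pattern=pattern,
        regex=re.compile("".join(pieces)),
    )


def load_motifs(path: str | Path) -> list[MotifPattern]:
    """Read a motif TSV (id, family, pattern)."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "id\t")):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise MotifError(f"{path}:{lineno}: expected 3 columns")
        motif_id, family, pattern = parts
        patterns.append(compile_motif(pattern, motif_id=motif_id, family=family))
    return patterns


@dataclass(frozen=True)
class FingerprintResult:
    protein_id: str
    family: str
    hits: tuple[tuple[str, bool, int | None], ...]  # (motif id, present, position)
    present: int
    total: int

    @property
    def fraction(self) -> str:
        return f"{self.present}/{self.total}"


def scan_motifs(
    protein: SequenceRecord, patterns: Sequence[MotifPattern]
) -> FingerprintResult:
    """Scan one protein against a motif set; each motif hits at most once."""
    if protein.alphabet != "protein":
        raise MotifError("motif scanning requires a protein sequence")
    hits = []
    for pat in patterns:
        pos = pat.find(protein.residues)
        hits.append((pat.id, pos is not None, pos))
    families = {p.family for p in patterns if p.family}
    family = families.pop() if len(families) == 1 else ",".join(sorted(families))
    return FingerprintResult(
        protein_id=protein.id,
        family=family,
        hits=tuple(hits),
        present=sum(1 for _, ok, _ in hits if ok),
        total=len(hits),
    )


def results_to_tsv(results: Sequence[FingerprintResult]) -> str:
    lines = ["protein\tfamily\tpresent\ttotal\thit_positions"]
    for res in results:
        positions = ";".join(
            f"{mid}:{pos if pos is not None else '-'}" for mid, _, pos in res.hits
        )
        lines.append(
            f"{res.protein_id}\t{res.family}\t{res.present}\t{res.total}\t{positions}"
        )
    return "\n".join(lines) + "\n"
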