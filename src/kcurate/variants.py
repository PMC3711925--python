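"""Allelic-variant calling, substitution classing and indel detection.

Substitutions between a primary locus and a near-identical secondary hit
are classified as synonymous, conservative (same side-chain group), or
non-conservative.  Calls are restricted to high-quality, high-identity
alignments whose placement (unplaced scaffold or gap-flanked interval)
is consistent with an allele rather than a duplication.  Indels between
ortholog pairs are reported as maximal gap runs in a codon alignment,
with domain overlap and quality flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .homology import SIDE_CHAIN_GROUPS, AlignmentResult
from .selection import CODON_TABLE, STOP_CODONS

PHRED_THRESHOLD = 50  # per-base minimum inside analyzable regions


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class DomainAnnotation:
    """Functional-domain intervals on one protein (1-based inclusive)."""

    protein: str
    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if start < 1 or end < start:
                raise VariantError(
                    f"{self.protein}: bad domain interval {start}-{end} ({label})"
                )

    def label_at(self, position: int) -> str:
        for start, end, label in self.intervals:
            if start <= position <= end:
                return label
        return "none"


def load_domains(path: str | Path) -> dict[str, DomainAnnotation]:
    """Read a 4-column TSV (protein, start, end, label) of domain intervals."""
    by_protein: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("protein\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise VariantError(f"{path}:{lineno}: expected 4 columns")
        protein, start, end, label = parts
        by_protein.setdefault(protein, []).append((int(start), int(end), label))
    return {
        p: DomainAnnotation(protein=p, intervals=tuple(sorted(iv)))
        for p, iv in by_protein.items()
    }


@dataclass(frozen=True)
class SubstitutionRecord:
    position: int  # 1-based residue index in the reference protein
    ref_aa: str
    alt_aa: str
    codon_ref: Optional[str]
    codon_alt: Optional[str]
    klass: str  # synonymous | conservative | non_conservative
    domain_overlap: str = "none"


@dataclass(frozen=True)
class IndelRecord:
    kind: str  # insertion | deletion
    position: int  # residue left of the gap run, reference coordinates
    residues: str
    lineage: str
    domain_overlap: str = "none"
    quality_ok: bool = True
    frame_ok: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise VariantError(f"bad indel kind {self.kind!r}")
        if not self.residues:
            raise VariantError("indel with empty residues")


def classify_substitution(
    ref_aa: str, alt_aa: str,
    groups: Sequence[frozenset[str]] = SIDE_CHAIN_GROUPS,
) -> str:
    """identical / conservative / non_conservative for one residue pair.

    Conservative means the two residues share a side-chain group; the
    relation is symmetric by construction.
    """
    ref_aa, alt_aa = ref_aa.upper(), alt_aa.upper()
    known = set().union(*groups)
    for aa in (ref_aa, alt_aa):
        if aa not in known:
            raise VariantError(f"unknown amino-acid code {aa!r}")
    if ref_aa == alt_aa:
        return "identical"
    if any(ref_aa in g and alt_aa in g for g in groups):
        return "conservative"
    return "non_conservative"


def quality_mask(
    aligned_a: str,
    aligned_b: str,
    quals_a: Optional[Sequence[int]] = None,
    quals_b: Optional[Sequence[int]] = None,
    gap_intervals_a: Sequence[tuple[int, int]] = (),
    gap_intervals_b: Sequence[tuple[int, int]] = (),
    threshold: int = PHRED_THRESHOLD,
) -> tuple[bool, ...]:
    """Per-column analyzability mask for a gapped alignment pair.

    A column is analyzable iff every contributing base meets the Phred
    threshold and neither contributing position falls inside a declared
    assembly-gap interval (1-based, in each sequence's ungapped
    coordinates).  Quality tracks, when given, must match the ungapped
    sequence lengths.
    """
    if len(aligned_a) != len(aligned_b):
        raise VariantError("aligned strings differ in length")
    for name, aligned, quals in (("a", aligned_a, quals_a), ("b", aligned_b, quals_b)):
        if quals is not None:
            expected = len(aligned.replace("-", ""))
            if len(quals) != expected:
                raise VariantError(
                    f"sequence {name}: {len(quals)} qualities for "
                    f"{expected} residues"
                )
    mask = []
    pos_a = pos_b = 0  # 1-based after increment
    for col_a, col_b in zip(aligned_a, aligned_b):
        ok = True
        if col_a != "-":
            pos_a += 1
            if quals_a is not None and quals_a[pos_a - 1] < threshold:
                ok = False
            if any(s <= pos_a <= e for s, e in gap_intervals_a):
                ok = False
        if col_b != "-":
            pos_b += 1
            if quals_b is not None and quals_b[pos_b - 1] < threshold:
                ok = False
            if any(s <= pos_b <= e for s, e in gap_intervals_b):
                ok = False
        mask.append(ok)
    return tuple(mask)


def codon_columns_ok(mask: Sequence[bool]) -> tuple[bool, ...]:
    """Collapse a per-base mask to per-codon columns (all three bases ok)."""
    if len(mask) % 3:
        raise VariantError("mask length not a multiple of 3")
    return tuple(
        mask[i] and mask[i + 1] and mask[i + 2] for i in range(0, len(mask), 3)
    )


def _translate(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE.get(codon, "X")


@dataclass(frozen=True)
class VariantCall:
    accepted: bool
    reason: str
    substitutions: tuple[SubstitutionRecord, ...] = ()
    indels: tuple[IndelRecord, ...] = ()


ALLELE_PLACEMENTS = frozenset({"unplaced", "gap_flanked"})


def call_allelic_variants(
    hit: AlignmentResult,
    placement: str,
    quals_primary: Optional[Sequence[int]] = None,
    quals_secondary: Optional[Sequence[int]] = None,
    min_identity: float = 95.0,
    phred_threshold: int = PHRED_THRESHOLD,
    domains: Optional[DomainAnnotation] = None,
    lineage: str = "secondary",
) -> VariantCall:
    """Accept or reject a secondary hit as an allele and emit its edits.

    The hit must be a codon-aware nucleotide alignment (primary coding
    sequence as query).  Acceptance requires identity >= ``min_identity``,
    a placement consistent with an allele (unplaced or gap-flanked), and
    every aligned base at or above the Phred threshold.  Differing codons
    become SubstitutionRecords; gap runs become small IndelRecords.
    Rejections carry their reason.
    """
    if hit.percent_identity < min_identity:
        return VariantCall(False, "below identity threshold")
    if placement not in ALLELE_PLACEMENTS:
        return VariantCall(False, "placement suggests duplication")
    mask = quality_mask(
        hit.aligned_query, hit.aligned_target,
        quals_primary, quals_secondary, threshold=phred_threshold,
    )
    if not all(mask):
        return VariantCall(False, "low quality sequence in aligned region")
    aq, at = hit.aligned_query.upper(), hit.aligned_target.upper()
    # pad to frame relative to the query span so codon boundaries line up
    offset = (hit.query_span[0] - 1) % 3
    subs: list[SubstitutionRecord] = []
    indels: list[IndelRecord] = []
    ref_residue = (hit.query_span[0] - 1 + offset) // 3  # residues before window
    col = offset
    while col + 3 <= len(aq):
        ca, cb = aq[col: col + 3], at[col: col + 3]
        if "-" in ca or "-" in cb:
            # delegate gap handling to a single-run indel record
            run_start = col
            while col < len(aq) and ("-" in aq[col] or "-" in at[col]):
                col += 1
            gap_a = aq[run_start:col].count("-")
            gap_b = at[run_start:col].count("-")
            kind = "insertion" if gap_a >= gap_b else "deletion"
            residues = (
                at[run_start:col].replace("-", "") if kind == "insertion"
                else aq[run_start:col].replace("-", "")
            )
            if residues:
                indels.append(
                    IndelRecord(
                        kind=kind,
                        position=max(ref_residue, 1),
                        residues=residues,
                        lineage=lineage,
                        domain_overlap=(
                            domains.label_at(max(ref_residue, 1)) if domains else "none"
                        ),
                        frame_ok=(col - run_start) % 3 == 0,
                    )
                )
            ref_residue += (col - run_start - gap_a) // 3
            continue
        ref_residue += 1
        if ca != cb:
            ref_aa, alt_aa = _translate(ca), _translate(cb)
            if ref_aa == alt_aa:
                klass = "synonymous"
            else:
                klass = classify_substitution(ref_aa, alt_aa)
                if klass == "identical":  # pragma: no cover - unreachable
                    klass = "synonymous"
            subs.append(
                SubstitutionRecord(
                    position=ref_residue,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    codon_ref=ca,
                    codon_alt=cb,
                    klass=klass,
                    domain_overlap=domains.label_at(ref_residue) if domains else "none",
                )
            )
        col += 3
    return VariantCall(True, "accepted", tuple(subs), tuple(indels))


def detect_indels(
    seq_a: str,
    seq_b: str,
    mask: Optional[Sequence[bool]] = None,
    domains: Optional[DomainAnnotation] = None,
    name_a: str = "a",
    name_b: str = "b",
) -> list[IndelRecord]:
    """Maximal gap runs in a codon alignment as IndelRecords.

    ``seq_a`` is the reference coding sequence; a gap run in ``seq_a``
    is an insertion carried by ``name_b`` (the gapless sequence), a gap
    run in ``seq_b`` a deletion in ``name_b``.  Runs overlapping masked
    columns get ``quality_ok=False``; gap lengths that break frame are
    flagged via ``frame_ok`` but still reported.  Positions and domain
    overlap are in reference-protein coordinates (the residue
    immediately left of the run).
    """
    if len(seq_a) != len(seq_b):
        raise VariantError("aligned sequences differ in length")
    if mask is not None and len(mask) != len(seq_a):
        raise VariantError("mask must cover every alignment column")
    records: list[IndelRecord] = []
    i = 0
    ref_pos = 0  # ungapped nucleotide position in seq_a
    n = len(seq_a)
    while i < n:
        if seq_a[i] == "-" or seq_b[i] == "-":
            gapped_in_a = seq_a[i] == "-"
            j = i
            if gapped_in_a:
                while j < n and seq_a[j] == "-":
                    j += 1
            else:
                while j < n and seq_b[j] == "-" and seq_a[j] != "-":
                    j += 1
            run = j - i
            segment = (seq_b if gapped_in_a else seq_a)[i:j].replace("-", "")
            kind = "insertion" if gapped_in_a else "deletion"
            lineage = name_b  # insertion carried by b; deletion missing from b
            in_frame = run % 3 == 0 and ref_pos % 3 == 0
            residue_left = ref_pos // 3  # residue count consumed so far
            if in_frame:
                residues = "".join(
                    _translate(segment[k: k + 3]) for k in range(0, len(segment), 3)
                )
            else:
                residues = segment
            quality_ok = True
            if mask is not None and any(not mask[k] for k in range(i, j)):
                quality_ok = False
            position = max(residue_left, 1)
            records.append(
                IndelRecord(
                    kind=kind,
                    position=position,
                    residues=residues,
                    lineage=lineage,
                    domain_overlap=domains.label_at(position) if domains else "none",
                    quality_ok=quality_ok,
                    frame_ok=in_frame,
                )
            )
            if not gapped_in_a:
                ref_pos += run
            i = j
        else:
            ref_pos += 1
            i += 1
    return records


def summarize_indels(records: list[IndelRecord]) -> dict:
    """Counts over quality-passing indels (quality_ok=False excluded)."""
    usable = [r for r in records if r.quality_ok]
    return {
        "total": len(usable),
        "insertions": sum(1 for r in usable if r.kind == "insertion"),
        "deletions": sum(1 for r in usable if r.kind == "deletion"),
        "in_domains": sum(1 for r in usable if r.domain_overlap != "none"),
        "excluded_low_quality": len(records) - len(usable),
    }


def variants_to_tsv(gene: str, call: VariantCall) -> str:
    """Variant report rows: gene, position, ref, alt, class, domain, reason."""
    lines = ["gene\tposition\tref\talt\tklass\tdomain_overlap\tquality_ok\treason"]
    if not call.accepted:
        lines.append(f"{gene}\t.\t.\t.\t.\t.\t.\t{call.reason}")
        return "\n".join(lines) + "\n"
    for sub in call.substitutions:
        lines.append(
            f"{gene}\t{sub.position}\t{sub.ref_aa}\t{sub.alt_aa}\t{sub.klass}\t"
            f"{sub.domain_overlap}\ttrue\taccepted"
        )
    for indel in call.indels:
        lines.append(
            f"{gene}\t{indel.position}\t{indel.kind}\t{indel.residues}\t.\t"
            f"{indel.domain_overlap}\t{'true' if indel.quality_ok else 'false'}\taccepted"
        )
    return "\n".join(lines) + "\n"
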