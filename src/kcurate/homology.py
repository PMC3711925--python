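"""Pairwise alignment and desk-scale secondary-locus search.

Local (Smith-Waterman) and global (Needleman-Wunsch) alignment with affine
gaps are delegated to Biopython's ``PairwiseAligner``; this module owns the
scoring-scheme contract, tie-breaking, identity/similarity statistics, and
the exact k-mer seed-and-extend search used to find duplicated loci and
allelic copies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome import SequenceRecord

#: Side-chain groups used for "conservative substitution" calls.
SIDE_CHAIN_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),   # aliphatic
    frozenset("FWY"),     # aromatic
    frozenset("STCNQ"),   # polar uncharged
    frozenset("KRH"),     # basic
    frozenset("DE"),      # acidic
    frozenset("G"),
    frozenset("P"),
)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters; a gap of length L costs open + extend * L."""

    matrix: Optional[str] = None  # substitution matrix name, e.g. "BLOSUM62"
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be >= 0")

    def configure(self, aligner: Align.PairwiseAligner) -> None:
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend


#: Defaults: BLOSUM62 11/1 for protein, +1/-2 with 5/2 gaps for nucleotide.
PROTEIN_SCHEME = ScoringScheme(matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0)
NUCLEOTIDE_SCHEME = ScoringScheme()

DEFAULT_SEED_SIZE = {"nucleotide": 11, "protein": 4}


@dataclass(frozen=True)
class AlignmentResult:
    aligned_query: str
    aligned_target: str
    score: float
    query_span: tuple[int, int]  # 1-based inclusive on the query
    target_span: tuple[int, int]
    percent_identity: float
    percent_similarity: float
    alphabet: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise AlignmentError("gapped strings differ in length")

    @property
    def aligned_columns(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_query, self.aligned_target)
            if a != "-" and b != "-"
        )

    def to_fasta(self, query_id: str = "query", target_id: str = "target") -> str:
        return (
            f">{query_id}\n{self.aligned_query}\n"
            f">{target_id}\n{self.aligned_target}\n"
        )


def _check_alphabets(query: SequenceRecord, target: SequenceRecord) -> str:
    if not query.residues or not target.residues:
        raise AlignmentError("cannot align empty sequences")
    if query.alphabet != target.alphabet:
        raise AlignmentError(
            f"mixed alphabets: {query.alphabet} vs {target.alphabet}"
        )
    return query.alphabet


def _column_stats(
    aligned_query: str, aligned_target: str, alphabet: str,
    conservative_groups: Sequence[frozenset[str]] = SIDE_CHAIN_GROUPS,
) -> tuple[float, float]:
    """(identity, similarity) percentages over gap-free columns."""
    identical = similar = columns = 0
    for a, b in zip(aligned_query, aligned_target):
        if a == "-" or b == "-":
            continue
        columns += 1
        if a == b:
            identical += 1
            similar += 1
        elif alphabet == "protein" and any(
            a in g and b in g for g in conservative_groups
        ):
            similar += 1
    if columns == 0:
        return 0.0, 0.0
    return 100.0 * identical / columns, 100.0 * similar / columns


def _pick_alignment(alignments, max_enumerate: int = 64):
    """Deterministic tie-break: longest alignment, then smallest query start."""
    best = None
    best_key = None
    for aln in itertools.islice(alignments, max_enumerate):
        qstart = int(aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
        key = (-aln.length, qstart)
        if best is None or key < best_key:
            best, best_key = aln, key
    return best


def _run(query: SequenceRecord, target: SequenceRecord,
         scheme: Optional[ScoringScheme], mode: str) -> AlignmentResult:
    alphabet = _check_alphabets(query, target)
    if scheme is None:
        scheme = PROTEIN_SCHEME if alphabet == "protein" else NUCLEOTIDE_SCHEME
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    scheme.configure(aligner)
    alignments = aligner.align(query.residues, target.residues)
    aln = _pick_alignment(alignments)
    if aln is None or (mode == "local" and len(aln.aligned[0]) == 0):
        # nothing aligns locally: empty alignment at score 0
        return AlignmentResult(
            aligned_query="", aligned_target="", score=0.0,
            query_span=(0, 0), target_span=(0, 0),
            percent_identity=0.0, percent_similarity=0.0, alphabet=alphabet,
        )
    aligned_query, aligned_target = str(aln[0]), str(aln[1])
    if mode == "local":
        # trim to the locally aligned window
        qblocks, tblocks = aln.aligned
        qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
        tspan = (int(tblocks[0][0]) + 1, int(tblocks[-1][1]))
    else:
        qspan = (1, len(query.residues))
        tspan = (1, len(target.residues))
    identity, similarity = _column_stats(aligned_query, aligned_target, alphabet)
    return AlignmentResult(
        aligned_query=aligned_query,
        aligned_target=aligned_target,
        score=float(aln.score),
        query_span=qspan,
        target_span=tspan,
        percent_identity=identity,
        percent_similarity=similarity,
        alphabet=alphabet,
    )


def align_local(query: SequenceRecord, target: SequenceRecord,
                scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under the scheme."""
    return _run(query, target, scheme, "local")


def align_global(query: SequenceRecord, target: SequenceRecord,
                 scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """End-to-end Needleman-Wunsch alignment; score may be negative."""
    return _run(query, target, scheme, "global")


def similarity_stats(
    alignment: AlignmentResult,
    conservative_groups: Sequence[frozenset[str]] = SIDE_CHAIN_GROUPS,
) -> tuple[float, float]:
    """(percent identity, percent similarity) for a protein alignment.

    Gap columns are excluded from the denominator; similarity adds
    same-side-chain-group columns on top of identity.
    """
    if alignment.alphabet != "protein":
        raise AlignmentError("similarity statistics require a protein alignment")
    return _column_stats(
        alignment.aligned_query, alignment.aligned_target,
        "protein", conservative_groups,
    )


def _kmers(residues: str, k: int) -> set[str]:
    return {residues[i: i + k] for i in range(len(residues) - k + 1)}


def find_secondary_loci(
    query: SequenceRecord,
    genome: dict[str, SequenceRecord],
    min_identity: float = 95.0,
    scheme: Optional[ScoringScheme] = None,
    seed_size: Optional[int] = None,
    primary: Optional[str] = None,
) -> list[tuple[str, AlignmentResult]]:
    """Seed-and-extend search for non-primary loci similar to the query.

    Loci sharing at least one exact k-mer with the query are locally
    aligned; hits with identity >= ``min_identity`` (computed over the
    aligned region, gap columns excluded) are returned sorted by score.
    The primary locus (defaults to the query id) is skipped.
    """
    if primary is None:
        primary = query.id
    if seed_size is None:
        seed_size = DEFAULT_SEED_SIZE[query.alphabet]
    query_kmers = _kmers(query.residues.upper(), seed_size)
    hits = []
    for locus, seq in genome.items():
        if locus == primary:
            continue
        if not query_kmers & _kmers(seq.residues.upper(), seed_size):
            continue
        aln = align_local(query, seq, scheme)
        if aln.percent_identity >= min_identity:
            hits.append((locus, aln))
    hits.sort(key=lambda h: (-h[1].score, h[0]))
    return hits


def hits_to_tsv(query_id: str, hits: list[tuple[str, AlignmentResult]]) -> str:
    """Tabular hit export: query, target, identity, similarity, score, spans."""
    lines = ["query\ttarget\tidentity\tsimilarity\tscore\tquery_span\ttarget_span"]
    for locus, aln in hits:
        lines.append(
            f"{query_id}\t{locus}\t{aln.percent_identity:.2f}\t"
            f"{aln.percent_similarity:.2f}\t{aln.score:g}\t"
            f"{aln.query_span[0]}-{aln.query_span[1]}\t"
            f"{aln.target_span[0]}-{aln.target_span[1]}"
        )
    return "\n".join(lines) + "\n"
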