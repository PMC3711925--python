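"""dN/dS estimation (Nei-Gojobori 1986 counting) and selection screening.

``estimate_dnds`` implements the NG86 method: expected synonymous and
nonsynonymous site counts per codon (mutations to stop codons removed from
the denominator), observed differences averaged with equal weight over all
stop-free minimal mutation paths, and Jukes-Cantor correction
``d = -(3/4) ln(1 - (4/3) p)``.  ``flag_high_dnds`` applies the two-stage
screen: flag ratios above twice the group mean, substitute quality-revised
values, then apply a fixed final cutoff (default 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Optional, Union

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
BASES = "ACGT"


class SelectionError(ValueError):
    pass


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) sites for one sense codon.

    Each of the three positions contributes 1 site, split by the fraction
    of its single-nucleotide neighbors (stop codons excluded) that are
    synonymous.  n + s = 3 for every sense codon.

    >>> ng86_site_counts("ATG")
    (3.0, 0.0)
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise SelectionError(f"stop codon {codon}")
    if codon not in CODON_TABLE:
        raise SelectionError(f"not a valid codon: {codon!r}")
    aa = CODON_TABLE[codon]
    n_sites = s_sites = 0.0
    for pos in range(3):
        syn = total = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            total += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if total == 0:
            # all three neighbors are stops: the position is inviolable;
            # count it as fully nonsynonymous (cannot happen in the
            # standard code, kept for safety)
            n_sites += 1.0
            continue
        s_sites += syn / total
        n_sites += 1.0 - syn / total
    return n_sites, s_sites


def _path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (nonsyn, syn) difference counts over stop-free paths."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid = []
    for order in permutations(diff_positions):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            valid.append((nd, sd))
    if not valid:
        # every path runs through a stop codon; fall back to counting all
        # paths, scoring stop-passing steps as nonsynonymous
        for order in permutations(diff_positions):
            current = codon_a
            nd = sd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
                if nxt in STOP_CODONS or CODON_TABLE.get(current) != CODON_TABLE.get(nxt):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            valid.append((nd, sd))
    n = len(valid)
    return sum(v[0] for v in valid) / n, sum(v[1] for v in valid) / n


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gapped, in-frame coding sequences with a codon mask.

    ``seq_a``/``seq_b`` are gapped nucleotide strings of equal length
    divisible by 3, codon-aligned (gaps come in whole-codon units for
    coding use).  ``mask`` marks analyzable codon columns; ``None`` means
    all columns are analyzable.
    """

    seq_a: str
    seq_b: str
    mask: Optional[tuple[bool, ...]] = None

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise SelectionError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise SelectionError("alignment length not a multiple of 3")
        for name, seq in (("a", self.seq_a), ("b", self.seq_b)):
            if len(seq.replace("-", "")) % 3:
                raise SelectionError(f"sequence {name}: degapped length not in frame")
        if self.mask is not None and len(self.mask) != self.codon_count:
            raise SelectionError("mask length must equal codon column count")

    @property
    def codon_count(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Analyzable codon pairs: unmasked, gap-free in both sequences."""
        pairs = []
        for i in range(self.codon_count):
            if self.mask is not None and not self.mask[i]:
                continue
            ca = self.seq_a[3 * i: 3 * i + 3].upper()
            cb = self.seq_b[3 * i: 3 * i + 3].upper()
            if "-" in ca or "-" in cb:
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise SelectionError(
                    f"stop codon in analyzable column {i + 1}: {ca}/{cb}"
                )
            pairs.append((ca, cb))
        return pairs


@dataclass(frozen=True)
class DnDsEstimate:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: Union[float, str]  # float, "undefined_dS_zero", or "not_available"


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SelectionError(f"proportion {p:.3f} >= 0.75; correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_dnds(alignment: CodonAlignment) -> DnDsEstimate:
    """NG86 dN/dS over the analyzable codon pairs of an alignment."""
    pairs = alignment.codon_pairs()
    if not pairs:
        raise SelectionError("no analyzable codon pairs")
    N = S = Nd = Sd = 0.0
    for ca, cb in pairs:
        na, sa = ng86_site_counts(ca)
        nb, sb = ng86_site_counts(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _path_differences(ca, cb)
        Nd += nd
        Sd += sd
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dN = _jukes_cantor(pN)
    dS = _jukes_cantor(pS)
    ratio: Union[float, str]
    if dS == 0.0:
        ratio = "undefined_dS_zero"
    else:
        ratio = dN / dS
    return DnDsEstimate(N, S, Nd, Sd, pN, pS, dN, dS, ratio)


# ---------------------------------------------------------------------------
# Two-stage high-dN/dS screen


@dataclass(frozen=True)
class SelectionFlag:
    stage1_mean: float
    stage1_cutoff: float
    stage1_set: frozenset[str]
    revised_mean: float
    final_cutoff: float
    two_x_revised_mean: float
    final_set: frozenset[str]
    exclusions: dict[str, str] = field(default_factory=dict)


RatioValue = Union[float, str]  # float or qualifier {"lt_0_01", "not_available"}


def _numeric(ratios: Mapping[str, RatioValue]) -> dict[str, float]:
    return {g: v for g, v in ratios.items() if isinstance(v, float)}


def flag_high_dnds(
    ratios: Mapping[str, RatioValue],
    revised: Optional[Mapping[str, float]] = None,
    final_cutoff: float = 0.1,
    stage1_factor: float = 2.0,
) -> SelectionFlag:
    """Two-stage high-selective-pressure screen.

    Stage 1 flags genes whose ratio exceeds ``stage1_factor`` times the
    mean of the numeric ratios.  Stage 2 substitutes quality-revised
    ratios where supplied, recomputes the mean, and takes the final set
    as genes with revised numeric ratio > ``final_cutoff``.  Qualifier
    values ("below detection", "not available") never enter means and are
    never flagged; 2x the revised mean is also reported for comparison
    with the fixed cutoff.
    """
    numeric = _numeric(ratios)
    if len(numeric) < 2:
        raise SelectionError("need at least two numeric ratios")
    stage1_mean = sum(numeric.values()) / len(numeric)
    stage1_cutoff = stage1_factor * stage1_mean
    stage1_set = frozenset(g for g, v in numeric.items() if v > stage1_cutoff)
    merged: dict[str, RatioValue] = dict(ratios)
    exclusions: dict[str, str] = {}
    if revised:
        for gene, value in revised.items():
            if gene in merged:
                exclusions[gene] = (
                    f"ratio revised {merged[gene]} -> {value} (quality diagnostics)"
                )
            merged[gene] = value
    revised_numeric = _numeric(merged)
    revised_mean = sum(revised_numeric.values()) / len(revised_numeric)
    final_set = frozenset(
        g for g, v in revised_numeric.items() if v > final_cutoff
    )
    return SelectionFlag(
        stage1_mean=stage1_mean,
        stage1_cutoff=stage1_cutoff,
        stage1_set=stage1_set,
        revised_mean=revised_mean,
        final_cutoff=final_cutoff,
        two_x_revised_mean=2.0 * revised_mean,
        final_set=final_set,
        exclusions=exclusions,
    )


@dataclass(frozen=True)
class LineageAssignment:
    gene: str
    ratio_finch_vs_outgroup: Optional[float]
    ratio_chicken_vs_outgroup: Optional[float]
    call: str  # finch_accelerated | chicken_accelerated | bird_accelerated | indeterminate


def assign_lineage(
    gene: str,
    ratio_finch_out: Optional[float],
    ratio_chicken_out: Optional[float],
    acceleration_factor: float = 1.5,
    final_cutoff: float = 0.1,
) -> LineageAssignment:
    """Attribute acceleration to a lineage using outgroup comparisons.

    A lineage dominates when its outgroup ratio is at least
    ``acceleration_factor`` times the other's; if both exceed the final
    cutoff without domination the call is bird-wide.
    """
    call = "indeterminate"
    if ratio_finch_out is not None and ratio_chicken_out is not None:
        rf, rc = ratio_finch_out, ratio_chicken_out
        if rc > 0 and rf >= acceleration_factor * rc:
            call = "finch_accelerated"
        elif rf > 0 and rc >= acceleration_factor * rf:
            call = "chicken_accelerated"
        elif rf > final_cutoff and rc > final_cutoff:
            call = "bird_accelerated"
    return LineageAssignment(gene, ratio_finch_out, ratio_chicken_out, call)
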