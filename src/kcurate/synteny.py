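"""Synteny-based locus classification and gain/loss reconciliation.

A candidate locus is classified as ortholog, duplication, allele,
pseudogene, or unresolved by applying rules in a fixed order over flank
sharing, alignment identity, genome placement, and sequence-degradation
marks.  Presence/absence of each gene across species is reconciled onto
the species tree under single-gain (Dollo) parsimony: one gain at the
deepest consistent node and a minimal set of loss branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

from .genome import GenomeMap, neighborhood
from .homology import AlignmentResult

DEFAULT_FLANK_WINDOW = 3
ALLELE_IDENTITY_THRESHOLD = 95.0

PRESENT, ABSENT, UNKNOWN_GAP = "present", "absent", "unknown_gap"


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenyEvidence:
    """Shared-flank counts between two placements of a locus."""

    shared_upstream: int
    shared_downstream: int
    flank_window: int
    rearrangement_flag: bool = False

    def __post_init__(self) -> None:
        if (self.shared_upstream > self.flank_window
                or self.shared_downstream > self.flank_window):
            raise SyntenyError("shared flank counts exceed the window")

    @property
    def supports_orthology(self) -> bool:
        """>=1 shared flank on each side, or >=3 shared flanks in total."""
        return (
            (self.shared_upstream >= 1 and self.shared_downstream >= 1)
            or self.shared_upstream + self.shared_downstream >= 3
        )


def synteny_evidence(
    query_map: GenomeMap, query_locus: str,
    target_map: GenomeMap, target_locus: str,
    k: int = DEFAULT_FLANK_WINDOW,
) -> SyntenyEvidence:
    """Count shared flank symbols per side between two loci.

    Flank comparison is unordered per side (gene identity, not
    orientation).  The rearrangement flag is set when a query flank
    symbol exists in the target species but on a different chromosome
    than the target locus.
    """
    up_q, down_q, _ = neighborhood(query_map, query_locus, k)
    up_t, down_t, _ = neighborhood(target_map, target_locus, k)
    shared_up = len(set(up_q) & set(up_t))
    shared_down = len(set(down_q) & set(down_t))
    target_chrom = target_map.find(target_locus).chrom
    rearranged = False
    for symbol in set(up_q) | set(down_q):
        if symbol in target_map:
            if target_map.find(symbol).chrom != target_chrom:
                rearranged = True
                break
    return SyntenyEvidence(
        shared_upstream=shared_up,
        shared_downstream=shared_down,
        flank_window=k,
        rearrangement_flag=rearranged,
    )


@dataclass(frozen=True)
class LocusClassification:
    call: str  # ortholog | duplication | allele | pseudogene | unresolved
    rule_trace: tuple[str, ...]
    evidence: Mapping[str, SyntenyEvidence] = field(default_factory=dict)
    placement: str = "placed"
    percent_identity: Optional[float] = None
    notes: str = ""


def classify_locus(
    candidate_symbol: str,
    placement: str,
    alignment: Optional[AlignmentResult],
    ortholog_evidence: Mapping[str, SyntenyEvidence],
    duplicate_evidence: Mapping[str, SyntenyEvidence] = {},
    degradation_marks: Sequence[str] = (),
    allele_identity: float = ALLELE_IDENTITY_THRESHOLD,
    min_duplicate_species: int = 2,
) -> LocusClassification:
    """Apply the classification rules in order; unresolved is the fallback.

    1. Shared flanks with the reference/outgroup locus on both sides in
       any comparator species -> ortholog.
    2. Placed locus whose own (distinct) flanks are conserved in at least
       ``min_duplicate_species`` species, the candidate's own genome
       included -> duplication.
    3. Identity >= the allele threshold and unplaced/gap-flanked
       placement -> allele.
    4. Any degradation mark (missing start codon, truncation without a
       gap excuse, no transcript support) -> pseudogene.

    Evidence maps are keyed by comparator species; the decision is
    invariant under their ordering.  Every call carries a rule trace.
    """
    if placement not in ("placed", "unplaced", "gap_flanked"):
        raise SyntenyError(f"bad placement {placement!r}")
    trace: list[str] = []
    evidence = dict(sorted(ortholog_evidence.items()))
    supporting = sorted(
        sp for sp, ev in ortholog_evidence.items() if ev.supports_orthology
    )
    if supporting:
        trace.append(
            f"rule1: shared flanks with reference locus in {supporting}"
        )
        return LocusClassification(
            call="ortholog", rule_trace=tuple(trace), evidence=evidence,
            placement=placement,
            percent_identity=alignment.percent_identity if alignment else None,
        )
    trace.append("rule1: no comparator species with flank support")
    dup_support = sorted(
        sp for sp, ev in duplicate_evidence.items() if ev.supports_orthology
    )
    # the candidate's own genome counts toward the species total
    if placement == "placed" and 1 + len(dup_support) >= min_duplicate_species:
        trace.append(f"rule2: distinct conserved flanks in {dup_support}")
        return LocusClassification(
            call="duplication", rule_trace=tuple(trace),
            evidence=dict(sorted(duplicate_evidence.items())),
            placement=placement,
            percent_identity=alignment.percent_identity if alignment else None,
            notes=f"conserved in {len(dup_support)} comparator species",
        )
    trace.append(
        f"rule2: placement={placement}, duplicate-flank support in "
        f"{1 + len(dup_support)} species (< {min_duplicate_species})"
    )
    identity = alignment.percent_identity if alignment else None
    if (
        identity is not None
        and identity >= allele_identity
        and placement in ("unplaced", "gap_flanked")
    ):
        trace.append(
            f"rule3: identity {identity:.1f} >= {allele_identity} and "
            f"{placement} placement"
        )
        return LocusClassification(
            call="allele", rule_trace=tuple(trace), evidence=evidence,
            placement=placement, percent_identity=identity,
        )
    trace.append("rule3: allele criteria not met")
    if degradation_marks:
        trace.append(f"rule4: degradation marks {sorted(degradation_marks)}")
        return LocusClassification(
            call="pseudogene", rule_trace=tuple(trace), evidence=evidence,
            placement=placement, percent_identity=identity,
            notes=";".join(sorted(degradation_marks)),
        )
    trace.append("rule4: no degradation marks; unresolved")
    return LocusClassification(
        call="unresolved", rule_trace=tuple(trace), evidence=evidence,
        placement=placement, percent_identity=identity,
    )


# ---------------------------------------------------------------------------
# Presence/absence and Dollo reconciliation


@dataclass
class PresenceAbsenceMatrix:
    genes: list[str]
    species: list[str]
    cells: dict[tuple[str, str], str]  # (gene, species) -> state

    def state(self, gene: str, species: str) -> str:
        return self.cells[(gene, species)]

    def row(self, gene: str) -> dict[str, str]:
        return {sp: self.cells[(gene, sp)] for sp in self.species}

    def to_tsv(self) -> str:
        lines = ["gene\t" + "\t".join(self.species)]
        for gene in self.genes:
            lines.append(
                gene + "\t" + "\t".join(self.cells[(gene, sp)] for sp in self.species)
            )
        return "\n".join(lines) + "\n"


def build_presence_matrix(
    genes: Sequence[str],
    maps: Mapping[str, GenomeMap],
    search_hits: Optional[Mapping[tuple[str, str], bool]] = None,
    k: int = DEFAULT_FLANK_WINDOW,
) -> PresenceAbsenceMatrix:
    """Presence/absence/unknown-gap states for each gene in each species.

    A gene is present when annotated in the species map (or confirmed by
    a sequence search hit).  An absent call requires the syntenic window
    — located via the gene's flanks in any species that retains it — to
    be free of assembly gaps; otherwise the cell is unknown_gap.
    """
    species = sorted(maps)
    cells: dict[tuple[str, str], str] = {}
    for gene in genes:
        carriers = [sp for sp in species if gene in maps[sp]]
        for sp in species:
            if gene in maps[sp] or (search_hits or {}).get((gene, sp), False):
                cells[(gene, sp)] = PRESENT
                continue
            cells[(gene, sp)] = _absent_or_gap(gene, maps[sp], maps, carriers, k)
    return PresenceAbsenceMatrix(genes=list(genes), species=species, cells=cells)


def _absent_or_gap(
    gene: str, target: GenomeMap, maps: Mapping[str, GenomeMap],
    carriers: Sequence[str], k: int,
) -> str:
    for carrier in carriers:
        up, down, _ = neighborhood(maps[carrier], gene, k)
        flank_feats = [target.find(s) for s in up + down if s in target]
        by_chrom: dict[str, list] = {}
        for f in flank_feats:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom, feats in by_chrom.items():
            if len(feats) < 2:
                continue
            start = min(f.start for f in feats)
            end = max(f.end for f in feats)
            if target.gaps_in(chrom, start, end):
                return UNKNOWN_GAP
    return ABSENT


@dataclass(frozen=True)
class GainLossEvents:
    gene: str
    gain_node: str  # internal node label or mrca(...) description
    loss_branches: tuple[str, ...]  # labels of subtree roots cut by a loss
    losses: int


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "mrca(" + ",".join(leaves) + ")"


def dollo_reconcile(
    gene: str,
    states: Mapping[str, str],
    tree: dendropy.Tree,
) -> GainLossEvents:
    """Single-gain, minimal-loss reconciliation of one presence row.

    ``states`` maps leaf label to present/absent/unknown_gap; unknown
    cells impose no constraint.  The gain is placed at the deepest
    (closest to the root) ancestor of all present leaves that adds no
    losses beyond the minimum; losses are the maximal subtrees under the
    gain that contain at least one absent leaf and no present leaf.
    """
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    unknown_labels = set(states) - set(leaf_by_label)
    if unknown_labels:
        raise SyntenyError(f"states name unknown leaves: {sorted(unknown_labels)}")
    present = {l for l, s in states.items() if s == PRESENT}
    absent = {l for l, s in states.items() if s == ABSENT}
    if not present:
        raise SyntenyError(f"{gene}: all-absent row cannot be reconciled")

    has_present: dict[dendropy.Node, bool] = {}
    has_absent: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            has_present[node] = label in present
            has_absent[node] = label in absent
        else:
            has_present[node] = any(has_present[c] for c in node.child_nodes())
            has_absent[node] = any(has_absent[c] for c in node.child_nodes())

    def loss_subtrees(gain: dendropy.Node) -> list[dendropy.Node]:
        cuts: list[dendropy.Node] = []

        def walk(v: dendropy.Node) -> None:
            if not has_present[v]:
                if has_absent[v]:
                    cuts.append(v)
                return
            for child in v.child_nodes():
                walk(child)

        for child in gain.child_nodes():
            walk(child)
        return cuts

    mrca = tree.mrca(taxa=[leaf_by_label[l].taxon for l in present])
    candidates = []
    node = mrca
    while node is not None:
        candidates.append(node)
        node = node.parent_node
    scored = [(len(loss_subtrees(n)), i, n) for i, n in enumerate(candidates)]
    min_losses = min(s[0] for s in scored)
    # deepest toward the root among minimal-loss candidates
    _, _, gain = max(s for s in scored if s[0] == min_losses)
    cuts = loss_subtrees(gain)
    return GainLossEvents(
        gene=gene,
        gain_node=node_label(gain),
        loss_branches=tuple(sorted(node_label(c) for c in cuts)),
        losses=len(cuts),
    )


def reconcile_matrix(
    matrix: PresenceAbsenceMatrix, tree: dendropy.Tree
) -> dict[str, GainLossEvents]:
    return {
        gene: dollo_reconcile(gene, matrix.row(gene), tree)
        for gene in matrix.genes
    }
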