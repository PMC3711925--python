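"""End-to-end orchestration: search, classify, reconcile, screen, report.

``run_pipeline`` drives a fixture bundle (real or simulated) through the
stages in order: secondary-locus search and classification, presence
matrix and gain/loss reconciliation, allelic-variant calling, indel
detection, and the dN/dS selection screen.  Candidate loci are the
unannotated models (symbols with the ``LOC`` prefix), mirroring how
novel loci surface in genome annotation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from . import homology
from .genome import GenomeMap, SequenceRecord, is_unplaced, neighborhood, read_tree
from .selection import CodonAlignment, estimate_dnds, flag_high_dnds, CODON_TABLE, STOP_CODONS
from .synteny import (
    build_presence_matrix, classify_locus, reconcile_matrix, synteny_evidence,
)
from .variants import DomainAnnotation, call_allelic_variants, detect_indels

CANDIDATE_PREFIX = "LOC"


class PipelineError(RuntimeError):
    pass


def translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i: i + 3].upper()
        if codon in STOP_CODONS:
            break
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def thread_codon_alignment(
    aligned_prot_a: str, aligned_prot_b: str, cds_a: str, cds_b: str,
) -> CodonAlignment:
    """Thread coding sequences onto a gapped protein alignment (pal2nal-style)."""
    out_a, out_b = [], []
    ia = ib = 0
    for pa, pb in zip(aligned_prot_a, aligned_prot_b):
        if pa == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia: 3 * ia + 3])
            ia += 1
        if pb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib: 3 * ib + 3])
            ib += 1
    return CodonAlignment(seq_a="".join(out_a), seq_b="".join(out_b))


def pair_codon_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    prot_a = SequenceRecord(id="a", residues=translate_cds(cds_a), alphabet="protein")
    prot_b = SequenceRecord(id="b", residues=translate_cds(cds_b), alphabet="protein")
    aln = homology.align_global(prot_a, prot_b)
    return thread_codon_alignment(
        aln.aligned_query, aln.aligned_target,
        cds_a[: 3 * len(prot_a.residues)], cds_b[: 3 * len(prot_b.residues)],
    )


def _placement(gmap: GenomeMap, symbol: str) -> str:
    feature = gmap.find(symbol)
    if is_unplaced(feature.chrom):
        return "unplaced"
    _, _, gaps = neighborhood(gmap, symbol, 1)
    return "gap_flanked" if gaps else "placed"


def _best_match(
    query: SequenceRecord,
    pool: Mapping[str, SequenceRecord],
    min_identity: float,
) -> Optional[tuple[str, homology.AlignmentResult]]:
    hits = homology.find_secondary_loci(
        query, dict(pool), min_identity=min_identity, primary=query.id
    )
    return hits[0] if hits else None


@dataclass
class PipelineReport:
    classifications: list[dict]
    presence_tsv: str
    events: dict[str, dict]
    variants: dict[str, dict]
    indels: list[dict]
    selection: dict
    provenance: dict
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifications": self.classifications,
                "presence_matrix": self.presence_tsv,
                "gain_loss_events": self.events,
                "variants": self.variants,
                "indels": self.indels,
                "selection": self.selection,
                "provenance": self.provenance,
                "warnings": self.warnings,
            },
            indent=1, sort_keys=True,
        )


def run_pipeline(
    maps: Mapping[str, GenomeMap],
    sequences: Mapping[str, Mapping[str, SequenceRecord]],
    tree_newick: str,
    species_pair: tuple[str, str] = ("finch", "chicken"),
    domains: Optional[Mapping[str, DomainAnnotation]] = None,
    final_cutoff: float = 0.1,
    flank_window: int = 3,
    counterpart_identity: float = 80.0,
    skip_stages: Sequence[str] = (),
) -> PipelineReport:
    """Run all stages over a fixture bundle; deterministic given inputs."""
    if not maps:
        raise PipelineError("no genome maps supplied")
    for sp in species_pair:
        if sp not in maps:
            raise PipelineError(f"species pair member {sp!r} has no genome map")
    tree = read_tree(tree_newick)
    warnings: list[str] = []
    domains = domains or {}

    annotated: dict[str, set[str]] = {
        sp: {f.symbol for f in maps[sp].all_features()
             if not f.symbol.startswith(CANDIDATE_PREFIX)}
        for sp in maps
    }
    candidates: dict[str, list[str]] = {
        sp: sorted(
            f.symbol for f in maps[sp].all_features()
            if f.symbol.startswith(CANDIDATE_PREFIX)
        )
        for sp in maps
    }

    # --- stage 1+2: secondary-locus search and synteny classification
    classifications: list[dict] = []
    variants: dict[str, dict] = {}
    if "classify" not in skip_stages:
        for sp in sorted(maps):
            for symbol in candidates[sp]:
                record = _classify_candidate(
                    sp, symbol, maps, sequences, annotated, candidates,
                    domains, flank_window, counterpart_identity, warnings,
                )
                classifications.append(record)
                if record["call"] == "allele" and record.get("variant_call"):
                    variants[f"{sp}:{symbol}"] = record.pop("variant_call")

    # --- stage 3: presence matrix + Dollo reconciliation
    presence_tsv = ""
    events: dict[str, dict] = {}
    if "reconcile" not in skip_stages:
        genes = sorted(set().union(*annotated.values()))
        matrix = build_presence_matrix(genes, dict(maps), k=flank_window)
        presence_tsv = matrix.to_tsv()
        for gene, ev in reconcile_matrix(matrix, tree).items():
            events[gene] = {
                "gain_node": ev.gain_node,
                "loss_branches": list(ev.loss_branches),
                "losses": ev.losses,
            }

    # --- stage 4: indel survey over the focal species pair
    indels: list[dict] = []
    if "indels" not in skip_stages:
        sp_a, sp_b = species_pair[1], species_pair[0]  # reference first
        shared = sorted(annotated[sp_a] & annotated[sp_b])
        for gene in shared:
            if gene not in sequences[sp_a] or gene not in sequences[sp_b]:
                continue
            caln = pair_codon_alignment(
                sequences[sp_a][gene].residues, sequences[sp_b][gene].residues
            )
            found = detect_indels(
                caln.seq_a, caln.seq_b,
                domains=domains.get(gene),
                name_a=sp_a, name_b=sp_b,
            )
            for rec in found:
                indels.append({
                    "gene": gene, "kind": rec.kind, "position": rec.position,
                    "residues": rec.residues, "lineage": rec.lineage,
                    "domain_overlap": rec.domain_overlap,
                    "quality_ok": rec.quality_ok, "frame_ok": rec.frame_ok,
                })

    # --- stage 5: dN/dS selection screen over the focal species pair
    selection_report: dict = {}
    if "selection" not in skip_stages:
        sp_a, sp_b = species_pair[1], species_pair[0]
        ratios: dict[str, object] = {}
        for gene in sorted(annotated[sp_a] & annotated[sp_b]):
            if gene not in sequences[sp_a] or gene not in sequences[sp_b]:
                continue
            caln = pair_codon_alignment(
                sequences[sp_a][gene].residues, sequences[sp_b][gene].residues
            )
            est = estimate_dnds(caln)
            ratios[gene] = est.ratio if isinstance(est.ratio, float) else "not_available"
        numeric = {g: v for g, v in ratios.items() if isinstance(v, float)}
        if len(numeric) >= 2:
            flag = flag_high_dnds(ratios, final_cutoff=final_cutoff)
            selection_report = {
                "ratios": {g: (round(v, 4) if isinstance(v, float) else v)
                           for g, v in ratios.items()},
                "stage1_mean": round(flag.stage1_mean, 4),
                "stage1_set": sorted(flag.stage1_set),
                "final_cutoff": flag.final_cutoff,
                "final_set": sorted(flag.final_set),
            }
        else:
            warnings.append("selection stage skipped: fewer than 2 numeric ratios")

    provenance = {
        "species": sorted(maps),
        "species_pair": list(species_pair),
        "inputs_hash": hashlib.sha256(
            json.dumps(
                {sp: sorted(sequences[sp]) for sp in sorted(sequences)},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    return PipelineReport(
        classifications=classifications,
        presence_tsv=presence_tsv,
        events=events,
        variants=variants,
        indels=indels,
        selection=selection_report,
        provenance=provenance,
        warnings=warnings,
    )


def _classify_candidate(
    sp: str,
    symbol: str,
    maps: Mapping[str, GenomeMap],
    sequences: Mapping[str, Mapping[str, SequenceRecord]],
    annotated: Mapping[str, set[str]],
    candidates: Mapping[str, list[str]],
    domains: Mapping[str, DomainAnnotation],
    flank_window: int,
    counterpart_identity: float,
    warnings: list[str],
) -> dict:
    seq = sequences[sp][symbol]
    pool = {g: sequences[sp][g] for g in annotated[sp] if g in sequences[sp]}
    parent_hit = _best_match(seq, pool, min_identity=50.0)
    if parent_hit is None:
        return {"species": sp, "symbol": symbol, "parent": None,
                "call": "unresolved", "rule_trace": ["no parent alignment"]}
    parent, aln = parent_hit
    placement = _placement(maps[sp], symbol)

    # the parent locus is annotated in this species, so the candidate is a
    # secondary locus: orthology to the parent's own slot is off the table
    ortholog_evidence: dict = {}
    duplicate_evidence: dict = {}
    for osp in sorted(maps):
        if osp == sp:
            continue
        opool = {
            c: sequences[osp][c] for c in candidates[osp] if c in sequences[osp]
        }
        if not opool:
            continue
        counterpart = _best_match(seq, opool, min_identity=counterpart_identity)
        if counterpart is None:
            continue
        try:
            duplicate_evidence[osp] = synteny_evidence(
                maps[sp], symbol, maps[osp], counterpart[0], k=flank_window
            )
        except KeyError:
            continue

    marks = []
    if not seq.residues.upper().startswith("ATG"):
        marks.append("missing_start_codon")
    parent_len = len(sequences[sp][parent])
    if len(seq) < 0.75 * parent_len:
        marks.append("truncation")

    classification = classify_locus(
        candidate_symbol=symbol,
        placement=placement,
        alignment=aln,
        ortholog_evidence=ortholog_evidence,
        duplicate_evidence=duplicate_evidence,
        degradation_marks=marks,
    )
    record = {
        "species": sp,
        "symbol": symbol,
        "parent": parent,
        "call": classification.call,
        "placement": placement,
        "percent_identity": round(aln.percent_identity, 2),
        "rule_trace": list(classification.rule_trace),
    }
    if classification.call == "allele":
        pair = homology.align_global(sequences[sp][parent], seq)
        call = call_allelic_variants(
            pair, placement,
            quals_primary=sequences[sp][parent].qualities,
            quals_secondary=seq.qualities,
            domains=domains.get(parent),
            lineage=sp,
        )
        record["variant_call"] = {
            "accepted": call.accepted,
            "reason": call.reason,
            "parent": parent,
            "substitutions": [
                {"position": s.position, "ref_aa": s.ref_aa, "alt_aa": s.alt_aa,
                 "klass": s.klass, "domain_overlap": s.domain_overlap}
                for s in call.substitutions
            ],
            "indels": [
                {"kind": i.kind, "position": i.position, "residues": i.residues}
                for i in call.indels
            ],
        }
    return record
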