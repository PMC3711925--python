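import numpy as np
import pytest

from kcurate.genome import SequenceRecord
from kcurate.homology import SIDE_CHAIN_GROUPS, align_global
from kcurate.pipeline import pair_codon_alignment
from kcurate.simulate import random_coding_sequence
from kcurate.variants import (
    DomainAnnotation, VariantError, call_allelic_variants,
    classify_substitution, codon_columns_ok, detect_indels, load_domains,
    quality_mask, summarize_indels,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("T", "S", "conservative"),
        ("T", "A", "non_conservative"),
        ("N", "D", "non_conservative"),
        ("Y", "S", "non_conservative"),
        ("L", "L", "identical"),
        ("L", "I", "conservative"),
        ("K", "R", "conservative"),
        ("D", "E", "conservative"),
        ("G", "A", "non_conservative"),
        ("P", "G", "non_conservative"),
    ],
)
def test_classify_substitution_examples(ref, alt, expected):
    assert classify_substitution(ref, alt) == expected


def test_classify_symmetric_over_all_400_pairs():
    for a in AA20:
        for b in AA20:
            assert classify_substitution(a, b) == classify_substitution(b, a)


def test_unknown_amino_acid_rejected():
    with pytest.raises(VariantError):
        classify_substitution("T", "B")


def test_groups_partition_the_alphabet():
    seen = [aa for g in SIDE_CHAIN_GROUPS for aa in g]
    assert sorted(seen) == sorted(AA20)


def test_quality_mask_all_high():
    mask = quality_mask("ACG", "ACG", (60, 60, 60), (60, 60, 60))
    assert mask == (True, True, True)


def test_quality_mask_low_base_masks_column():
    mask = quality_mask("ACG", "ACG", (60, 20, 60), (60, 60, 60))
    assert mask == (True, False, True)


def test_quality_mask_gap_interval_masks_column():
    mask = quality_mask("ACG", "ACG", gap_intervals_a=((2, 2),))
    assert mask == (True, False, True)


def test_quality_mask_handles_alignment_gaps():
    mask = quality_mask("A-CG", "AACG", (60, 60, 60), (60, 60, 20, 60))
    assert mask == (True, True, False, True)


def test_quality_mask_length_mismatch_rejected():
    with pytest.raises(VariantError):
        quality_mask("ACG", "ACG", (60, 60), None)


def test_codon_columns_collapse():
    assert codon_columns_ok([True] * 3 + [True, False, True]) == (True, False)


def _allele_pair(rng=None, edits=()):
    rng = rng or np.random.default_rng(0)
    primary = random_coding_sequence(120, rng)
    codons = [primary[i: i + 3] for i in range(0, len(primary), 3)]
    for pos, new_codon in edits:
        codons[pos - 1] = new_codon
    secondary = "".join(codons)
    rec_p = SequenceRecord(id="p", residues=primary,
                           qualities=tuple([60] * len(primary)))
    rec_s = SequenceRecord(id="s", residues=secondary,
                           qualities=tuple([60] * len(secondary)))
    return rec_p, rec_s, align_global(rec_p, rec_s)


def test_call_allelic_variants_planted_edits():
    # plant codons with known outcomes: TTT->TTC syn, ACT->TCT cons (T->S),
    # AAT->GAT non-cons (N->D); positions chosen on distinct codons
    rng = np.random.default_rng(1)
    primary = "ATG" + "TTT" + "ACT" + "AAT" + random_coding_sequence(116, rng)[9:]
    codons = [primary[i: i + 3] for i in range(0, len(primary), 3)]
    codons[1], codons[2], codons[3] = "TTC", "TCT", "GAT"
    secondary = "".join(codons)
    rec_p = SequenceRecord(id="p", residues=primary, qualities=(60,) * len(primary))
    rec_s = SequenceRecord(id="s", residues=secondary, qualities=(60,) * len(secondary))
    call = call_allelic_variants(
        align_global(rec_p, rec_s), "unplaced",
        quals_primary=rec_p.qualities, quals_secondary=rec_s.qualities,
    )
    assert call.accepted
    got = {(s.position, s.klass) for s in call.substitutions}
    assert got == {(2, "synonymous"), (3, "conservative"), (4, "non_conservative")}


def test_call_rejected_below_identity():
    rng = np.random.default_rng(2)
    primary = random_coding_sequence(40, rng)
    other = random_coding_sequence(40, rng)
    rec_p = SequenceRecord(id="p", residues=primary, qualities=(60,) * len(primary))
    rec_s = SequenceRecord(id="s", residues=other, qualities=(60,) * len(other))
    call = call_allelic_variants(align_global(rec_p, rec_s), "unplaced")
    assert not call.accepted
    assert call.reason == "below identity threshold"


def test_call_rejected_placed_chromosome():
    rec_p, rec_s, aln = _allele_pair()
    call = call_allelic_variants(aln, "placed")
    assert not call.accepted
    assert call.reason == "placement suggests duplication"


def test_call_rejected_low_quality():
    rec_p, rec_s, aln = _allele_pair()
    quals = [60] * len(rec_s)
    quals[30] = 20
    call = call_allelic_variants(
        aln, "unplaced",
        quals_primary=rec_p.qualities, quals_secondary=tuple(quals),
    )
    assert not call.accepted
    assert "quality" in call.reason


def test_call_annotates_domains():
    rng = np.random.default_rng(3)
    primary = random_coding_sequence(120, rng)
    codons = [primary[i: i + 3] for i in range(0, len(primary), 3)]
    codons[49] = "TGG" if codons[49] != "TGG" else "TAT"
    secondary = "".join(codons)
    rec_p = SequenceRecord(id="p", residues=primary, qualities=(60,) * len(primary))
    rec_s = SequenceRecord(id="s", residues=secondary, qualities=(60,) * len(secondary))
    domains = DomainAnnotation(protein="p", intervals=((40, 60, "ion_transport"),))
    call = call_allelic_variants(
        align_global(rec_p, rec_s), "unplaced", domains=domains
    )
    assert call.accepted
    assert any(s.domain_overlap == "ion_transport" for s in call.substitutions)


def test_detect_indels_ng_style_deletion_in_domain():
    # reference has NG at residues 681-682 inside an ion transport domain;
    # scaled down: residues 5-6 deleted in the other lineage
    ref_prot = "MKVAWNGQRLT"
    alt_prot = "MKVAWQRLT"  # NG deleted
    codon = {"M": "ATG", "K": "AAA", "V": "GTT", "A": "GCT", "W": "TGG",
             "N": "AAT", "G": "GGT", "Q": "CAA", "R": "CGT", "L": "CTT",
             "T": "ACT"}
    cds_ref = "".join(codon[a] for a in ref_prot)
    cds_alt = "".join(codon[a] for a in alt_prot)
    caln = pair_codon_alignment(cds_ref, cds_alt)
    domains = DomainAnnotation(protein="ref", intervals=((4, 8, "ion_transport"),))
    records = detect_indels(caln.seq_a, caln.seq_b, domains=domains,
                            name_a="chicken", name_b="finch")
    assert len(records) == 1
    rec = records[0]
    assert rec.kind == "deletion"
    assert rec.residues == "NG"
    assert rec.lineage == "finch"
    assert rec.position == 5
    assert rec.domain_overlap == "ion_transport"
    assert rec.frame_ok


def test_detect_indels_planted_insertion():
    rng = np.random.default_rng(5)
    ref = random_coding_sequence(60, rng)
    codons = [ref[i: i + 3] for i in range(0, len(ref), 3)]
    codons[20:20] = ["TGG", "CAA"]  # 2-codon insertion in the other lineage
    alt = "".join(codons)
    caln = pair_codon_alignment(ref, alt)
    records = detect_indels(caln.seq_a, caln.seq_b, name_a="a", name_b="b")
    assert len(records) == 1
    assert records[0].kind == "insertion"
    assert len(records[0].residues) == 2
    assert records[0].lineage == "b"


def test_indel_near_masked_region_flagged():
    seq_a = "ATGAAATTTCCC"
    seq_b = "ATGAAA---CCC"
    mask = [True] * 6 + [False] * 3 + [True] * 3
    records = detect_indels(seq_a, seq_b, mask=mask)
    assert len(records) == 1
    assert not records[0].quality_ok
    summary = summarize_indels(records)
    assert summary["total"] == 0
    assert summary["excluded_low_quality"] == 1


def test_indel_residue_sum_matches_gap_columns():
    rng = np.random.default_rng(8)
    ref = random_coding_sequence(80, rng)
    codons = [ref[i: i + 3] for i in range(0, len(ref), 3)]
    del codons[10:12]
    codons[40:40] = ["TGG"]
    alt = "".join(codons)
    caln = pair_codon_alignment(ref, alt)
    records = detect_indels(caln.seq_a, caln.seq_b)
    gap_columns = caln.seq_a.count("-") + caln.seq_b.count("-")
    assert sum(len(r.residues) for r in records if r.frame_ok) == gap_columns // 3


def test_frame_breaking_gap_flagged_not_dropped():
    seq_a = "ATGAAATTTCCC"
    seq_b = "ATGAA--TTCCC"
    records = detect_indels(seq_a, seq_b)
    assert len(records) == 1
    assert not records[0].frame_ok


def test_load_domains_tsv(tmp_path):
    path = tmp_path / "domains.tsv"
    path.write_text(
        "protein\tstart\tend\tlabel\nP1\t10\t30\tion_transport\nP1\t40\t60\ttransmembrane\n"
    )
    domains = load_domains(path)
    assert domains["P1"].label_at(15) == "ion_transport"
    assert domains["P1"].label_at(45) == "transmembrane"
    assert domains["P1"].label_at(99) == "none"
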