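import random

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from kcurate.genome import SequenceRecord
from kcurate.homology import (
    NUCLEOTIDE_SCHEME, PROTEIN_SCHEME, AlignmentError, ScoringScheme,
    align_global, align_local, find_secondary_loci, hits_to_tsv,
    similarity_stats,
)

NEG = float("-inf")


def _scorer(scheme):
    if scheme.matrix:
        mat = substitution_matrices.load(scheme.matrix)
        return lambda a, b: mat[a][b]
    return lambda a, b: scheme.match if a == b else scheme.mismatch


def oracle_global(x, y, scheme):
    """Independent full-matrix affine-gap DP (Gotoh), scores only."""
    s = _scorer(scheme)
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    n, m = len(x), len(y)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(scheme.gap_open + ge * i)
    for j in range(1, m + 1):
        Iy[0][j] = -(scheme.gap_open + ge * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s(x[i - 1], y[j - 1])
            Ix[i][j] = max(M[i - 1][j] - go, Ix[i - 1][j] - ge, Iy[i - 1][j] - go)
            Iy[i][j] = max(M[i][j - 1] - go, Iy[i][j - 1] - ge, Ix[i][j - 1] - go)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def oracle_local(x, y, scheme):
    s = _scorer(scheme)
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    n, m = len(x), len(y)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s(x[i - 1], y[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nt(seq, id="q"):
    return SequenceRecord(id=id, residues=seq)


def aa(seq, id="q"):
    return SequenceRecord(id=id, residues=seq, alphabet="protein")


def test_self_alignment_full_identity():
    res = align_local(nt("ACGTACGTAA"), nt("ACGTACGTAA", "t"))
    assert res.percent_identity == 100.0
    assert res.aligned_query == "ACGTACGTAA"


def test_single_base_local_alignment():
    scheme = ScoringScheme(match=1, mismatch=-1, gap_open=0, gap_extend=2)
    res = align_local(nt("ACGT"), nt("TTTT", "t"), scheme)
    assert res.score == 1.0
    assert res.aligned_query == "T"


def test_global_equal_sequences_no_gaps():
    res = align_global(aa("MKVRW"), aa("MKVRW", "t"))
    assert "-" not in res.aligned_query + res.aligned_target
    assert res.percent_identity == 100.0


def test_global_single_gap_column():
    res = align_global(aa("MKV"), aa("MV", "t"))
    assert (res.aligned_query + res.aligned_target).count("-") == 1


def test_mixed_alphabets_rejected():
    with pytest.raises(AlignmentError, match="mixed"):
        align_local(nt("ACGT"), aa("MKV", "t"))


def test_empty_sequence_rejected():
    with pytest.raises(AlignmentError):
        align_global(nt("A"), SequenceRecord(id="t", residues=""))


@pytest.mark.parametrize("mode_impl,mode_oracle", [
    (align_local, oracle_local), (align_global, oracle_global),
])
def test_scores_match_dp_oracle_nucleotide(mode_impl, mode_oracle):
    rng = random.Random(7)
    for _ in range(25):
        x = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        y = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        res = mode_impl(nt(x), nt(y, "t"), NUCLEOTIDE_SCHEME)
        assert res.score == pytest.approx(mode_oracle(x, y, NUCLEOTIDE_SCHEME))


@pytest.mark.parametrize("mode_impl,mode_oracle", [
    (align_local, oracle_local), (align_global, oracle_global),
])
def test_scores_match_dp_oracle_protein(mode_impl, mode_oracle):
    rng = random.Random(11)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(15):
        x = "".join(rng.choice(letters) for _ in range(rng.randint(5, 25)))
        y = "".join(rng.choice(letters) for _ in range(rng.randint(5, 25)))
        res = mode_impl(aa(x), aa(y, "t"), PROTEIN_SCHEME)
        assert res.score == pytest.approx(mode_oracle(x, y, PROTEIN_SCHEME))


def test_score_symmetric_under_exchange():
    rng = random.Random(3)
    for _ in range(10):
        x = "".join(rng.choice("ACGT") for _ in range(20))
        y = "".join(rng.choice("ACGT") for _ in range(18))
        assert align_local(nt(x), nt(y, "t")).score == align_local(
            nt(y), nt(x, "t")
        ).score
        assert align_global(nt(x), nt(y, "t")).score == align_global(
            nt(y), nt(x, "t")
        ).score


@settings(max_examples=30, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=2, max_size=15),
    st.text(alphabet="ACGT", min_size=2, max_size=15),
    st.text(alphabet="ACGT", min_size=1, max_size=6),
)
def test_local_score_monotone_under_matching_extension(x, y, suffix):
    base = align_local(nt(x), nt(y, "t")).score
    extended = align_local(nt(x + suffix), nt(y + suffix, "t")).score
    assert extended >= base


def test_similarity_stats_identical():
    res = align_global(aa("MKVRWLQAGH"), aa("MKVRWLQAGH", "t"))
    assert similarity_stats(res) == (100.0, 100.0)


def test_similarity_stats_mixed_columns():
    # 10 columns: 8 identical, 1 same-group (L->I aliphatic), 1 cross-group
    q = aa("MKVRWLQAGH")
    t = aa("MKVRWIQAGD", "t")  # L->I conservative, H->D non-conservative
    res = align_global(q, t)
    identity, similarity = similarity_stats(res)
    assert identity == pytest.approx(80.0)
    assert similarity == pytest.approx(90.0)


def test_similarity_stats_rejects_nucleotide():
    res = align_global(nt("ACGT"), nt("ACGT", "t"))
    with pytest.raises(AlignmentError):
        similarity_stats(res)


def _mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def test_find_secondary_loci_exact_copy():
    rng = random.Random(5)
    query = nt("".join(rng.choice("ACGT") for _ in range(120)), "gene1")
    genome = {
        "gene1": query,
        "copy": nt(query.residues, "copy"),
        "other": nt("".join(rng.choice("ACGT") for _ in range(120)), "other"),
    }
    hits = find_secondary_loci(query, genome, min_identity=95)
    assert [h[0] for h in hits] == ["copy"]
    assert hits[0][1].percent_identity == 100.0


def test_find_secondary_loci_divergent_copy_excluded():
    rng = random.Random(6)
    base = "".join(rng.choice("ACGT") for _ in range(120))
    query = nt(base, "gene1")
    genome = {"gene1": query, "copy": nt(_mutate(base, range(0, 120, 10)), "copy")}
    hits = find_secondary_loci(query, genome, min_identity=95)
    assert hits == []


def test_find_secondary_loci_matches_exhaustive_oracle():
    rng = random.Random(9)
    base = "".join(rng.choice("ACGT") for _ in range(120))
    query = nt(base, "gene1")
    genome = {"gene1": query}
    for k in range(20):
        positions = list(range(10, 10 + 6 * k, 6))[:k]
        genome[f"copy{k:02d}"] = nt(_mutate(base, positions), f"copy{k:02d}")
    hits = {h[0] for h in find_secondary_loci(query, genome, min_identity=95)}
    expected = set()
    for locus, seq in genome.items():
        if locus == "gene1":
            continue
        res = align_local(query, seq)
        if res.percent_identity >= 95:
            expected.add(locus)
    assert hits == expected
    assert len(expected) > 0


def test_hits_export_tabular():
    query = nt("ACGTACGTACGTACG", "g")
    genome = {"g": query, "c": nt(query.residues, "c")}
    hits = find_secondary_loci(query, genome, min_identity=95)
    text = hits_to_tsv("g", hits)
    assert text.splitlines()[0].startswith("query\ttarget")
    assert "\tc\t100.00\t" in text.splitlines()[1]


def test_gap_penalties_must_be_nonnegative():
    with pytest.raises(AlignmentError):
        ScoringScheme(gap_open=-1)
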