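import itertools
import random

import pytest

from kcurate.genome import GeneFeature, GenomeMap, read_tree
from kcurate.homology import AlignmentResult
from kcurate.synteny import (
    GainLossEvents, SyntenyError, SyntenyEvidence, build_presence_matrix,
    classify_locus, dollo_reconcile, node_label, synteny_evidence,
)

TREE8 = "((fish,(frog,((lizard,(chicken,finch)),(platypus,(mouse,human))))));"


def make_map(species, chrom_orders, gaps=()):
    gmap = GenomeMap(species=species)
    for chrom, symbols in chrom_orders.items():
        for i, sym in enumerate(symbols):
            start = 1000 * i + 1
            gmap.add(GeneFeature(chrom=chrom, start=start, end=start + 500,
                                 symbol=sym))
    for chrom, start, end in gaps:
        gmap.add(GeneFeature(chrom=chrom, start=start, end=end,
                             symbol=f"gap{start}", is_gap=True))
    gmap.sort()
    return gmap


def fake_alignment(identity):
    return AlignmentResult(
        aligned_query="A" * 10, aligned_target="A" * 10, score=10.0,
        query_span=(1, 10), target_span=(1, 10),
        percent_identity=identity, percent_similarity=identity,
        alphabet="nucleotide",
    )


def test_identical_flank_sets():
    q = make_map("a", {"chr1": ["F1", "F2", "F3", "X", "F4", "F5", "F6"]})
    t = make_map("b", {"chr9": ["F1", "F2", "F3", "X", "F4", "F5", "F6"]})
    ev = synteny_evidence(q, "X", t, "X", k=3)
    assert (ev.shared_upstream, ev.shared_downstream) == (3, 3)
    assert not ev.rearrangement_flag


def test_inverted_downstream_flanks_unchanged():
    q = make_map("a", {"chr1": ["F1", "F2", "X", "F3", "F4"]})
    t = make_map("b", {"chr1": ["F1", "F2", "X", "F4", "F3"]})
    ev = synteny_evidence(q, "X", t, "X", k=2)
    assert (ev.shared_upstream, ev.shared_downstream) == (2, 2)


def test_split_flanks_set_rearrangement_flag():
    q = make_map("a", {"chr1": ["F1", "F2", "X", "F3", "F4"]})
    t = make_map("b", {"chr1": ["F1", "X", "F3"], "chr7": ["F2", "F4"]})
    ev = synteny_evidence(q, "X", t, "X", k=2)
    assert ev.rearrangement_flag


def test_synteny_absent_locus_errors():
    q = make_map("a", {"chr1": ["A", "X"]})
    with pytest.raises(KeyError):
        synteny_evidence(q, "Z", q, "X")


def test_flank_counts_bounded_by_window():
    with pytest.raises(SyntenyError):
        SyntenyEvidence(shared_upstream=4, shared_downstream=0, flank_window=3)


def ev(up, down, k=3, rearranged=False):
    return SyntenyEvidence(up, down, k, rearranged)


def test_classify_ortholog_shared_flanks():
    result = classify_locus(
        "X", "placed", fake_alignment(88.0),
        ortholog_evidence={"human": ev(1, 1)},
    )
    assert result.call == "ortholog"
    assert any("rule1" in step for step in result.rule_trace)


def test_classify_duplication_conserved_distinct_flanks():
    result = classify_locus(
        "XL", "placed", fake_alignment(90.0),
        ortholog_evidence={},
        duplicate_evidence={"chicken": ev(2, 2), "lizard": ev(1, 2)},
    )
    assert result.call == "duplication"


def test_classify_allele_on_unplaced_scaffold():
    result = classify_locus(
        "Xalt", "unplaced", fake_alignment(97.0),
        ortholog_evidence={},
    )
    assert result.call == "allele"


def test_classify_pseudogene_from_degradation_marks():
    result = classify_locus(
        "XP", "placed", fake_alignment(99.0),
        ortholog_evidence={},
        degradation_marks=("missing_start_codon", "truncation"),
    )
    assert result.call == "pseudogene"
    assert "missing_start_codon" in result.notes


def test_classify_unresolved_fallback():
    result = classify_locus("X?", "placed", fake_alignment(80.0), {})
    assert result.call == "unresolved"
    assert len(result.rule_trace) == 4


def test_classify_permutation_invariant():
    evidence = {"a": ev(0, 1), "b": ev(1, 1), "c": ev(0, 0)}
    calls = set()
    for order in itertools.permutations(evidence.items()):
        result = classify_locus("X", "placed", fake_alignment(90.0), dict(order))
        calls.add((result.call, tuple(result.rule_trace)))
    assert len(calls) == 1


def test_presence_matrix_all_present():
    maps = {
        sp: make_map(sp, {"chr1": ["A", "G1", "B"]}) for sp in ("s1", "s2", "s3")
    }
    matrix = build_presence_matrix(["G1"], maps)
    assert all(matrix.state("G1", sp) == "present" for sp in maps)


def test_presence_matrix_planted_loss():
    full = {"chr1": ["A", "B", "G1", "C", "D"]}
    lost = {"chr1": ["A", "B", "C", "D"]}
    maps = {
        "lizard": make_map("lizard", full),
        "chicken": make_map("chicken", lost),
        "finch": make_map("finch", lost),
    }
    matrix = build_presence_matrix(["G1"], maps)
    assert matrix.state("G1", "lizard") == "present"
    assert matrix.state("G1", "chicken") == "absent"
    assert matrix.state("G1", "finch") == "absent"


def test_presence_matrix_gap_means_unknown():
    full = {"chr1": ["A", "B", "G1", "C", "D"]}
    lost = {"chr1": ["A", "B", "C", "D"]}
    maps = {
        "lizard": make_map("lizard", full),
        # gap interval inside the B..C window of the species missing G1
        "finch": make_map("finch", lost, gaps=[("chr1", 1700, 1900)]),
    }
    matrix = build_presence_matrix(["G1"], maps)
    assert matrix.state("G1", "finch") == "unknown_gap"


def test_presence_matrix_tsv_export():
    maps = {"s1": make_map("s1", {"chr1": ["A", "G1", "B"]})}
    text = build_presence_matrix(["G1"], maps).to_tsv()
    assert text.splitlines()[0] == "gene\ts1"
    assert text.splitlines()[1] == "G1\tpresent"


# --- Dollo reconciliation ---------------------------------------------------


def leaves_of(label, tree):
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return sorted(l.taxon.label for l in node.leaf_iter())
    return [label]


def test_dollo_teleostomi_gain_mammal_loss():
    tree = read_tree(TREE8)
    states = {"finch": "present", "chicken": "present", "lizard": "present",
              "fish": "present", "mouse": "absent", "human": "absent"}
    events = dollo_reconcile("G", states, tree)
    assert set(leaves_of(events.gain_node, tree)) >= {
        "fish", "lizard", "chicken", "finch"}
    assert events.losses == 1
    # the loss is cut at the mammal branch (platypus is unconstrained)
    assert leaves_of(events.loss_branches[0], tree) == [
        "human", "mouse", "platypus"]


def test_dollo_tetrapod_gain_supraprimate_loss():
    tree = read_tree(
        "((fish,(frog,((lizard,(chicken,finch)),(platypus,((mouse,human),(horse,cow)))))));"
    )
    states = {"frog": "present", "lizard": "present", "chicken": "present",
              "finch": "present", "platypus": "present", "horse": "present",
              "cow": "present", "fish": "absent", "mouse": "absent",
              "human": "absent"}
    events = dollo_reconcile("G", states, tree)
    assert events.losses == 1
    assert leaves_of(events.loss_branches[0], tree) == ["human", "mouse"]
    assert "fish" not in leaves_of(events.gain_node, tree)


def test_dollo_present_everywhere():
    tree = read_tree(TREE8)
    states = {l: "present" for l in
              ("fish", "frog", "lizard", "chicken", "finch",
               "platypus", "mouse", "human")}
    events = dollo_reconcile("G", states, tree)
    assert events.losses == 0
    assert len(leaves_of(events.gain_node, tree)) == 8


def test_dollo_all_absent_is_error():
    tree = read_tree(TREE8)
    with pytest.raises(SyntenyError):
        dollo_reconcile("G", {"fish": "absent", "frog": "absent"}, tree)


def test_dollo_unknown_gap_unconstrained():
    tree = read_tree(TREE8)
    states = {"finch": "present", "chicken": "unknown_gap",
              "lizard": "present", "mouse": "absent"}
    events = dollo_reconcile("G", states, tree)
    # chicken's gap imposes no loss, and the absent mouse lies outside the
    # gain clade, so no loss branch is needed at all
    assert events.losses == 0
    assert "mouse" not in leaves_of(events.gain_node, tree)


def brute_force_dollo(states, tree):
    """Exhaustive minimal-loss search: try every gain node and every
    loss-edge subset of increasing size."""
    present = {l for l, s in states.items() if s == "present"}
    absent = {l for l, s in states.items() if s == "absent"}
    nodes = list(tree.preorder_node_iter())
    best = None
    for gain in nodes:
        below = {l.taxon.label for l in gain.leaf_iter()}
        if not present <= below:
            continue
        sub_nodes = [n for n in gain.preorder_iter() if n is not gain]
        for k in range(0, len(sub_nodes) + 1):
            found = None
            for cut in itertools.combinations(sub_nodes, k):
                covered = set()
                for c in cut:
                    covered |= {l.taxon.label for l in c.leaf_iter()}
                if (absent & below) <= covered and not (present & covered):
                    found = k
                    break
            if found is not None:
                if best is None or found < best:
                    best = found
                break
    return best


def random_tree(rng, n_leaves):
    labels = [f"s{i}" for i in range(n_leaves)]
    items = list(labels)
    while len(items) > 1:
        a = items.pop(rng.randrange(len(items)))
        b = items.pop(rng.randrange(len(items)))
        items.append(f"({a},{b})")
    return read_tree(items[0] + ";"), labels


def test_dollo_minimal_vs_brute_force_on_random_trees():
    rng = random.Random(13)
    for _ in range(15):
        n = rng.randint(4, 10)
        tree, labels = random_tree(rng, n)
        states = {}
        for label in labels:
            states[label] = rng.choice(["present", "absent", "unknown_gap"])
        if "present" not in states.values():
            states[labels[0]] = "present"
        events = dollo_reconcile("G", states, tree)
        assert events.losses == brute_force_dollo(states, tree)


def test_dollo_gain_prefers_deepest_without_extra_losses():
    # sibling subtree of the MRCA is all-unknown: gain should float up
    tree = read_tree("((a,b),(c,d));")
    states = {"a": "present", "b": "present",
              "c": "unknown_gap", "d": "unknown_gap"}
    events = dollo_reconcile("G", states, tree)
    assert len(leaves_of(events.gain_node, tree)) == 4  # the root


def test_gain_loss_events_structure():
    tree = read_tree(TREE8)
    states = {"finch": "present", "mouse": "absent"}
    events = dollo_reconcile("G", states, tree)
    assert isinstance(events, GainLossEvents)
    assert events.gene == "G"
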