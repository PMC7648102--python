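"""Signed circular gene-order comparison: signatures, breakpoint distance,
conserved blocks and the event classifier."""

import random

import pytest

from mitochar.gene_order import (
    GeneOrderSignature,
    breakpoint_distance,
    classify_events,
    conserved_blocks,
    format_order_string,
    parse_order_string,
    signature,
)
from mitochar.simulate import apply_rearrangements


def _sig(text, origin=None):
    return parse_order_string(text, origin_gene=origin)


def test_signature_preserves_genome_order_and_signs(lg):
    # anchor on a plus-strand gene so normalization leaves strands as-is
    sig = signature(lg, shared_set={"nad5", "nad4l", "nad4"}, origin_gene="nad4l")
    names = [g for g, _ in sig.genes]
    signs = dict(sig.genes)
    assert set(names) == {"nad5", "nad4l", "nad4"}
    assert signs == {"nad5": -1, "nad4l": 1, "nad4": 1}
    # consecutive run in genome order: nad5 then nad4l then nad4
    i = names.index("nad5")
    assert names[(i + 1) % 3] == "nad4l" and names[(i + 2) % 3] == "nad4"


def test_signature_single_gene():
    assert len(_sig("cox1")) == 1


def test_signature_missing_shared_gene_listed(lg):
    with pytest.raises(KeyError, match="nonexistent"):
        signature(lg, shared_set={"cox1", "nonexistent"})


def test_signature_duplicates_excluded_by_default(lg):
    sig = signature(lg)
    assert "trnM" not in sig.symbols  # trnM1/trnM2 both dropped
    assert len(sig) == 36


def test_signature_duplicates_keep_first(lg):
    sig = signature(lg, duplicates="first")
    assert "trnM" in sig.symbols
    assert len(sig) == 37


def test_normalization_invariant_to_origin_choice(lg):
    a = signature(lg, origin_gene="cox1")
    b = signature(lg, origin_gene="nad2")
    assert GeneOrderSignature(b.genes, "cox1").genes == a.genes


def test_normalization_flips_circle_for_minus_origin():
    a = _sig("cox1,nad2,-nad5")
    b = _sig("-cox1,nad5,-nad2")  # same circle read on the other strand
    assert a.genes == GeneOrderSignature(b.genes, "cox1").genes


def test_breakpoint_distance_identity(lg):
    sig = signature(lg)
    assert breakpoint_distance(sig, sig) == 0


def test_breakpoint_distance_single_block_inversion():
    base = _sig("a,b,c,d,e,f,g,h,i,j")
    inverted = _sig("a,b,-e,-d,-c,f,g,h,i,j")
    assert breakpoint_distance(base, inverted) == 2


def test_breakpoint_distance_symmetric_on_random_permutations():
    rng = random.Random(5)
    genes = [f"g{i}" for i in range(10)]
    for _ in range(20):
        p1 = rng.sample(genes, 10)
        p2 = rng.sample(genes, 10)
        s1 = _sig(",".join(("" if rng.random() < 0.5 else "-") + g for g in p1), origin="g0")
        s2 = _sig(",".join(("" if rng.random() < 0.5 else "-") + g for g in p2), origin="g0")
        assert breakpoint_distance(s1, s2) == breakpoint_distance(s2, s1)


def test_breakpoint_distance_triangle_inequality_sampled():
    rng = random.Random(9)
    genes = [f"g{i}" for i in range(10)]

    def rand_sig():
        perm = rng.sample(genes, 10)
        return _sig(
            ",".join(("" if rng.random() < 0.5 else "-") + g for g in perm),
            origin="g0",
        )

    for _ in range(30):
        a, b, c = rand_sig(), rand_sig(), rand_sig()
        assert breakpoint_distance(a, c) <= (
            breakpoint_distance(a, b) + breakpoint_distance(b, c)
        )


def test_breakpoint_distance_gene_set_mismatch():
    with pytest.raises(ValueError, match="gene sets differ"):
        breakpoint_distance(_sig("a,b,c"), _sig("a,b,d"))


def test_k_inversions_bound_breakpoints():
    """k random block inversions create at most 2k breakpoints."""
    base = _sig(",".join(f"g{i}" for i in range(12)), origin="g0")
    for seed in range(8):
        for k in (1, 2, 4):
            rearranged, log = apply_rearrangements(
                base, k, mix=(1.0, 0.0, 0.0), seed=seed
            )
            assert len(log) == k
            assert breakpoint_distance(base, rearranged) <= 2 * k


def test_conserved_blocks_identity_is_one_block():
    sig = _sig("a,b,c,d,e")
    blocks = conserved_blocks(sig, sig)
    assert len(blocks) == 1 and set(blocks[0].genes) == {"a", "b", "c", "d", "e"}
    assert not blocks[0].inverted


def test_conserved_blocks_flags_inverted_run():
    base = _sig("a,b,c,d,e,f,g,h")
    flipped = _sig("a,b,-e,-d,-c,f,g,h")
    blocks = conserved_blocks(base, flipped)
    inv = [b for b in blocks if b.inverted]
    assert len(inv) == 1 and tuple(inv[0].genes) == ("c", "d", "e")


def test_conserved_blocks_scrambled_gives_singletons():
    base = _sig("a,b,c,d,e,f", origin="a")
    scrambled = _sig("a,d,b,f,c,e", origin="a")
    blocks = conserved_blocks(base, scrambled)
    assert all(len(b.genes) == 1 for b in blocks)
    assert len(blocks) == 6


def test_conserved_blocks_symmetric_partition():
    base = _sig("a,b,c,d,e,f,g,h")
    other = _sig("a,b,-e,-d,-c,f,g,h")
    b1 = {frozenset(b.genes) for b in conserved_blocks(base, other)}
    b2 = {frozenset(b.genes) for b in conserved_blocks(other, base)}
    assert b1 == b2


def test_classifier_identity_all_in_place():
    sig = _sig("a,b,c,d,e,f")
    report = classify_events(sig, sig)
    assert set(report.per_gene_events.values()) == {"in_place"}
    assert report.breakpoints == 0


def test_classifier_flags_single_sign_flip_as_inverted():
    base = _sig("a,b,c,d,e,f")
    flipped = _sig("a,b,-c,d,e,f")
    events = classify_events(base, flipped).per_gene_events
    assert events["c"] == "inverted"
    assert all(v == "in_place" for g, v in events.items() if g != "c")


def test_classifier_long_move_is_translocation():
    base = _sig(",".join(f"g{i}" for i in range(12)), origin="g0")
    # move g2 five ranks downstream (well beyond the default window of 2)
    moved = _sig("g0,g1,g3,g4,g5,g6,g7,g2,g8,g9,g10,g11", origin="g0")
    events = classify_events(base, moved, window=2).per_gene_events
    assert events["g2"] == "translocated"


def test_classifier_adjacent_swap_is_shuffle():
    base = _sig("a,b,c,d,e,f")
    swapped = _sig("a,c,b,d,e,f")
    events = classify_events(base, swapped).per_gene_events
    assert events["b"] == "shuffled" and events["c"] == "shuffled"


def test_classifier_recalls_all_singleton_inversions():
    """Every singleton gene the generator inverts is labelled inverted."""
    base = _sig(",".join(f"g{i}" for i in range(15)), origin="g0")
    for seed in range(6):
        rng = random.Random(seed)
        genes = list(base.genes)
        flipped_names = set()
        for idx in rng.sample(range(1, 15), 3):
            g, s = genes[idx]
            genes[idx] = (g, -s)
            flipped_names.add(g)
        target = GeneOrderSignature(tuple(genes), "g0")
        events = classify_events(base, target).per_gene_events
        for name in flipped_names:
            assert events[name] == "inverted", (seed, name)


def test_order_string_round_trip():
    sig = _sig("cox1,-nad5,nad4l")
    assert parse_order_string(format_order_string(sig)).genes == sig.genes


def test_lg_vs_nf_fixture_distance_matches_adjacency_oracle(lg, nf):
    """Breakpoint distance between the two limpets equals an independent
    adjacency count done directly on the order tuples."""
    shared = set(signature(lg).symbols) & set(signature(nf).symbols)
    s1 = signature(lg, shared_set=shared)
    s2 = signature(nf, shared_set=shared)

    def adjacencies(sig):
        out = set()
        n = len(sig.genes)
        for i in range(n):
            a, b = sig.genes[i], sig.genes[(i + 1) % n]
            out.add(((a[0], a[1]), (b[0], b[1])))
            out.add(((b[0], -b[1]), (a[0], -a[1])))
        return out

    shared_adj = len(adjacencies(s1) & adjacencies(s2)) // 2
    expected = len(s1) - shared_adj
    assert breakpoint_distance(s1, s2) == expected
    assert breakpoint_distance(s1, s2) > 0  # heavily rearranged pair
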