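"""Nei-Gojobori site/difference counting against an independent
brute-force oracle, plus parameter-recovery properties."""

import itertools
import math
import random

import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq

from mitochar.kaks import count_differences, count_sites, kaks

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_BASES = "ACGT"


def _aa(codon: str) -> str:
    """Oracle translation, straight from Biopython's table."""
    if codon in _TABLE5.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=5))


def _oracle_sites(codon: str) -> tuple[float, float]:
    """Independent per-position enumeration of synonymous site fractions."""
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) != "*":
                outcomes.append(_aa(mut) == _aa(codon))
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def _oracle_differences(c1: str, c2: str) -> tuple[float, float]:
    """Exhaustive pathway enumeration: every ordering of the differing
    positions, stop-crossing pathways discarded."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return float("nan"), float("nan")
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


_NON_STOP = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _TABLE5.stop_codons
]


def test_phe_codon_has_one_third_synonymous_site(code5):
    s, n = count_sites("TTT", code5)
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_fourfold_third_position_contributes_full_site(code5):
    s, _ = count_sites("GTT", code5)  # Val: third position fully degenerate
    assert s >= 1.0
    third = sum(
        _aa("GT" + b) == "V" for b in _BASES if b != "T"
    )
    assert third == 3  # confirms the 4-fold degeneracy the site count uses


def test_sites_sum_to_three_for_every_codon(code5):
    for codon in _NON_STOP:
        s, n = count_sites(codon, code5)
        assert s + n == pytest.approx(3.0, abs=1e-9), codon


def test_sites_match_oracle_for_every_codon(code5):
    for codon in _NON_STOP:
        assert count_sites(codon, code5) == pytest.approx(_oracle_sites(codon)), codon


def test_stop_codon_rejected(code5):
    with pytest.raises(ValueError):
        count_sites("TAA", code5)


def test_single_synonymous_difference(code5):
    assert count_differences("TTT", "TTC", code5) == (1.0, 0.0)


def test_identical_codons_no_differences(code5):
    assert count_differences("TTT", "TTT", code5) == (0.0, 0.0)


def test_differences_match_pathway_oracle_on_all_pairs(code5):
    """Pathway-averaged Sd/Nd equals exhaustive enumeration for a seeded
    sample of codon pairs covering 1, 2 and 3 differing positions."""
    rng = random.Random(42)
    pairs = [(rng.choice(_NON_STOP), rng.choice(_NON_STOP)) for _ in range(300)]
    for c1, c2 in pairs:
        exp_sd, exp_nd = _oracle_differences(c1, c2)
        if math.isnan(exp_sd):
            continue
        got_sd, got_nd = count_differences(c1, c2, code5)
        assert got_sd == pytest.approx(exp_sd), (c1, c2)
        assert got_nd == pytest.approx(exp_nd), (c1, c2)
        n_diff = sum(a != b for a, b in zip(c1, c2))
        assert got_sd + got_nd == pytest.approx(n_diff, abs=1e-9)


def test_five_codon_pair_equals_first_principles_oracle(code5):
    """Full Ka/Ks on a small pair equals an oracle assembled from the
    independent site and pathway enumerations plus the Jukes-Cantor map."""
    s1 = "ATGTTTGGACGAATT"
    s2 = "ATGTTCGGGCGAACT"
    c1 = [s1[i : i + 3] for i in range(0, 15, 3)]
    c2 = [s2[i : i + 3] for i in range(0, 15, 3)]
    S = sum(_oracle_sites(c)[0] for c in c1 + c2) / 2
    N = sum(_oracle_sites(c)[1] for c in c1 + c2) / 2
    Sd = sum(_oracle_differences(a, b)[0] for a, b in zip(c1, c2))
    Nd = sum(_oracle_differences(a, b)[1] for a, b in zip(c1, c2))
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    result = kaks(s1, s2, code5)
    assert result.S == pytest.approx(S)
    assert result.N == pytest.approx(N)
    assert result.Sd == pytest.approx(Sd)
    assert result.Nd == pytest.approx(Nd)
    assert result.Ks == pytest.approx(jc(Sd / S))
    assert result.Ka == pytest.approx(jc(Nd / N))
    assert result.ratio == pytest.approx(jc(Nd / N) / jc(Sd / S))


def test_identical_sequences_zero_distances_undefined_ratio(code5):
    r = kaks("ATGAAATTT", "ATGAAATTT", code5)
    assert r.Ka == 0.0 and r.Ks == 0.0 and r.ratio is None


def test_one_synonymous_change_gives_zero_ka(code5):
    base = "GTT" * 100
    mutated = "GTC" + "GTT" * 99  # third-position Val change: synonymous
    r = kaks(base, mutated, code5)
    assert r.Ka == 0.0 and r.Ks > 0.0 and r.ratio == 0.0


def test_symmetry_in_all_fields(code5):
    rng = random.Random(7)
    s1 = "".join(rng.choice(_NON_STOP) for _ in range(30))
    s2 = "".join(rng.choice(_NON_STOP) for _ in range(30))
    a, b = kaks(s1, s2, code5), kaks(s2, s1, code5)
    assert (a.S, a.N, a.Sd, a.Nd, a.Ks, a.Ka, a.ratio) == (
        b.S, b.N, b.Sd, b.Nd, b.Ks, b.Ka, b.ratio,
    )


def test_synonymous_only_mutation_recovers_ka_zero(code5):
    """Mutating only fully degenerate third positions leaves Ka at 0."""
    rng = random.Random(3)
    fourfold = ["GT", "GC", "GG", "CC", "CG", "CT", "AC", "TC"]
    codons = [rng.choice(fourfold) + rng.choice(_BASES) for _ in range(80)]
    mutated = [
        c[:2] + rng.choice([b for b in _BASES if b != c[2]]) if i % 6 == 0 else c
        for i, c in enumerate(codons)
    ]
    r = kaks("".join(codons), "".join(mutated), code5)
    assert r.Ka == 0.0 and r.Ks > 0.0


def test_nonsynonymous_only_mutation_recovers_ks_zero(code5):
    # first-position changes between amino-acid families, no stop risk
    s1 = "TTT" * 40  # Phe
    s2 = "GTT" * 40  # Val: one nonsynonymous difference per codon
    r = kaks(s1, s2, code5)
    assert r.Ks == 0.0 and r.Ka > 0.0
    assert r.Sd == 0.0 and r.Nd == 40.0


def test_ks_monotone_in_added_synonymous_differences(code5):
    base = "GTT" * 60
    previous = -1.0
    for k in (1, 5, 10, 20):
        mutated = "GTC" * k + "GTT" * (60 - k)
        ks = kaks(base, mutated, code5).Ks
        assert ks > previous
        previous = ks


def test_alignment_validation(code5):
    with pytest.raises(ValueError, match="lengths differ"):
        kaks("ATGAAA", "ATG", code5)
    with pytest.raises(ValueError, match="divisible"):
        kaks("ATGA", "ATGA", code5)
    with pytest.raises(ValueError, match="stop"):
        kaks("ATGTAAAAA", "ATGAAAAAA", code5)
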