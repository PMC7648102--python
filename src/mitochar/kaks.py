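"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

Synonymous and nonsynonymous *sites* are counted per codon as the expected
fraction of single-base changes that preserve the amino acid (changes to a
stop codon are excluded from both numerator and denominator).
*Differences* between two aligned codons are averaged over all orderings of
the differing positions (1, 2 or 6 pathways), skipping pathways that pass
through a stop codon.  The resulting proportions pS = Sd/S and pN = Nd/N
are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4) ln(1 - 4p/3); Ka/Ks < 1 indicates purifying selection, > 1
positive selection.

The alignment is assumed given: gapless, in frame, equal lengths, no
internal stop codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .codons import GeneticCode

__all__ = ["KaKsResult", "count_sites", "count_differences", "kaks", "kaks_report"]

_BASES = "ACGT"


@dataclass(frozen=True)
class KaKsResult:
    """Site/difference counts and corrected distances for one CDS pair.

    ``Ks``/``Ka`` are ``None`` when the Jukes–Cantor correction saturates
    (p >= 3/4); ``ratio`` is ``None`` when Ks is zero or undefined.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    method: str = "NG86 + Jukes-Cantor"

    @property
    def saturated(self) -> bool:
        return self.Ks is None and self.pS >= 0.75 or self.Ka is None and self.pN >= 0.75


def count_sites(codon: str, code: GeneticCode) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Per position, the synonymous fraction is (synonymous single-base
    changes not creating a stop) / (single-base changes not creating a
    stop); the two fractions per position sum to 1, so the totals sum to 3.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = code.translate(codon)
    syn = 0.0
    for pos in range(3):
        syn_changes = 0
        valid_changes = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            valid_changes += 1
            if code.translate(mutant) == aa:
                syn_changes += 1
        if valid_changes:
            syn += syn_changes / valid_changes
    return syn, 3.0 - syn


def count_differences(
    c1: str, c2: str, code: GeneticCode, exclude_stop_pathways: bool = True
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    codons.

    All orderings of the differing positions are enumerated; each step of a
    pathway is classified by whether the amino acid changes.  Pathways that
    pass through a stop codon are excluded (unless every pathway would be,
    in which case all are kept so that Sd + Nd equals the Hamming
    distance).
    """
    c1, c2 = c1.upper(), c2.upper()
    if code.is_stop(c1) or code.is_stop(c2):
        raise ValueError("stop codons cannot be compared")
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if exclude_stop_pathways and code.is_stop(nxt):
                return None
            if code.translate(current) == code.translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    pathways = [walk(order) for order in permutations(diff_positions)]
    valid = [p for p in pathways if p is not None]
    if not valid:
        valid = [
            p
            for order in permutations(diff_positions)
            if (p := _walk_through_stops(c1, c2, order, code)) is not None
        ]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _walk_through_stops(c1, c2, order, code):
    syn = nonsyn = 0.0
    current = c1
    for pos in order:
        nxt = current[:pos] + c2[pos] + current[pos + 1 :]
        a, b = code.codon_to_aa[current], code.codon_to_aa[nxt]
        if a == b:
            syn += 1
        else:
            nonsyn += 1
        current = nxt
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks(seq1: str, seq2: str, code: GeneticCode | None = None) -> KaKsResult:
    """NG86 Ka/Ks with Jukes–Cantor correction for one in-frame CDS pair."""
    code = code or GeneticCode(5)
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence lengths differ: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3:
        raise ValueError(f"alignment length {len(seq1)} not divisible by 3")
    codons1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]
    for name, codons in (("seq1", codons1), ("seq2", codons2)):
        for i, c in enumerate(codons):
            if code.is_stop(c):
                raise ValueError(f"{name}: internal stop codon {c} at codon {i + 1}")

    s1 = n1 = s2 = n2 = 0.0
    sd = nd = 0.0
    for a, b in zip(codons1, codons2):
        sa, na = count_sites(a, code)
        sb, nb = count_sites(b, code)
        s1 += sa
        n1 += na
        s2 += sb
        n2 += nb
        d_s, d_n = count_differences(a, b, code)
        sd += d_s
        nd += d_n
    S = (s1 + s2) / 2.0
    N = (n1 + n2) / 2.0
    pS = sd / S if S else 0.0
    pN = nd / N if N else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    ratio = None
    if Ks is not None and Ks > 0 and Ka is not None:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio)


def kaks_report(pairs: dict[str, tuple[str, str]], code: GeneticCode | None = None) -> str:
    """Tab-separated Ka/Ks table over named CDS pairs
    (Gene, S, N, Sd, Nd, Ks, Ka, KaKs)."""
    code = code or GeneticCode(5)
    lines = ["Gene\tS\tN\tSd\tNd\tKs\tKa\tKaKs"]

    def fmt(x):
        return "NA" if x is None else f"{x:.4f}"

    for gene, (a, b) in pairs.items():
        r = kaks(a, b, code)
        lines.append(
            f"{gene}\t{r.S:.2f}\t{r.N:.2f}\t{r.Sd:.2f}\t{r.Nd:.2f}"
            f"\t{fmt(r.Ks)}\t{fmt(r.Ka)}\t{fmt(r.ratio)}"
        )
    return "\n".join(lines) + "\n"
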