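"""Rule-based secondary-structure checks for tRNAs and hairpins.

This is a deliberately simplified, auditable folder — inverted-repeat
search with Watson–Crick and GU (wobble) pairing — not a thermodynamic
one.  It answers the two structural questions a mitogenome description
asks: does a short non-coding sequence (the light-strand replication
origin, OL) fold into a hairpin, and does a tRNA carry all four cloverleaf
arms (metazoan mitochondrial trnS1/trnS2 typically lack the dihydrouridine
(DHU) arm)?
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HairpinResult", "ArmReport", "find_hairpin", "cloverleaf_report"]

_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),  # GU wobble (DNA alphabet)
}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def paired(a: str, b: str, allow_GU: bool = True) -> bool:
    return (a, b) in (_PAIRS if allow_GU else _WC)


@dataclass(frozen=True)
class HairpinResult:
    """Best stem-loop placement found in a sequence.

    ``stem_start`` is the 1-based offset of the 5' stem arm;
    ``paired_fraction`` is the fraction of stem positions paired (1.0 for
    the exhaustive perfect-stem search).
    """

    stem_length: int
    loop_length: int
    stem_start: int
    paired_fraction: float = 1.0


def find_hairpin(
    seq: str,
    min_stem: int = 5,
    max_loop: int = 10,
    allow_GU: bool = True,
) -> HairpinResult | None:
    """Exhaustive inverted-repeat scan for the best hairpin.

    All (loop position, loop length) placements are tried and the stem is
    extended outward while bases pair; the maximal-stem placement wins,
    ties broken by smaller loop, then leftmost position.  Returns ``None``
    when no placement reaches ``min_stem`` (in particular when the
    sequence is shorter than ``2 * min_stem + 3``).
    """
    if min_stem < 3 or max_loop < 3:
        raise ValueError("min_stem and max_loop must each be >= 3")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_stem + 3:
        return None
    best: tuple[int, int, int] | None = None  # (-stem, loop, start)
    for loop_start in range(min_stem, n - min_stem):
        for loop_len in range(3, max_loop + 1):
            stem = 0
            while (
                loop_start - 1 - stem >= 0
                and loop_start + loop_len + stem < n
                and paired(
                    seq[loop_start - 1 - stem],
                    seq[loop_start + loop_len + stem],
                    allow_GU,
                )
            ):
                stem += 1
            if stem >= min_stem:
                cand = (-stem, loop_len, loop_start - stem)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    stem, loop_len, start0 = -best[0], best[1], best[2]
    return HairpinResult(stem_length=stem, loop_length=loop_len, stem_start=start0 + 1)


@dataclass(frozen=True)
class ArmReport:
    """Cloverleaf arm presence for one tRNA (stem lengths in bp, or None
    when the arm is absent)."""

    acceptor_stem: int | None
    dhu_stem: int | None
    anticodon_stem: int | None
    tpsic_stem: int | None
    anticodon: str

    @property
    def cloverleaf(self) -> bool:
        return all(
            s is not None
            for s in (self.acceptor_stem, self.dhu_stem, self.anticodon_stem, self.tpsic_stem)
        )


def _anticodon_anchor(seq: str, anticodon: str) -> int:
    """0-based start of the anticodon occurrence nearest mid-sequence."""
    hits = []
    start = 0
    while True:
        i = seq.find(anticodon, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    if not hits:
        raise ValueError(f"anticodon {anticodon!r} not found in tRNA sequence")
    mid = (len(seq) - len(anticodon)) / 2
    return min(hits, key=lambda i: abs(i - mid))


def cloverleaf_report(
    trna_seq: str,
    anticodon: str,
    allow_GU: bool = True,
    acceptor_min: int = 6,
    arm_min: int = 3,
    anticodon_stem_min: int = 4,
) -> ArmReport:
    """Check the four cloverleaf arms of a tRNA sequence.

    The anticodon is anchored at its occurrence nearest mid-sequence with
    a canonical 7 nt loop centered on it; the anticodon stem is the run of
    pairs across that loop (present when >= ``anticodon_stem_min``).  The
    acceptor stem pairs the 5' and 3' termini (up to one mismatch,
    present when >= ``acceptor_min`` pairs).  The DHU and T-Psi-C arms are
    sought as hairpins (stem >= ``arm_min``) in the regions between the
    acceptor 5' arm and the anticodon arm, and between the anticodon arm
    and the acceptor 3' arm, respectively.
    """
    seq = trna_seq.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    if not 55 <= len(seq) <= 95:
        raise ValueError(
            f"tRNA length {len(seq)} outside the plausible range [55, 95]"
        )
    a = _anticodon_anchor(seq, anticodon)
    loop_start, loop_end = a - 2, a + 5  # 7 nt loop centered on the anticodon

    # anticodon stem: consecutive pairs closing the loop
    ac_stem = 0
    while (
        loop_start - 1 - ac_stem >= 0
        and loop_end + ac_stem < len(seq)
        and paired(seq[loop_start - 1 - ac_stem], seq[loop_end + ac_stem], allow_GU)
    ):
        ac_stem += 1
    anticodon_stem = ac_stem if ac_stem >= anticodon_stem_min else None

    # acceptor stem: 5' terminus against 3' terminus, <= 1 mismatch, <= 8 rungs
    acc_pairs = 0
    mismatches = 0
    for k in range(min(8, len(seq) // 2)):
        if paired(seq[k], seq[len(seq) - 1 - k], allow_GU):
            acc_pairs += 1
        else:
            mismatches += 1
            if mismatches > 1:
                break
    acceptor = acc_pairs if acc_pairs >= acceptor_min else None

    ac_arm_lo = loop_start - max(ac_stem, anticodon_stem_min)
    ac_arm_hi = loop_end + max(ac_stem, anticodon_stem_min)

    dhu_window = seq[7 : max(7, ac_arm_lo)]
    dhu_hp = find_hairpin(dhu_window, min_stem=arm_min, max_loop=8, allow_GU=allow_GU)
    dhu = dhu_hp.stem_length if dhu_hp else None

    tpsic_window = seq[min(len(seq) - 7, ac_arm_hi) : len(seq) - 7]
    tpsic_hp = find_hairpin(tpsic_window, min_stem=arm_min, max_loop=9, allow_GU=allow_GU)
    tpsic = tpsic_hp.stem_length if tpsic_hp else None

    return ArmReport(
        acceptor_stem=acceptor,
        dhu_stem=dhu,
        anticodon_stem=anticodon_stem,
        tpsic_stem=tpsic,
        anticodon=anticodon,
    )


def cloverleaf_table(rows) -> str:
    """Tab-separated arm report (Gene, Anticodon, Acceptor, DHU,
    AnticodonStem, TPsiC, Cloverleaf) from (gene, ArmReport) pairs."""
    lines = ["Gene\tAnticodon\tAcceptor\tDHU\tAnticodonStem\tTPsiC\tCloverleaf"]

    def fmt(x):
        return "absent" if x is None else str(x)

    for gene, report in rows:
        lines.append(
            "\t".join(
                [
                    gene,
                    report.anticodon,
                    fmt(report.acceptor_stem),
                    fmt(report.dhu_stem),
                    fmt(report.anticodon_stem),
                    fmt(report.tpsic_stem),
                    "yes" if report.cloverleaf else "no",
                ]
            )
        )
    return "\n".join(lines) + "\n"
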