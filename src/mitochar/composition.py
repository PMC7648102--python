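"""Base composition, A+T content, and strand-asymmetry skews.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C) measure the
compositional asymmetry between the two strands of a genome or region; a
negative AT skew means the counted strand carries more T than A.  Per-gene
rows are computed on the gene's sense (coding) strand, the whole-genome row
on the deposited strand, which is why their signs can disagree.

Ambiguity code N is counted separately and excluded from all denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .records import MitogenomeRecord

__all__ = [
    "BaseComposition",
    "compose",
    "skew",
    "skew_from_percentages",
    "region_composition_table",
    "composition_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (report convention, unlike bankers')."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BaseComposition:
    """Counts and derived statistics for one sequence region.

    ``at_skew``/``gc_skew`` are ``None`` when the corresponding base pair is
    entirely absent (zero denominator).
    """

    n_A: int
    n_T: int
    n_G: int
    n_C: int
    n_other: int

    @property
    def total(self) -> int:
        return self.n_A + self.n_T + self.n_G + self.n_C

    @property
    def size(self) -> int:
        return self.total + self.n_other

    @property
    def pct_A(self) -> float:
        return 100.0 * self.n_A / self.total

    @property
    def pct_T(self) -> float:
        return 100.0 * self.n_T / self.total

    @property
    def pct_G(self) -> float:
        return 100.0 * self.n_G / self.total

    @property
    def pct_C(self) -> float:
        return 100.0 * self.n_C / self.total

    @property
    def at_pct(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def at_skew(self) -> float | None:
        return skew(self.n_A, self.n_T)

    @property
    def gc_skew(self) -> float | None:
        return skew(self.n_G, self.n_C)


def skew(x: float, y: float) -> float | None:
    """(x - y)/(x + y), or None when the denominator is zero."""
    if x + y == 0:
        return None
    return (x - y) / (x + y)


def skew_from_percentages(pct_x: float, pct_y: float) -> float | None:
    """Skew recomputed from printed percentages (verification path when no
    sequence is available)."""
    return skew(pct_x, pct_y)


def compose(sequence: str) -> BaseComposition:
    """Count bases of a DNA string (case-insensitive; N excluded from
    percentages and skews)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    return BaseComposition(
        n_A=counts["A"],
        n_T=counts["T"],
        n_G=counts["G"],
        n_C=counts["C"],
        n_other=len(sequence) - acgt,
    )


def region_composition_table(
    record: MitogenomeRecord,
) -> list[tuple[str, BaseComposition]]:
    """Composition rows: whole genome, each PCG, then concatenated tRNAs,
    rRNAs and PCGs (each gene taken sense-strand, in genome order).

    Requires the record to carry its sequence.
    """
    if record.sequence is None:
        raise ValueError(f"record {record.organism!r} has no sequence")
    rows: list[tuple[str, BaseComposition]] = [
        ("Mitogenome", compose(record.sequence))
    ]
    concat: dict[str, list[str]] = {"tRNA": [], "rRNA": [], "PCG": []}
    for f in record.features:
        if f.category in concat:
            concat[f.category].append(record.feature_sequence(f))
        if f.category == "PCG":
            rows.append((f.name, compose(record.feature_sequence(f))))
    for label, key in (("tRNAs", "tRNA"), ("rRNAs", "rRNA"), ("PCGs", "PCG")):
        if concat[key]:
            rows.append((label, compose("".join(concat[key]))))
    return rows


_REPORT_COLUMNS = ("Region", "Size", "A%", "T%", "G%", "C%", "A+T%", "AT-skew", "GC-skew")


def composition_report(record: MitogenomeRecord) -> str:
    """Tab-separated composition report (percentages 2 d.p., skews 3 d.p.)."""

    def fmt_pct(x: float) -> str:
        return f"{round_half_away(x, 2):.2f}"

    def fmt_skew(x: float | None) -> str:
        return "NA" if x is None else f"{round_half_away(x, 3):.3f}"

    lines = ["\t".join(_REPORT_COLUMNS)]
    for region, bc in region_composition_table(record):
        lines.append(
            "\t".join(
                [
                    region,
                    str(bc.size),
                    fmt_pct(bc.pct_A),
                    fmt_pct(bc.pct_T),
                    fmt_pct(bc.pct_G),
                    fmt_pct(bc.pct_C),
                    fmt_pct(bc.at_pct),
                    fmt_skew(bc.at_skew),
                    fmt_skew(bc.gc_skew),
                ]
            )
        )
    return "\n".join(lines) + "\n"
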