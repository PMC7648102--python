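"""Circular-coordinate arithmetic over annotated mitogenomes.

Reproduces the Length and Intergenic columns of a published annotation
table from coordinates alone, localizes the control region as the largest
unannotated circular gap, and summarizes the annotation per category.

Conventions (1-based inclusive coordinates throughout):

* length of a non-wrapping feature: ``stop - start + 1``;
  wrapping (circular records only): ``(genome_length - start + 1) + stop``.
* intergenic gap between consecutive features A, B in genome order:
  ``start(B) - stop(A) - 1``; negative values are overlaps.  The final
  entry wraps around the origin.  The gap is attributed to the upstream
  feature, matching the row placement of published tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import GeneFeature, MitogenomeRecord

__all__ = [
    "GapEntry",
    "ControlRegion",
    "AnnotationSummary",
    "feature_length",
    "gap_report",
    "locate_control_region",
    "annotation_summary",
    "annotation_report",
]


@dataclass(frozen=True)
class GapEntry:
    """Signed spacer between two consecutive features (negative = overlap)."""

    after_feature: str
    before_feature: str
    gap_bp: int


@dataclass(frozen=True)
class ControlRegion:
    """Largest unannotated circular gap with derived coordinates."""

    after_feature: str | None
    before_feature: str | None
    length_bp: int
    start: int | None
    stop: int | None

    @property
    def found(self) -> bool:
        return self.length_bp > 0


@dataclass(frozen=True)
class AnnotationSummary:
    counts_per_category: dict
    trna_length_min: int | None
    trna_length_max: int | None
    pcg_total_length: int
    pcg_fraction: float
    rrna_total_length: int
    trna_total_length: int


def feature_length(
    feature: GeneFeature, genome_length: int, circular: bool = True
) -> int:
    """Length in bp of a feature, handling circular wrap-around."""
    if feature.wraps or feature.stop < feature.start:
        if not circular:
            raise ValueError(
                f"{feature.name}: wrapping feature on a non-circular genome"
            )
        return (genome_length - feature.start + 1) + feature.stop
    return feature.stop - feature.start + 1


def gap_report(record: MitogenomeRecord) -> list[GapEntry]:
    """Signed intergenic gaps between consecutive features, one per feature.

    The entry attributed to the last feature wraps around the circular
    origin.  Fewer than two features yield an empty list.
    """
    feats = record.features
    if len(feats) < 2:
        return []
    entries: list[GapEntry] = []
    for a, b in zip(feats, feats[1:]):
        entries.append(GapEntry(a.name, b.name, b.start - a.stop - 1))
    last, first = feats[-1], feats[0]
    wrap_gap = (record.genome_length - last.stop) + (first.start - 1)
    entries.append(GapEntry(last.name, first.name, wrap_gap))
    return entries


def locate_control_region(record: MitogenomeRecord) -> ControlRegion:
    """Find the putative control region: the largest positive circular gap.

    Mitogenome annotations commonly leave the A+T-rich control region
    unannotated; it then shows up as the dominant intergenic spacer.  When
    every gap is <= 0 the result has ``found == False``.
    """
    gaps = gap_report(record)
    if not gaps:
        return ControlRegion(None, None, 0, None, None)
    best = max(gaps, key=lambda g: g.gap_bp)
    if best.gap_bp <= 0:
        return ControlRegion(None, None, 0, None, None)
    upstream = record[best.after_feature]
    g = record.genome_length
    start = upstream.stop % g + 1
    stop = (start - 1 + best.gap_bp - 1) % g + 1
    return ControlRegion(best.after_feature, best.before_feature, best.gap_bp, start, stop)


def annotation_summary(record: MitogenomeRecord) -> AnnotationSummary:
    """Per-category counts and length totals for a record."""
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    trna_lengths: list[int] = []
    for f in record.features:
        length = feature_length(f, record.genome_length, record.circular)
        counts[f.category] = counts.get(f.category, 0) + 1
        totals[f.category] = totals.get(f.category, 0) + length
        if f.category == "tRNA":
            trna_lengths.append(length)
    pcg_total = totals.get("PCG", 0)
    return AnnotationSummary(
        counts_per_category=counts,
        trna_length_min=min(trna_lengths) if trna_lengths else None,
        trna_length_max=max(trna_lengths) if trna_lengths else None,
        pcg_total_length=pcg_total,
        pcg_fraction=100.0 * pcg_total / record.genome_length,
        rrna_total_length=totals.get("rRNA", 0),
        trna_total_length=totals.get("tRNA", 0),
    )


_REPORT_COLUMNS = (
    "Gene",
    "Strand",
    "Start",
    "Stop",
    "Length",
    "StartCodon",
    "StopCodon",
    "Intergenic",
    "Anticodon",
)


def annotation_report(record: MitogenomeRecord) -> str:
    """Tab-separated per-genome annotation report (published-table layout).

    Length and Intergenic are recomputed from the coordinates.
    """
    gaps = {g.after_feature: g.gap_bp for g in gap_report(record)}
    lines = ["\t".join(_REPORT_COLUMNS)]
    for f in record.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.strand,
                    str(f.start),
                    str(f.stop),
                    str(feature_length(f, record.genome_length, record.circular)),
                    f.start_codon or "",
                    f.stop_codon or "",
                    str(gaps.get(f.name, "")),
                    f.anticodon or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"
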