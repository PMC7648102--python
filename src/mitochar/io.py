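"""Reading and writing mitogenome annotations and sequences.

Supported formats:

* tab-separated feature tables mirroring published annotation tables
  (columns ``Gene``, ``Strand``, ``Start``, ``Stop``; optionally
  ``Category``, ``Anticodon``, ``StartCodon``, ``StopCodon``; extra columns
  are ignored).  Record-level metadata (organism, genome length,
  circularity) travels in ``#`` comment lines as tab-separated ``key=value``
  pairs.
* GenBank flat files (via Biopython), including ``complement(...)`` and
  origin-spanning ``join(...)`` locations.
* FASTA, sequence only (via Biopython).
"""

from __future__ import annotations

import io as _io

from Bio import SeqIO

from .records import (
    GeneFeature,
    MitogenomeRecord,
    canonical_name,
    infer_category,
    validate,
)

__all__ = [
    "FeatureTableError",
    "parse_feature_table",
    "write_feature_table",
    "parse_genbank",
    "read_fasta",
    "write_fasta",
]

_TABLE_COLUMNS = (
    "Gene",
    "Category",
    "Strand",
    "Start",
    "Stop",
    "Anticodon",
    "StartCodon",
    "StopCodon",
)
_REQUIRED = ("Gene", "Strand", "Start", "Stop")


class FeatureTableError(ValueError):
    """Malformed feature table or GenBank input."""


def _parse_meta(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        for token in line.lstrip("#").strip().split("\t"):
            if "=" in token:
                key, value = token.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def parse_feature_table(
    table_text: str,
    genome_length: int | None = None,
    organism: str | None = None,
    circular: bool | None = None,
    canonicalize: bool = True,
) -> MitogenomeRecord:
    """Parse a tab-separated feature table into a :class:`MitogenomeRecord`.

    ``genome_length``/``organism``/``circular`` override any values found in
    ``#`` metadata lines.  When the ``Category`` column is absent the
    category is inferred from the gene-name prefix (trn -> tRNA, rrn ->
    rRNA, CR -> control_region, else PCG).

    Raises :class:`FeatureTableError` naming the missing column, the
    offending row, or the duplicated gene names.
    """
    comment_lines = [l for l in table_text.splitlines() if l.startswith("#")]
    rows = [l for l in table_text.splitlines() if l.strip() and not l.startswith("#")]
    meta = _parse_meta(comment_lines)
    if organism is None:
        organism = meta.get("organism", "unknown")
    if genome_length is None:
        if "genome_length" not in meta:
            raise FeatureTableError(
                "genome_length not given and not present in table metadata"
            )
        genome_length = int(meta["genome_length"])
    if circular is None:
        circular = meta.get("circular", "true").lower() in ("true", "1", "yes")

    if not rows:
        return MitogenomeRecord(organism, genome_length, [], circular)

    header = rows[0].split("\t")
    for col in _REQUIRED:
        if col not in header:
            raise FeatureTableError(f"missing required column {col!r}")
    idx = {col: header.index(col) for col in header}

    def cell(parts: list[str], col: str) -> str | None:
        if col not in idx or idx[col] >= len(parts):
            return None
        value = parts[idx[col]].strip()
        return value or None

    features: list[GeneFeature] = []
    for row_no, row in enumerate(rows[1:], start=1):
        parts = row.split("\t")
        name = cell(parts, "Gene")
        if not name:
            raise FeatureTableError(f"row {row_no}: empty Gene cell")
        if canonicalize:
            name = canonical_name(name)
        try:
            start = int(cell(parts, "Start"))
            stop = int(cell(parts, "Stop"))
        except (TypeError, ValueError):
            raise FeatureTableError(
                f"row {row_no} ({name}): non-integer coordinate "
                f"Start={cell(parts, 'Start')!r} Stop={cell(parts, 'Stop')!r}"
            ) from None
        strand = cell(parts, "Strand") or "+"
        # tolerate the typographic minus used in print
        strand = {"−": "-", "+": "+", "-": "-"}.get(strand, strand)
        features.append(
            GeneFeature(
                name=name,
                strand=strand,
                start=start,
                stop=stop,
                category=cell(parts, "Category"),
                anticodon=cell(parts, "Anticodon"),
                start_codon=cell(parts, "StartCodon"),
                stop_codon=cell(parts, "StopCodon"),
            )
        )

    names = [f.name for f in features]
    duplicates = sorted({n for n in names if names.count(n) > 1})
    if duplicates:
        raise FeatureTableError(f"duplicate gene names: {', '.join(duplicates)}")
    return MitogenomeRecord(organism, genome_length, features, circular)


def write_feature_table(record: MitogenomeRecord) -> str:
    """Serialize a record to the tab-separated feature-table format.

    Round-trips: ``parse_feature_table(write_feature_table(r))`` reproduces
    every feature field of ``r``.
    """
    lines = [
        f"# organism={record.organism}\tgenome_length={record.genome_length}"
        f"\tcircular={str(record.circular).lower()}",
        "\t".join(_TABLE_COLUMNS),
    ]
    for f in record.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.category,
                    f.strand,
                    str(f.start),
                    str(f.stop),
                    f.anticodon or "",
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


_GENBANK_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control_region"}


def _genbank_feature_name(feat) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def parse_genbank(text: str, canonicalize: bool = True) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    ``complement(...)`` locations map to strand '-'; a ``join(...)`` across
    the circular origin yields a single wrapping feature (``stop < start``).
    CDS/tRNA/rRNA/D-loop features are used; bare ``gene`` features are only
    kept for genes with no typed counterpart.  Duplicate gene names receive
    numeric suffixes in ascending-start order (trnM -> trnM1, trnM2).
    """
    try:
        seq_record = SeqIO.read(_io.StringIO(text), "genbank")
    except ValueError as exc:
        raise FeatureTableError(f"unparseable GenBank input: {exc}") from exc

    genome_length = len(seq_record)
    try:
        sequence = str(seq_record.seq)
        if not sequence or set(sequence) == {"N"}:
            sequence = None
    except Bio_UndefinedSequenceError:  # pragma: no cover - name bound below
        sequence = None

    circular = seq_record.annotations.get("topology", "circular") == "circular"
    organism = seq_record.annotations.get("organism", seq_record.id or "unknown")

    features: list[GeneFeature] = []
    covered: list[tuple[int, int]] = []
    typed = [f for f in seq_record.features if f.type in _GENBANK_TYPES]
    bare = [f for f in seq_record.features if f.type == "gene"]
    typed_names = set()

    def convert(feat, category):
        location = feat.location
        if location is None:
            raise FeatureTableError(
                f"unparseable location in feature {feat.type!r}"
            )
        parts = sorted(location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start) + 1
        stop = int(parts[-1].end)
        wraps = False
        if len(parts) > 1:
            # join over the origin: last segment ends at genome end,
            # first segment starts at 1 (after sorting by start)
            if int(parts[0].start) == 0 and int(parts[-1].end) == genome_length:
                start = int(parts[1].start) + 1 if len(parts) == 2 else int(parts[-1].start) + 1
                stop = int(parts[0].end)
                wraps = True
            else:
                raise FeatureTableError(
                    f"unsupported compound location {location}"
                )
        strand = "-" if location.strand == -1 else "+"
        name = _genbank_feature_name(feat) or f"{feat.type}_{start}"
        if canonicalize:
            name = canonical_name(name)
        anticodon = None
        if category == "tRNA" and "anticodon" in feat.qualifiers:
            raw = feat.qualifiers["anticodon"][0]
            anticodon = raw.split("seq:")[-1].rstrip(")").upper() if "seq:" in raw else raw.upper()
            anticodon = anticodon.replace("U", "T")[:3]
        return GeneFeature(
            name=name, strand=strand, start=start, stop=stop,
            category=category, anticodon=anticodon,
        )

    for feat in typed:
        gf = convert(feat, _GENBANK_TYPES[feat.type])
        features.append(gf)
        typed_names.add(gf.name)
        covered.append((gf.start, gf.stop))
    for feat in bare:
        gf = convert(feat, None)
        if gf.name in typed_names or any(
            s == gf.start and e == gf.stop for s, e in covered
        ):
            continue
        features.append(gf)

    # disambiguate duplicated gene names with numeric suffixes
    features.sort(key=lambda f: f.start)
    from collections import Counter
    from dataclasses import replace

    counts = Counter(f.name for f in features)
    seen: dict[str, int] = {}
    renamed = []
    for f in features:
        if counts[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            renamed.append(replace(f, name=f"{f.name}{seen[f.name]}"))
        else:
            renamed.append(f)

    return MitogenomeRecord(organism, genome_length, renamed, circular, sequence)


# Biopython raises this when a GenBank record declares a length but carries
# no ORIGIN block; imported lazily to keep a single import site.
try:
    from Bio.Seq import UndefinedSequenceError as Bio_UndefinedSequenceError
except ImportError:  # pragma: no cover
    class Bio_UndefinedSequenceError(Exception):
        pass


def read_fasta(text: str) -> tuple[str, str]:
    """Read the first sequence of a FASTA string -> (header, sequence)."""
    rec = next(SeqIO.parse(_io.StringIO(text), "fasta"))
    return rec.description, str(rec.seq).upper()


def write_fasta(header: str, sequence: str, width: int = 70) -> str:
    lines = [f">{header}"]
    for i in range(0, len(sequence), width):
        lines.append(sequence[i : i + width])
    return "\n".join(lines) + "\n"
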