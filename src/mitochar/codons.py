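"""Codon extraction and codon-usage statistics under mitochondrial codes.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial): AGA/AGG encode Ser, ATA Met, TGA Trp, leaving TAA/TAG as
the only stops.  Synonymous families split Ser and Leu the way codon-usage
figures conventionally do: Ser1 = AGN, Ser2 = TCN, Leu1 = CTN, Leu2 = TTR.

Invertebrate mitochondrial CDSs frequently end on an incomplete stop codon
(a bare T or TA at the gene boundary) that is completed to TAA by
post-transcriptional polyadenylation; :func:`extract_cds` recognizes these,
pads them, and reports the stop as ``"T(AA)"`` / ``"TA(A)"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .records import GeneFeature, MitogenomeRecord

__all__ = [
    "GeneticCode",
    "CdsExtract",
    "CodonCounts",
    "RscuResult",
    "extract_cds",
    "count_codons",
    "rscu",
    "aa_usage",
    "rscu_report",
]

BASES = "TCAG"

_AA1_TO_3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class GeneticCode:
    """A 64-codon translation table plus split synonymous families.

    ``codon_to_aa`` maps DNA codons to one-letter amino acids ('*' = stop);
    ``family_of`` maps a codon to its family label (e.g. 'Leu2'), and
    ``families`` maps labels to synonymous codon sets.
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.name = table.names[0]
        self.codon_to_aa: dict[str, str] = {}
        for c1 in BASES:
            for c2 in BASES:
                for c3 in BASES:
                    codon = c1 + c2 + c3
                    if codon in table.stop_codons:
                        self.codon_to_aa[codon] = "*"
                    else:
                        self.codon_to_aa[codon] = table.forward_table[codon]
        self.stop_codons = frozenset(table.stop_codons)
        self.start_codons = frozenset(table.start_codons)
        self.families: dict[str, frozenset[str]] = {}
        buckets: dict[str, set[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa == "*":
                continue
            buckets.setdefault(self._family_label(codon, aa), set()).add(codon)
        self.families = {k: frozenset(v) for k, v in buckets.items()}
        self._family_of = {
            codon: label for label, codons in self.families.items() for codon in codons
        }

    @staticmethod
    def _family_label(codon: str, aa: str) -> str:
        if aa == "S":
            return "Ser1" if codon.startswith("AG") else "Ser2"
        if aa == "L":
            return "Leu1" if codon.startswith("CT") else "Leu2"
        return _AA1_TO_3[aa]

    def family_of(self, codon: str) -> str:
        return self._family_of[codon]

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def __repr__(self) -> str:
        return f"GeneticCode(table_id={self.table_id}, name={self.name!r})"


@dataclass
class CdsExtract:
    """Codon decomposition of one CDS."""

    codons: list[str]
    start_codon: str
    stop_codon: str
    incomplete_stop: bool = False
    warnings: list[str] = field(default_factory=list)


def split_codons(cds: str, gene: str = "CDS") -> tuple[list[str], str, bool]:
    """Split a sense-strand CDS into codons, completing an incomplete stop.

    Returns ``(codons, stop_string, incomplete_flag)`` where ``stop_string``
    is e.g. ``"TAA"``, ``"T(AA)"`` or ``"TA(A)"``.
    """
    cds = cds.upper()
    remainder = len(cds) % 3
    incomplete = False
    if remainder == 1:
        if cds[-1] != "T":
            raise ValueError(
                f"{gene}: length mod 3 == 1 but trailing base is {cds[-1]!r}, not T"
            )
        cds += "AA"
        stop_string = "T(AA)"
        incomplete = True
    elif remainder == 2:
        if cds[-2:] != "TA":
            raise ValueError(
                f"{gene}: length mod 3 == 2 but trailing bases are "
                f"{cds[-2:]!r}, not TA"
            )
        cds += "A"
        stop_string = "TA(A)"
        incomplete = True
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if not incomplete:
        stop_string = codons[-1] if codons else ""
    return codons, stop_string, incomplete


def extract_cds(record: MitogenomeRecord, feature: GeneFeature | str) -> CdsExtract:
    """Extract the codon list of a protein-coding feature.

    The feature's sense-strand sequence is split into triplets; a trailing
    T/TA is treated as an incomplete stop and padded with A's.  Internal
    stop codons and a non-stop final codon are reported as warnings, not
    errors (published annotations occasionally contain them).
    """
    if isinstance(feature, str):
        feature = record[feature]
    if feature.category != "PCG":
        raise ValueError(f"{feature.name}: not a protein-coding feature")
    seq = record.feature_sequence(feature)
    codons, stop_string, incomplete = split_codons(seq, feature.name)
    warnings = []
    code = GeneticCode(5)
    for i, codon in enumerate(codons[:-1]):
        if i > 0 and code.is_stop(codon):
            warnings.append(f"internal stop codon {codon} at codon {i + 1}")
    if not incomplete and codons and not code.is_stop(codons[-1]):
        warnings.append(f"final codon {codons[-1]} is not a stop codon")
    return CdsExtract(
        codons=codons,
        start_codon=codons[0] if codons else "",
        stop_codon=stop_string,
        incomplete_stop=incomplete,
        warnings=warnings,
    )


@dataclass
class CodonCounts:
    counts: Counter
    total: int

    @classmethod
    def from_codons(cls, codons) -> "CodonCounts":
        c = Counter(codons)
        return cls(counts=c, total=sum(c.values()))


def count_codons(
    extracts, code: GeneticCode | None = None, include_start_stop: bool = False
) -> CodonCounts:
    """Pool codon counts over CDS extracts.

    By default the initiation codon and the (possibly padded) termination
    codon of each CDS are excluded, so counts reflect internal codon usage
    only; ``include_start_stop=True`` keeps them.
    """
    pooled: Counter = Counter()
    for ext in extracts:
        codons = ext.codons if include_start_stop else ext.codons[1:-1]
        pooled.update(codons)
    if code is not None and not include_start_stop:
        for stop in code.stop_codons:
            pooled.pop(stop, None)
    return CodonCounts(counts=pooled, total=sum(pooled.values()))


@dataclass
class RscuResult:
    values: dict[str, float]
    zero_families: frozenset[str]


def rscu(counts: CodonCounts, code: GeneticCode) -> RscuResult:
    """Relative synonymous codon usage.

    RSCU(c) = n_c * k / sum over c's synonymous family, where k is the
    family size; 1 means no bias.  Families with zero total get RSCU 0 for
    all members and are flagged.  Stop codons are excluded.
    """
    values: dict[str, float] = {}
    zero: set[str] = set()
    for label, codons in code.families.items():
        family_total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        if family_total == 0:
            zero.add(label)
            for c in codons:
                values[c] = 0.0
        else:
            for c in codons:
                values[c] = counts.counts.get(c, 0) * k / family_total
    return RscuResult(values=values, zero_families=frozenset(zero))


def aa_usage(counts: CodonCounts, code: GeneticCode) -> list[tuple[str, int, float]]:
    """Amino-acid usage as (family label, count, codons-per-thousand),
    sorted by descending frequency.  Ser and Leu are split into their
    Ser1/Ser2 and Leu1/Leu2 families."""
    if counts.total == 0:
        raise ValueError("empty codon counts")
    per_family: Counter = Counter()
    for codon, n in counts.counts.items():
        if code.is_stop(codon):
            continue
        per_family[code.family_of(codon)] += n
    rows = [
        (label, n, 1000.0 * n / counts.total)
        for label, n in per_family.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def rscu_report(record: MitogenomeRecord, code: GeneticCode | None = None) -> str:
    """Tab-separated codon-usage report over all PCGs of a record
    (AminoAcid, Codon, Count, CDspT, RSCU)."""
    code = code or GeneticCode(5)
    extracts = [extract_cds(record, f) for f in record.features_of("PCG")]
    counts = count_codons(extracts, code)
    result = rscu(counts, code)
    lines = ["AminoAcid\tCodon\tCount\tCDspT\tRSCU"]
    for label in sorted(code.families):
        for codon in sorted(code.families[label]):
            n = counts.counts.get(codon, 0)
            cdspt = 1000.0 * n / counts.total if counts.total else 0.0
            lines.append(
                f"{label}\t{codon}\t{n}\t{cdspt:.2f}\t{result.values[codon]:.3f}"
            )
    return "\n".join(lines) + "\n"
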