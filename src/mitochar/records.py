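"""Core domain types for circular mitogenome annotations.

A :class:`MitogenomeRecord` is the unit every analysis stage consumes: a
circular genome of known length, an ordered list of :class:`GeneFeature`
annotations (1-based, inclusive coordinates, as in GenBank and in published
annotation tables), and an optional nucleotide sequence.

Typical metazoan mitogenomes carry 13 protein-coding genes (PCGs), 22 tRNAs,
2 rRNAs and one large non-coding control region; limpet (Lottiidae)
mitogenomes add duplicated tRNAs (e.g. trnM1/trnM2), which is why duplicate
gene names are disambiguated with numeric suffixes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "CATEGORIES",
    "GeneFeature",
    "MitogenomeRecord",
    "canonical_name",
    "infer_category",
    "validate",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region", "other")

#: Protein-coding gene symbols of the standard metazoan mitochondrial set.
PCG_NAMES = frozenset(
    {
        "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
        "atp6", "atp8", "cytb",
    }
)

#: The 22 standard mitochondrial tRNA symbols (Leu and Ser come in two
#: isoacceptor families, conventionally trnL1/trnL2 and trnS1/trnS2).
STANDARD_TRNAS = frozenset(
    "trn" + x
    for x in (
        "A C D E F G H I K L1 L2 M N P Q R S1 S2 T V W Y".split()
    )
)

# Case-insensitive aliases for common alternative gene names.
_ALIASES = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "cytb": "cytb", "cob": "cytb", "cyb": "cytb",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "12s": "rrnS", "rrns": "rrnS", "12s rrna": "rrnS", "srrna": "rrnS",
    "16s": "rrnL", "rrnl": "rrnL", "16s rrna": "rrnL", "lrrna": "rrnL",
    "d-loop": "CR", "cr": "CR", "control region": "CR",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}


def canonical_name(name: str) -> str:
    """Map common gene-name aliases onto the symbols used throughout
    (cox1..3, nad1..6, nad4l, atp6/8, cytb, trnX, rrnS/rrnL, CR).

    Unknown names pass through verbatim.
    """
    raw = name.strip()
    low = raw.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    if low in PCG_NAMES:
        return low
    # tRNA spellings: trnM, trna-met, tRNA-Met, trnM(cat)
    m = re.match(r"^trna?[-_ ]?([a-z]{3})\b", low)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)]
    m = re.match(r"^(trn[a-z])(\d*)$", low)
    if m:
        return m.group(1)[:3] + m.group(1)[3].upper() + m.group(2)
    if low.startswith("rrn") and len(low) == 4:
        return "rrn" + raw[3].upper() if raw[3] in "SLsl" else raw
    return raw


def infer_category(name: str) -> str:
    """Infer the feature category from a (canonical) gene symbol."""
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    if name.upper() in {"CR", "D-LOOP"} or name.lower().startswith("control"):
        return "control_region"
    if base_symbol(name) in PCG_NAMES:
        return "PCG"
    return "PCG"


def base_symbol(name: str) -> str:
    """Strip a duplicate-copy suffix: trnM1/trnM2 -> trnM, trnW2 -> trnW.

    trnL1/trnL2 and trnS1/trnS2 are distinct isoacceptor genes, not
    duplicates, and are preserved as-is.
    """
    if name in STANDARD_TRNAS:
        return name
    m = re.match(r"^(trn[A-Z])(\d+)$", name)
    if m and m.group(1) in STANDARD_TRNAS:
        return m.group(1)
    return name


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region: a row of a published annotation table.

    Coordinates are 1-based and inclusive on the deposited strand. A feature
    that spans the circular origin is stored with ``stop < start`` and
    ``wraps=True``.
    """

    name: str
    strand: str  # '+' or '-'
    start: int
    stop: int
    category: str | None = None
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.category is None:
            object.__setattr__(self, "category", infer_category(self.name))
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.wraps and self.stop < self.start:
            object.__setattr__(self, "wraps", True)


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: length, ordered features, optional sequence."""

    organism: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: f.start)
        if self.sequence is not None:
            self.sequence = self.sequence.upper()

    # -- convenience accessors -------------------------------------------

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def features_of(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def region_sequence(self, start: int, stop: int, wraps: bool = False) -> str:
        """Deposited-strand sequence of a 1-based inclusive interval."""
        if self.sequence is None:
            raise ValueError(f"record {self.organism!r} has no sequence")
        if wraps or stop < start:
            if not self.circular:
                raise ValueError("wrapping interval on a linear record")
            return self.sequence[start - 1 :] + self.sequence[:stop]
        return self.sequence[start - 1 : stop]

    def feature_sequence(self, feature: GeneFeature | str) -> str:
        """Sense-strand (coding) sequence of a feature.

        Minus-strand features are reverse-complemented so the returned
        string always reads 5'->3' of the gene itself.
        """
        if isinstance(feature, str):
            feature = self[feature]
        seq = self.region_sequence(feature.start, feature.stop, feature.wraps)
        if feature.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def validate(record: MitogenomeRecord) -> list[str]:
    """Check record invariants; returns issue descriptions (empty = valid).

    Issues are data, not exceptions: a record transcribed from a published
    table may legitimately carry oddities worth reporting rather than
    rejecting.
    """
    issues: list[str] = []
    if record.genome_length <= 0:
        issues.append(f"genome_length must be positive, got {record.genome_length}")
    if record.sequence is not None and len(record.sequence) != record.genome_length:
        issues.append(
            f"sequence length {len(record.sequence)} != genome_length "
            f"{record.genome_length}"
        )
    seen: dict[str, int] = {}
    for f in record.features:
        for coord, label in ((f.start, "start"), (f.stop, "stop")):
            if not 1 <= coord <= record.genome_length:
                issues.append(
                    f"{f.name}: {label} {coord} outside [1, {record.genome_length}]"
                )
        if f.wraps and not record.circular:
            issues.append(f"{f.name}: wrapping feature on a non-circular record")
        if f.anticodon is not None and f.category != "tRNA":
            issues.append(f"{f.name}: anticodon on non-tRNA feature")
        if f.category == "tRNA" and f.anticodon is None:
            issues.append(f"{f.name}: warning: tRNA without anticodon")
        seen[f.name] = seen.get(f.name, 0) + 1
    for name, n in seen.items():
        if n > 1:
            issues.append(f"duplicate feature name {name!r} ({n} occurrences)")
    starts = [f.start for f in record.features]
    if starts != sorted(starts):
        issues.append("features not sorted by start coordinate")
    return issues
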