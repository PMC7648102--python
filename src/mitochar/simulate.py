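"""Seeded synthetic mitogenomes with known ground truth.

The generator emulates a limpet-like circular mitogenome: 13 PCGs, ~23
tRNAs (including a duplicated trnM), 2 rRNAs and one large unannotated
AT-rich control region, with configurable per-category base composition
and skews, codon-usage bias, planted start/stop codons (including
incomplete T/TA stops), planted tRNA cloverleaf structures, and scripted
gene-order rearrangements.  Everything is deterministic given the seed,
and every planted property is returned as a ground-truth record so each
analysis stage can be tested by parameter recovery.

Intergenic sequence is drawn i.i.d. per base from the composition implied
by (AT fraction, AT skew, GC skew); no dinucleotide structure is modelled.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .gene_order import GeneOrderSignature
from .records import GeneFeature, MitogenomeRecord

__all__ = [
    "GenePlan",
    "SimulationConfig",
    "default_config",
    "simulate_mitogenome",
    "build_trna",
    "apply_rearrangements",
    "export_simulation",
]

#: anticodons of the standard mitochondrial tRNA set (DNA alphabet)
TRNA_ANTICODONS = {
    "trnA": "TGC", "trnC": "GCA", "trnD": "GTC", "trnE": "TTC",
    "trnF": "GAA", "trnG": "TCC", "trnH": "GTG", "trnI": "GAT",
    "trnK": "TTT", "trnL1": "TAG", "trnL2": "TAA", "trnM": "CAT",
    "trnN": "GTT", "trnP": "TGG", "trnQ": "TTG", "trnR": "TCG",
    "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}

_STOP_CODONS = ("TAA", "TAG")


@dataclass(frozen=True)
class GenePlan:
    """One planned feature: symbol, category, strand and target length.

    For PCGs the length must be consistent with the planned stop: a
    complete stop needs ``length % 3 == 0``, an incomplete ``"T(AA)"``
    stop needs ``length % 3 == 1`` and ``"TA(A)"`` needs ``% 3 == 2``.
    tRNA lengths are dictated by the structural template (63 nt) and the
    planned value is ignored.
    """

    name: str
    category: str
    strand: str = "+"
    length: int = 0
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    anticodon: str | None = None
    dhu_arm: bool = True


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_plan: list = field(default_factory=list)
    target_at: float = 0.602
    target_at_skew: float = -0.063
    target_gc_skew: float = 0.211
    codon_bias: dict = field(default_factory=dict)
    spacer_lengths: list = field(default_factory=lambda: [5])
    genome_length: int | None = None
    organism: str = "Simulated limpet mitogenome"

    def base_probs(self) -> dict[str, float]:
        at, gc = self.target_at, 1.0 - self.target_at
        return {
            "A": at * (1 + self.target_at_skew) / 2,
            "T": at * (1 - self.target_at_skew) / 2,
            "G": gc * (1 + self.target_gc_skew) / 2,
            "C": gc * (1 - self.target_gc_skew) / 2,
        }


# Gene content patterned on the Lottia goshimai mitogenome: same symbols,
# strands, categories and coordinate-derived lengths, same spacer layout
# (the 1722 bp gap after trnR plays the control region).
_LIMPET_PLAN: list[tuple[str, str, str, int, str, str]] = [
    ("cox1", "PCG", "+", 1560, "GTG", "TAG"),
    ("trnM1", "tRNA", "+", 66, "", ""),
    ("nad1", "PCG", "-", 930, "ATG", "TAG"),
    ("trnT", "tRNA", "+", 69, "", ""),
    ("trnY", "tRNA", "-", 67, "", ""),
    ("nad5", "PCG", "-", 1674, "ATT", "TAA"),
    ("nad4l", "PCG", "+", 303, "ATG", "TAG"),
    ("nad4", "PCG", "+", 1326, "ATG", "TAG"),
    ("cox3", "PCG", "-", 858, "ATG", "TAA"),
    ("trnG", "tRNA", "+", 60, "", ""),
    ("trnS2", "tRNA", "+", 65, "", ""),
    ("trnQ", "tRNA", "+", 67, "", ""),
    ("atp6", "PCG", "-", 762, "ATG", "TAA"),
    ("cox2", "PCG", "-", 666, "ATG", "TAA"),
    ("trnL1", "tRNA", "+", 66, "", ""),
    ("trnI", "tRNA", "+", 72, "", ""),
    ("trnP", "tRNA", "+", 68, "", ""),
    ("trnF", "tRNA", "+", 68, "", ""),
    ("nad6", "PCG", "+", 519, "ATG", "TAA"),
    ("nad3", "PCG", "+", 354, "ATG", "TAA"),
    ("trnM2", "tRNA", "-", 67, "", ""),
    ("trnL2", "tRNA", "+", 66, "", ""),
    ("trnA", "tRNA", "-", 70, "", ""),
    ("trnN", "tRNA", "-", 68, "", ""),
    ("trnW", "tRNA", "-", 70, "", ""),
    ("nad2", "PCG", "-", 963, "ATT", "TAA"),
    ("trnV", "tRNA", "-", 69, "", ""),
    ("trnK", "tRNA", "+", 69, "", ""),
    ("trnS1", "tRNA", "+", 67, "", ""),
    ("trnD", "tRNA", "-", 66, "", ""),
    ("rrnS", "rRNA", "+", 921, "", ""),
    ("trnE", "tRNA", "+", 70, "", ""),
    ("trnC", "tRNA", "+", 69, "", ""),
    ("rrnL", "rRNA", "+", 1533, "", ""),
    ("cytb", "PCG", "+", 1164, "ATG", "TAA"),
    ("trnR", "tRNA", "+", 69, "", ""),
    ("atp8", "PCG", "-", 159, "ATG", "TAA"),
    ("trnH", "tRNA", "+", 70, "", ""),
]

_LIMPET_SPACERS = [
    26, 0, 37, 3, 9, 178, 51, 67, 10, 11, 8, 22, 85, 86, 5, 8, 1, 43, 4, 11,
    45, 12, 0, 15, 14, 103, 7, 15, 10, 76, 11, 11, 0, 63, 28, 1722, 145, 26,
]

#: mild codon bias echoing the usage reported for limpet mitogenomes
#: (TTA, ATT, GTT, TTT enriched)
_DEFAULT_BIAS = {"TTA": 4.0, "ATT": 3.0, "GTT": 3.0, "TTT": 3.0}


def default_config(seed: int = 0) -> SimulationConfig:
    """Limpet-patterned simulation: study-like gene order, composition
    (AT 60.2%, AT skew -0.063, GC skew 0.211) and spacers."""
    plan = []
    from .records import base_symbol

    for name, category, strand, length, start, stop in _LIMPET_PLAN:
        anticodon = TRNA_ANTICODONS.get(base_symbol(name)) if category == "tRNA" else None
        # trnS1/trnS2 lack the DHU arm in limpets; plant that too
        dhu = name not in ("trnS1", "trnS2")
        plan.append(
            GenePlan(
                name=name, category=category, strand=strand, length=length,
                start_codon=start, stop_codon=stop, anticodon=anticodon,
                dhu_arm=dhu,
            )
        )
    return SimulationConfig(
        seed=seed,
        genome_plan=plan,
        codon_bias=dict(_DEFAULT_BIAS),
        spacer_lengths=list(_LIMPET_SPACERS),
    )


def compositional_config(
    seed: int = 0,
    target_at: float = 0.602,
    target_at_skew: float = -0.063,
    target_gc_skew: float = 0.211,
    region_length: int = 2000,
    n_regions: int = 6,
) -> SimulationConfig:
    """A genome of unstructured (compositionally sampled) regions only.

    Composition targets apply exactly (i.i.d. per base) to rRNA, control
    region and spacer sequence; PCGs and tRNAs follow their own generative
    rules (codon bias, structure template).  Use this config when testing
    composition/skew recovery at binomial tolerance.
    """
    plan = [
        GenePlan(name=f"region{i + 1}", category="other", strand="+", length=region_length)
        for i in range(n_regions)
    ]
    return SimulationConfig(
        seed=seed,
        genome_plan=plan,
        target_at=target_at,
        target_at_skew=target_at_skew,
        target_gc_skew=target_gc_skew,
        spacer_lengths=[50],
        organism="Compositional simulation",
    )


def _draw_bases(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    if n <= 0:
        return ""
    letters = np.array(list(probs))
    p = np.array(list(probs.values()), dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def _draw_codons(rng, n, bias, code_stops=_STOP_CODONS) -> list[str]:
    codons = [
        a + b + c
        for a in "TCAG"
        for b in "TCAG"
        for c in "TCAG"
        if a + b + c not in code_stops
    ]
    weights = np.array([bias.get(c, 1.0) for c in codons], dtype=float)
    weights /= weights.sum()
    return list(rng.choice(np.array(codons), size=n, p=weights)) if n > 0 else []


def _complement_pair(rng) -> tuple[str, str]:
    a = rng.choice(np.array(list("ACGT")))
    return a, {"A": "T", "T": "A", "G": "C", "C": "G"}[a]


def _stem(rng, length: int) -> tuple[str, str]:
    """A perfect Watson–Crick stem: (5' arm, 3' arm)."""
    left = []
    right = []
    for _ in range(length):
        a, b = _complement_pair(rng)
        left.append(a)
        right.append(b)
    return "".join(left), "".join(reversed(right))


def build_trna(
    rng: np.random.Generator, anticodon: str, dhu_arm: bool = True
) -> tuple[str, dict]:
    """Build a 63 nt tRNA with planted cloverleaf arms.

    Layout: acceptor 5' arm (7 bp) - spacer - DHU arm (4 bp stem, 5 nt
    loop; poly-A when ``dhu_arm`` is False) - spacer - anticodon arm (5 bp
    stem, 7 nt loop centered on the anticodon) - spacer - T-Psi-C arm
    (4 bp stem, 5 nt loop) - acceptor 3' arm.  Returns the sequence and
    the planted ground truth.
    """
    anticodon = anticodon.upper()
    acc5, acc3 = _stem(rng, 7)
    if dhu_arm:
        d5, d3 = _stem(rng, 4)
        d_arm = d5 + "A" * 5 + d3
    else:
        d_arm = "A" * 13
    ac5, ac3 = _stem(rng, 5)
    flank = "T" if anticodon[0] != "T" else "C"
    loop = flank * 2 + anticodon + "AA"
    t5, t3 = _stem(rng, 4)
    t_arm = t5 + "A" * 5 + t3
    seq = acc5 + "AA" + d_arm + "AA" + ac5 + loop + ac3 + "AA" + t_arm + acc3
    truth = {
        "anticodon": anticodon,
        "acceptor_stem": True,
        "dhu_arm": dhu_arm,
        "anticodon_stem": True,
        "tpsic_arm": True,
        "length": len(seq),
    }
    return seq, truth


def _plan_pcg_codons(plan: GenePlan) -> tuple[int, str, int]:
    """Number of body codons, emitted stop string, and emitted stop length."""
    stop = plan.stop_codon
    if stop in ("T(AA)", "T"):
        if plan.length % 3 != 1:
            raise ValueError(f"{plan.name}: incomplete stop T needs length % 3 == 1")
        return (plan.length - 1 - 3) // 3, "T", 1
    if stop in ("TA(A)", "TA"):
        if plan.length % 3 != 2:
            raise ValueError(f"{plan.name}: incomplete stop TA needs length % 3 == 2")
        return (plan.length - 2 - 3) // 3, "TA", 2
    if plan.length % 3 != 0:
        raise ValueError(f"{plan.name}: PCG length {plan.length} not divisible by 3")
    return plan.length // 3 - 2, stop, 3


def simulate_mitogenome(
    config: SimulationConfig,
) -> tuple[MitogenomeRecord, dict]:
    """Generate (record with sequence and annotation, ground-truth dict).

    Deterministic given ``config.seed``.  Raises on an infeasible plan
    (planned content exceeding a requested total genome length).
    """
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs()
    if not config.genome_plan:
        config = replace_plan_with_default(config)
    plan = config.genome_plan
    spacers = config.spacer_lengths or [0]

    parts: list[str] = []
    features: list[GeneFeature] = []
    truth: dict = {
        "seed": config.seed,
        "base_probs": probs,
        "genes": {},
        "trnas": {},
    }
    pos = 1
    codon_truth: dict[str, Counter] = {}

    for i, gp in enumerate(plan):
        if gp.category == "PCG":
            n_body, stop_emitted, stop_len = _plan_pcg_codons(gp)
            if n_body < 0:
                raise ValueError(f"{gp.name}: planned length {gp.length} too short")
            body = _draw_codons(rng, n_body, config.codon_bias)
            sense = gp.start_codon + "".join(body) + stop_emitted
            codon_truth[gp.name] = Counter(body)
            truth["genes"][gp.name] = {
                "start_codon": gp.start_codon,
                "stop_codon": gp.stop_codon,
                "incomplete_stop": stop_len < 3,
                "n_body_codons": n_body,
            }
            anticodon = None
        elif gp.category == "tRNA":
            sense, trna_truth = build_trna(rng, gp.anticodon or "CAT", gp.dhu_arm)
            truth["trnas"][gp.name] = trna_truth
            anticodon = gp.anticodon
        else:  # rRNA / control_region / other: compositional sequence
            sense = _draw_bases(rng, gp.length, probs)
            anticodon = None

        genomic = (
            sense if gp.strand == "+" else str(Seq(sense).reverse_complement())
        )
        start = pos
        stop = pos + len(genomic) - 1
        features.append(
            GeneFeature(
                name=gp.name,
                strand=gp.strand,
                start=start,
                stop=stop,
                category=gp.category,
                anticodon=anticodon,
                start_codon=gp.start_codon or None if gp.category == "PCG" else None,
                stop_codon=gp.stop_codon or None if gp.category == "PCG" else None,
            )
        )
        parts.append(genomic)
        pos = stop + 1

        spacer_len = spacers[i % len(spacers)]
        if i == len(plan) - 1 and config.genome_length is not None:
            built = sum(len(p) for p in parts) + sum(
                spacers[j % len(spacers)] for j in range(len(plan) - 1)
            )
            slack = config.genome_length - built
            if slack < 0:
                raise ValueError(
                    f"planned content ({built} bp) exceeds requested genome "
                    f"length {config.genome_length}"
                )
            spacer_len = slack
        parts.append(_draw_bases(rng, spacer_len, probs))
        pos += spacer_len

    sequence = "".join(parts)
    record = MitogenomeRecord(
        organism=config.organism,
        genome_length=len(sequence),
        features=features,
        circular=True,
        sequence=sequence,
    )
    truth["genome_length"] = len(sequence)
    truth["codon_counts"] = {g: dict(c) for g, c in codon_truth.items()}
    truth["order"] = [
        (f.name, 1 if f.strand == "+" else -1) for f in features
    ]
    truth["target_at"] = config.target_at
    truth["target_at_skew"] = config.target_at_skew
    truth["target_gc_skew"] = config.target_gc_skew
    return record, truth


def replace_plan_with_default(config: SimulationConfig) -> SimulationConfig:
    base = default_config(config.seed)
    base.target_at = config.target_at
    base.target_at_skew = config.target_at_skew
    base.target_gc_skew = config.target_gc_skew
    if config.codon_bias:
        base.codon_bias = config.codon_bias
    if config.genome_length is not None:
        base.genome_length = config.genome_length
    base.organism = config.organism
    return base


def apply_rearrangements(
    order: GeneOrderSignature,
    k: int,
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> tuple[GeneOrderSignature, list[dict]]:
    """Apply ``k`` random events (block inversion / single-gene
    translocation / adjacent swap) and log each one.

    The origin gene (index 0 of the normalized signature) anchors the
    coordinate frame and is never moved or inverted, so event labels stay
    interpretable relative to it.  Deterministic given ``seed``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    n = len(genes)
    log: list[dict] = []
    p = np.array(mix, dtype=float)
    p /= p.sum()
    kinds = ["inversion", "translocation", "shuffle"]
    for _ in range(k):
        kind = kinds[int(rng.choice(3, p=p))] if n > 2 else "inversion"
        if kind == "inversion":
            i = int(rng.integers(1, n))
            max_len = n - i
            length = int(rng.integers(1, max_len + 1))
            block = genes[i : i + length]
            genes[i : i + length] = [(g, -s) for g, s in reversed(block)]
            log.append({"event": "inversion", "genes": [g for g, _ in block]})
        elif kind == "translocation":
            i = int(rng.integers(1, n))
            gene = genes.pop(i)
            j = int(rng.integers(1, n))
            genes.insert(j, gene)
            log.append({"event": "translocation", "genes": [gene[0]]})
        else:  # shuffle: swap an adjacent pair
            i = int(rng.integers(1, n - 1))
            genes[i], genes[i + 1] = genes[i + 1], genes[i]
            log.append(
                {"event": "shuffle", "genes": [genes[i][0], genes[i + 1][0]]}
            )
    return GeneOrderSignature(tuple(genes), order.origin_gene), log


def export_simulation(record: MitogenomeRecord, truth: dict, outdir) -> dict:
    """Write FASTA, feature table, GenBank and ground-truth JSON; returns
    the mapping of artifact name -> path."""
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = record.organism.replace(" ", "_").lower()
    paths = {
        "fasta": outdir / f"{stem}.fasta",
        "table": outdir / f"{stem}.tsv",
        "genbank": outdir / f"{stem}.gb",
        "truth": outdir / f"{stem}.truth.json",
    }
    header = f"{record.organism} | seed={truth.get('seed')} | {record.genome_length} bp"
    paths["fasta"].write_text(mio.write_fasta(header, record.sequence))
    paths["table"].write_text(mio.write_feature_table(record))
    paths["genbank"].write_text(_to_genbank(record))
    paths["truth"].write_text(json.dumps(truth, indent=1, default=str))
    return paths


def _to_genbank(record: MitogenomeRecord) -> str:
    import io as _io

    from Bio import SeqIO
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    types = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control_region": "D-loop"}
    sr = SeqRecord(
        Seq(record.sequence or "N" * record.genome_length),
        id="SIMULATED",
        name="SIMULATED",
        description=record.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.organism,
        },
    )
    for f in record.features:
        loc = SimpleLocation(f.start - 1, f.stop, strand=1 if f.strand == "+" else -1)
        qualifiers = {"gene": [f.name]}
        if f.anticodon:
            qualifiers["anticodon"] = [f.anticodon]
        sr.features.append(
            SeqFeature(loc, type=types.get(f.category, "misc_feature"), qualifiers=qualifiers)
        )
    buf = _io.StringIO()
    SeqIO.write(sr, buf, "genbank")
    return buf.getvalue()
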