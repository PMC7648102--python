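"""Circular signed gene-order comparison.

A gene order is modelled as a signed circular permutation of shared gene
symbols (sign = transcription strand).  Two orders are compared through
their signed adjacencies: the breakpoint distance is the number of shared
genes minus the number of conserved adjacencies, where an adjacency (a, b)
also matches its mirror (-b, -a), so a wholly inverted block keeps its
internal adjacencies and costs only its two boundary breakpoints.

On top of the distance, a rank-displacement classifier labels each gene as
in place, shuffled (local repositioning within a window), translocated
(long-range repositioning), inverted, or both — an auditable
operationalization of the qualitative event vocabulary used in
mitogenome-rearrangement studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import MitogenomeRecord, base_symbol, canonical_name

__all__ = [
    "GeneOrderSignature",
    "ConservedBlock",
    "RearrangementReport",
    "signature",
    "parse_order_string",
    "format_order_string",
    "breakpoint_distance",
    "shared_adjacencies",
    "conserved_blocks",
    "classify_events",
]

Signed = tuple[str, int]


@dataclass(frozen=True)
class GeneOrderSignature:
    """Signed circular permutation, rotation/reflection-normalized.

    Normalization rotates the circle so ``origin_gene`` comes first and, if
    the origin gene lies on the minus strand, flips the whole circle
    (reversing the order and negating every sign) first — so two
    annotations of the same molecule that happen to be deposited on
    opposite strands or with different origins compare equal.
    """

    genes: tuple[Signed, ...]
    origin_gene: str

    def __post_init__(self):
        symbols = [g for g, _ in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene symbols must be unique in a signature")
        if self.origin_gene not in symbols:
            raise ValueError(f"origin gene {self.origin_gene!r} not in signature")
        object.__setattr__(self, "genes", _normalize(self.genes, self.origin_gene))

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def rank(self, gene: str) -> int:
        for i, (g, _) in enumerate(self.genes):
            if g == gene:
                return i
        raise KeyError(gene)

    def sign(self, gene: str) -> int:
        return self.genes[self.rank(gene)][1]


def _normalize(genes: tuple[Signed, ...], origin: str) -> tuple[Signed, ...]:
    lst = list(genes)
    i = next(k for k, (g, _) in enumerate(lst) if g == origin)
    if lst[i][1] < 0:
        lst = [(g, -s) for g, s in reversed(lst)]
        i = next(k for k, (g, _) in enumerate(lst) if g == origin)
    return tuple(lst[i:] + lst[:i])


def signature(
    record: MitogenomeRecord,
    shared_set=None,
    origin_gene: str | None = None,
    duplicates: str = "exclude",
) -> GeneOrderSignature:
    """Signed gene order of a record, restricted to ``shared_set``.

    Gene names are canonicalized and duplicate copies (trnM1/trnM2,
    trnW1/trnW2) are either dropped (``duplicates='exclude'``, default —
    species with unequal copy numbers stay comparable) or collapsed to the
    first occurrence (``'first'``).

    Raises ``KeyError`` listing missing shared genes.
    """
    if duplicates not in ("exclude", "first"):
        raise ValueError("duplicates must be 'exclude' or 'first'")
    entries: list[Signed] = []
    seen_bases: dict[str, int] = {}
    for f in record.features:
        base = base_symbol(f.name)
        is_duplicate_copy = base != f.name
        seen_bases[base] = seen_bases.get(base, 0) + 1
        if is_duplicate_copy:
            if duplicates == "exclude" or seen_bases[base] > 1:
                continue
        elif seen_bases[base] > 1:
            continue
        entries.append((base, 1 if f.strand == "+" else -1))
    if shared_set is not None:
        shared = {canonical_name(g) for g in shared_set}
        missing = sorted(shared - {g for g, _ in entries})
        if missing:
            raise KeyError(
                f"shared genes absent from {record.organism!r}: {', '.join(missing)}"
            )
        entries = [(g, s) for g, s in entries if g in shared]
    if not entries:
        raise ValueError("empty signature")
    if origin_gene is None:
        origin_gene = "cox1" if any(g == "cox1" for g, _ in entries) else entries[0][0]
    return GeneOrderSignature(tuple(entries), canonical_name(origin_gene))


def parse_order_string(text: str, origin_gene: str | None = None) -> GeneOrderSignature:
    """Parse a one-line circular order: comma-separated signed symbols,
    e.g. ``"cox1,-nad5,nad4l"``."""
    entries: list[Signed] = []
    for token in text.strip().split(","):
        token = token.strip()
        if not token:
            continue
        sign = 1
        if token[0] in "+-":
            sign = -1 if token[0] == "-" else 1
            token = token[1:]
        entries.append((canonical_name(token), sign))
    if not entries:
        raise ValueError("empty gene-order string")
    if origin_gene is None:
        origin_gene = entries[0][0]
    return GeneOrderSignature(tuple(entries), canonical_name(origin_gene))


def format_order_string(sig: GeneOrderSignature) -> str:
    return ",".join(("-" if s < 0 else "") + g for g, s in sig.genes)


def _adjacency_set(sig: GeneOrderSignature) -> set[tuple[Signed, Signed]]:
    """Canonical signed adjacencies of a circular signature.

    The adjacency (a, b) and its reading on the other strand (-b, -a) are
    the same physical junction; both are canonicalized to one form.
    """
    adj = set()
    n = len(sig.genes)
    for i in range(n):
        a = sig.genes[i]
        b = sig.genes[(i + 1) % n]
        mirror = ((b[0], -b[1]), (a[0], -a[1]))
        adj.add(min((a, b), mirror))
    return adj


def _check_same_genes(s1: GeneOrderSignature, s2: GeneOrderSignature) -> None:
    if s1.symbols != s2.symbols:
        only1 = sorted(s1.symbols - s2.symbols)
        only2 = sorted(s2.symbols - s1.symbols)
        raise ValueError(
            f"gene sets differ (only in first: {only1}; only in second: {only2})"
        )


def shared_adjacencies(s1: GeneOrderSignature, s2: GeneOrderSignature) -> int:
    _check_same_genes(s1, s2)
    return len(_adjacency_set(s1) & _adjacency_set(s2))


def breakpoint_distance(s1: GeneOrderSignature, s2: GeneOrderSignature) -> int:
    """Signed circular breakpoint distance: n minus shared adjacencies."""
    return len(s1) - shared_adjacencies(s1, s2)


@dataclass(frozen=True)
class ConservedBlock:
    genes: tuple[str, ...]
    inverted: bool


def conserved_blocks(
    s1: GeneOrderSignature, s2: GeneOrderSignature
) -> list[ConservedBlock]:
    """Maximal runs of s1 that appear consecutively in s2, either in the
    same order and signs or fully reversed with flipped signs (inverted).
    The blocks partition the circle; identical signatures give one block."""
    _check_same_genes(s1, s2)
    n = len(s1)
    succ2: dict[Signed, Signed] = {}
    for i in range(n):
        succ2[s2.genes[i]] = s2.genes[(i + 1) % n]

    def pair_type(i: int) -> str | None:
        a = s1.genes[i]
        b = s1.genes[(i + 1) % n]
        if succ2.get(a) == b:
            return "forward"
        if succ2.get((b[0], -b[1])) == (a[0], -a[1]):
            return "reverse"
        return None

    types = [pair_type(i) for i in range(n)]
    if n == 1:
        g, s = s1.genes[0]
        return [ConservedBlock((g,), s2.sign(g) != s)]
    if all(t == "forward" for t in types):
        return [ConservedBlock(tuple(g for g, _ in s1.genes), False)]
    if all(t == "reverse" for t in types):
        return [ConservedBlock(tuple(g for g, _ in s1.genes), True)]

    # break the circle at every non-conserved junction
    breaks = [i for i in range(n) if types[i] is None]
    blocks: list[ConservedBlock] = []
    for bi, start_break in enumerate(breaks):
        end_break = breaks[(bi + 1) % len(breaks)]
        i = (start_break + 1) % n
        genes = [s1.genes[i]]
        j = i
        while j != end_break:
            genes.append(s1.genes[(j + 1) % n])
            j = (j + 1) % n
        symbols = tuple(g for g, _ in genes)
        if len(genes) == 1:
            inverted = s2.sign(symbols[0]) != genes[0][1]
        else:
            inverted = types[i] == "reverse"
        blocks.append(ConservedBlock(symbols, inverted))
    return blocks


@dataclass(frozen=True)
class RearrangementReport:
    shared_adjacencies: int
    breakpoints: int
    per_gene_events: dict
    conserved_blocks: list = field(default_factory=list)
    window: int = 2


def classify_events(
    reference: GeneOrderSignature,
    target: GeneOrderSignature,
    window: int = 2,
) -> RearrangementReport:
    """Per-gene rearrangement classification of ``target`` against
    ``reference``.

    A gene is *inverted* iff its sign differs.  Positional displacement is
    the minimal circular shift of the gene's rank after anchoring the two
    orders on the largest conserved block: 0 -> in_place, <= window ->
    shuffled, > window -> translocated.  Inversion combines with a
    beyond-window displacement as ``inverted_translocated``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    _check_same_genes(reference, target)
    n = len(reference)
    blocks = conserved_blocks(reference, target)
    anchor_block = max(blocks, key=lambda b: (len(b.genes), not b.inverted))
    anchor_gene = anchor_block.genes[0]
    offset = (target.rank(anchor_gene) - reference.rank(anchor_gene)) % n

    events: dict[str, str] = {}
    for gene, sign in reference.genes:
        inverted = target.sign(gene) != sign
        d = (target.rank(gene) - reference.rank(gene) - offset) % n
        displacement = min(d, n - d)
        if displacement == 0:
            label = "inverted" if inverted else "in_place"
        elif displacement <= window:
            label = "inverted" if inverted else "shuffled"
        else:
            label = "inverted_translocated" if inverted else "translocated"
        events[gene] = label

    shared = shared_adjacencies(reference, target)
    return RearrangementReport(
        shared_adjacencies=shared,
        breakpoints=n - shared,
        per_gene_events=events,
        conserved_blocks=blocks,
        window=window,
    )
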