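# Methods

This note documents the conventions, formulas, parameter defaults and
design choices behind each analysis stage, and what the synthetic-data
tests do and do not establish about real data.

## Coordinates and circular arithmetic

All coordinates are 1-based and inclusive on the deposited strand, the
convention of GenBank records and of published mitogenome annotation
tables; conversion to 0-based happens only inside the I/O layer. A feature
spanning the circular origin is stored with `stop < start` and a wrap
flag; its length is `(L − start + 1) + stop` for genome length `L`.

The intergenic value between consecutive features A and B (sorted by
start, both strands interleaved) is `start(B) − stop(A) − 1`; negative
values are overlaps. The entry for the last feature wraps around the
origin. The gap is attributed to the upstream feature, matching the row
placement of published tables. This convention reproduces every printed
intergenic cell of the two packaged limpet tables except one (below), and
satisfies the conservation identity
`Σ feature lengths + Σ signed gaps = genome length` exactly on both
fixtures and on all simulated genomes.

The control region is located as the largest positive circular gap —
mitogenome annotation pipelines typically leave the CR unannotated, so it
appears as the dominant spacer (1,722 bp between *trnR* and *atp8* in
*L. goshimai*; 1,561 bp between *nad5* and *atp8* in *N. fuscoviridis*).

### Known inconsistencies in the packaged tables

Three cells of the published annotation tables contradict their own
coordinates, and the fixtures record both values
(`datasets.KNOWN_ERRATA`): the *L. goshimai* trnG length (printed 67,
coordinates span 60), the *N. fuscoviridis* trnC length (printed 66,
span 60), and the *N. fuscoviridis* nad5 intergenic cell (printed 1562,
coordinates — and the source's own prose CR length — give 1561). The
coordinate-derived values win everywhere: notably, the published
per-category tRNA totals (1,558 and 1,597 bp) equal the sum of coordinate
spans only under that choice. Consequently the shortest *L. goshimai*
tRNA by coordinates is 60 bp (trnG), not the 65 bp the source prose
quotes. Four skew cells of the composition table (*N. fuscoviridis* cox2
and cox3) cannot be reproduced from their own printed percentages even
approximately and are likewise flagged as errata; the remaining 64 cells
reproduce to ±0.001.

## Base composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), computed on counts
(equivalently on percentages). `N` bases are counted separately and
excluded from every denominator; a zero denominator yields an undefined
(None) skew rather than a number. Per-gene rows use the gene's sense
(coding) strand — reverse-complemented for minus-strand genes — while the
whole-genome row uses the deposited strand; this is why per-gene skew
signs can disagree with the genome row, as they do in the published
table. Report rounding is 2 d.p. for percentages and 3 d.p. for skews,
half-away-from-zero; raw values are kept internally.

## Codon usage

The genetic code is NCBI translation table 5 (invertebrate mitochondrial:
AGA/AGG → Ser, ATA → Met, TGA → Trp; stops TAA/TAG), taken from
Biopython. Synonymous families split serine and leucine as codon-usage
figures conventionally do: Ser1 = AGN, Ser2 = TCN, Leu1 = CTN,
Leu2 = TTR.

A CDS whose length mod 3 leaves a trailing `T` or `TA` is treated as an
incomplete stop codon and padded with `AA`/`A` (the polyadenylation
convention), reported as `T(AA)` / `TA(A)`. A trailing base other than T
is an error; internal stops and a non-stop final codon are warnings, not
errors, since published annotations occasionally contain them.

RSCU(c) = n_c · k / Σ over c's synonymous family (k = family size); mean
RSCU per non-empty family is 1 by construction, and empty families are
flagged rather than divided by zero. Start and stop codons are excluded
from usage counts by default (configurable): initiation codons are
constrained by function rather than codon preference. Amino-acid usage is
reported per thousand codons.

## Ka/Ks (Nei–Gojobori 1986 + Jukes–Cantor)

The estimator choice is a documented default: the source analyses we
mirror report Ka/Ks without naming an estimator, and NG86 with JC
correction is the classic counting method. Synonymous sites per codon
position are the fraction of the three single-base changes that preserve
the amino acid, with changes to stop codons removed from numerator and
denominator (so S + N = 3 per codon always). Differences between two
codons are averaged over all orderings of the differing positions (1, 2
or 6 pathways); pathways through stop codons are excluded, unless every
pathway is excluded, in which case all are kept so Sd + Nd still equals
the Hamming distance. S and N are averaged over the two sequences;
pS = Sd/S and pN = Nd/N are corrected by d = −(3/4) ln(1 − 4p/3), with
p ≥ 3/4 flagged as saturated (distance undefined) and Ka/Ks undefined
when Ks = 0. Alignments are assumed given: gapless, in frame, equal
length, no internal stops — no aligner is implemented.

## Gene-order comparison

A gene order is a signed circular permutation over a shared gene set,
normalized so a chosen origin gene (cox1 by default) comes first on the
plus strand, flipping the whole circle if necessary — two annotations of
the same molecule deposited on opposite strands therefore compare equal.
Duplicate tRNA copies (trnM1/trnM2, trnW1/trnW2) are excluded from
signatures by default so species with unequal copy numbers stay
comparable (`duplicates="first"` keeps the first copy); trnL1/trnL2 and
trnS1/trnS2 are distinct isoacceptor genes and are never collapsed.

The breakpoint distance is n minus the number of shared signed
adjacencies, where the adjacency (a, b) matches its other-strand reading
(−b, −a); a wholly inverted block therefore costs only its two boundary
breakpoints. This is a pseudometric (identity, symmetry, triangle
inequality — the latter verified empirically on seeded random
signatures); no optimal-scenario reconstruction (Hannenhalli–Pevzner,
DCJ) is attempted.

Conserved blocks are maximal runs consecutive in both orders, either with
identical signs or fully reversed with flipped signs (flagged inverted);
they partition the circle. The event classifier anchors the two orders on
the largest conserved block, then labels each gene by sign change
(inverted) and circular rank displacement: 0 in place, ≤ window
"shuffled", > window "translocated" (window default 2 genes; inversion
beyond the window reports `inverted_translocated`). This is an
operationalization of the qualitative shuffling/translocation/inversion
vocabulary of mitogenome papers — auditable, but sensitive to the window
near its boundary, and a single long-range translocation necessarily
shifts the ranks of the genes it jumps over by one, which the classifier
reports as local shuffling of those genes.

The shipped "ancestral gastropod" order is an editable stand-in
(`ancestral_gastropod_order.synthetic.txt`) patterned on conserved
molluscan arrangements, not a transcription of any published
reconstruction; replace it with your preferred reference before drawing
conclusions against it.

## tRNA and hairpin structure

A deliberately simplified, rule-based folder — not a thermodynamic one.
Pairing is Watson–Crick plus GU wobble (GT in the DNA alphabet).
`find_hairpin` enumerates every (loop position, loop length ∈ [3,
max_loop]) placement, extends a perfect stem outwards, and returns the
maximal stem (ties: smaller loop, then leftmost). Defaults for OL
detection: min_stem 5, max_loop 10, GU allowed — these detect the 9 bp
stem / 3 nt loop of the reported 21-mer OL sequence.

`cloverleaf_report` anchors the anticodon at its occurrence nearest
mid-sequence inside a canonical 7 nt loop; the anticodon stem is the run
of pairs closing that loop (present at ≥ 4 bp), the acceptor stem pairs
the 5' and 3' termini (≥ 6 of up to 8 rungs, one mismatch allowed), and
the DHU and TΨC arms are sought as hairpins (stem ≥ 3 bp) in the regions
between acceptor arm and anticodon arm on each side. All thresholds are
parameters. This recovers 100% of generator-planted arms; on real tRNAs
it is a screen for gross features (such as the DHU-arm loss of
trnS1/trnS2), not a replacement for covariance-model tools.

## The synthetic-data generator

The default plan mirrors the *L. goshimai* genome: the same 38 features
with their strands, categories and coordinate-derived lengths, the same
spacer layout (overlaps clamped to zero), the 1,722 bp unannotated gap
standing in for the CR, and composition targets set to the study genome's
whole-genome values (AT 0.602, AT skew −0.063, GC skew 0.211). The codon
bias default enriches TTA, ATT, GTT and TTT — the codons reported most
used in these limpets. trnS1/trnS2 are planted without DHU arms, as
observed.

Unstructured sequence (rRNA-length regions, spacers, CR) is drawn i.i.d.
per base from the probabilities implied by (AT, AT skew, GC skew) — so
composition targets are recovered at binomial tolerance there, and
`compositional_config` builds an all-unstructured genome (12.3 kb by
default) for exactly that test. PCG composition instead emerges from the
codon bias, and tRNAs from the 63 nt structural template (planted stems:
acceptor 7 bp, DHU 4 bp, anticodon 5 bp around a 7 nt loop, TΨC 4 bp),
so whole-genome composition of a full simulated mitogenome deliberately
deviates from the unstructured target. No dinucleotide structure, indels,
or tree-based evolution are modelled. In `apply_rearrangements` the
origin gene anchors the coordinate frame and is itself never moved or
inverted, keeping event logs interpretable relative to it.

Passing recovery tests on these genomes demonstrates that each stage
inverts its own generative model (codons planted are codons recovered,
arms planted are arms detected, k inversions cost ≤ 2k breakpoints);
they do not validate biological inference on real sequences, where
structure, composition and annotation error interact.

## Problem sizes and determinism

All table-derived checks run on the packaged 38/39-row fixtures in
milliseconds. Property checks use seeded generators at deliberately
modest sizes — 12 kb compositional genomes, 120-codon Ka/Ks pairs,
12-gene signatures, ~180 planted tRNAs — chosen so the binomial and
combinatorial tolerances they assert are meaningful. Every random path
takes an explicit seed; reports are byte-identical across reruns on the
same inputs.
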