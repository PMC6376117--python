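# Methods

## Coordinate and annotation model

All internal coordinates are 0-based half-open (BED/RefFlat
convention); GTF input is shifted on read. Ordinal positions follow
transcription order: exon 1 is the 5′-most transcribed exon, so on the
minus strand it is the right-most exon genomically, and intron N lies
between exons N and N+1. A gene groups all isoforms sharing a symbol;
gene length is the span from the minimum transcript start to the
maximum transcript end, and exonic length (for FPKM) is the union of
exons across isoforms. The union-exon FPKM is a deliberate
simplification: likelihood-based multi-isoform apportionment would
require an EM fit that adds nothing at toy scale, and the union length
makes FPKM a deterministic function of the annotation. An optional
exclusion-interval set (for rRNA/tRNA/chrM-style masking) is applied to
the exonic length when provided; the default is empty.

## Back-splice detection

The caller is annotation-anchored by construction: candidate junctions
are enumerated per transcript over all exon pairs with acceptor
ordinal ≤ donor ordinal, so no call can fall outside the candidate
index. First and last exons are included as candidates; the inclusive
cognate-isoform assignment (below) means a junction can legitimately
map to ordinal 1 in some isoform, and we report such assignments rather
than forbid them.

Read matching is self-contained string matching rather than an external
aligner: exact substring search against a concatenated reference
(spliced isoforms in both orientations plus the genome) with a
pigeonhole seed-and-extend Hamming fallback when `max_mismatches > 0`.
Defaults: junction flank `k = 42` nt (read length 50 minus the anchor),
`min_anchor = 8` nt on each side of the junction point,
`max_mismatches = 1`. A read matching more than one junction equally
well is discarded (unique-best rule). The mate of a junction read must
match the wrap-doubled circular sequence in either orientation, which
also accepts mates that cross the junction themselves. A pair whose two
mates map uniquely to *different* junctions is ambiguous and dropped.

Cognate linear isoforms are assigned inclusively: every isoform whose
junction-side boundaries (acceptor 5′ start, donor 3′ end) are exon
boundaries and whose transcript span covers the circle is a potential
parent. Each (circRNA, isoform) pair contributes once to positional and
length statistics, which avoids arbitrarily choosing a parent isoform
at the cost of occasional ordinal-1 assignments. Internal-exon skipping
within the circle span is not modelled.

Abundance is JPM = verified pairs / (mapped reads / 1e6), computed per
library with that library's own mapped total. The retention filter
keeps a circRNA when its mean JPM over a cell type's samples is ≥ 0.1,
or when its mean JPM over the eight polysome fractions is ≥ 0.1
(rescue rule). Both comparisons are inclusive and evaluated with a
1e-9 relative epsilon so that a mean of eight stored 0.1 values (which
floats represent as 0.0999…) still passes the boundary.

## Matched reference sets

Six constructions: cell-specific (mean FPKM ≥ 1, inclusive), non-circ
(cell-specific minus circRNA-producing genes), exon-count-,
gene-length- and expression-adjusted sets (for each target value, the
nearest pool member in the property is drawn without replacement, ties
broken by a seeded shuffle; the achieved vs target mean is reported and
a drift beyond 25% of the target mean raises a warning), and
position-adjusted feature sets (largest-remainder allocation of counts
to ordinal positions, then seeded without-replacement sampling within
each position, so the achieved distribution matches the target within
one feature per position). Whether to sample with or without
replacement was an open choice; without-replacement was picked because
it cannot duplicate members, and the error message suggests a
replacement flag when the pool is exhausted. Every set is a pure
function of (pool, targets, seed).

## Structural statistics

Acceptor/donor position profiles divide the ordinal-position counts by
the number of transcripts possessing an exon at that position, then
rescale the ratios to sum to 1 over occupied positions. The final
divisor of this double normalisation was genuinely ambiguous;
normalising the ratios to unit sum is implemented because it makes
profiles comparable across sets and invariant to uniform scaling of the
exon counts (a property the tests assert). Length tables report
mean/median/n per (class, role, kind) cell with a two-sided
Mann-Whitney U test against the matching reference row; the reference
uses internal exons only (first and last exons removed) and all introns
of the reference genes. Flanking introns are the intron immediately
upstream of the acceptor exon and immediately downstream of the donor
exon in transcription order (acceptor at ordinal 2 → upstream flank is
intron 1).

The Mann-Whitney implementation delegates to scipy: exact enumeration
when n1+n2 ≤ 16 with no ties, otherwise the normal approximation with
tie and continuity correction. The acceptance tests verify it against
an independent brute-force enumeration over all labelings up to 8 vs 8.
No multiple-testing correction is applied; raw P-values are reported.
The two-sample proportion test is the continuity-corrected chi-square
(the form R's `prop.test` computes), cross-checked against a Fisher
exact oracle in tests. In the RBP footprint comparison, "site counts
normalised per exon" is operationalised as the proportion of exons of
each class carrying at least one footprint — a raw sites-per-exon ratio
is not a proportion once density exceeds one site per exon — with raw
per-class site totals reported alongside.

## Polysome fractions and circular ORFs

The fraction matrix holds JPM per circRNA over the total cytoplasmic
column and fractions F1–F8, each normalised by its own library depth.
`Free* = 9 × total − Σ(fractions)` is implemented exactly as defined;
the ×9 multiplier presumably equalises depth across the nine libraries,
and we do not reinterpret it. Negative Free* values are flagged and
floored at zero for reporting — at toy library depths the per-library
JPM scales differ enough that negative raw values are common, which the
flag makes visible rather than hiding. tc-circRNAs are selected by mean
fraction JPM ≥ 0.1 (inclusive); the total column plays no role.

The ORF scanner treats the spliced circular sequence as having an
implicit junction between its last and first nucleotide. Start codons
are AUG plus the near-cognate CUG and GUG (the union is scanned; the
set is an argument). From each start the codon walk proceeds circularly
for at most three full passes; the first in-frame UAG/UAA/UGA
terminates the ORF, and a walk that completes three passes without a
stop is flagged as an infinite loop (possible only when the circle
length is divisible by 3, where the frame closes on itself).
`crosses_junction` is set when the walk passes the back-splice point.
The scanner is verified against a triple-concatenation linear-scan
oracle on 1,000 random circles of 30–300 nt.

m6A sites from multiple source lists are pooled and deduplicated before
counting; any overlap with a circle exon counts (half-open arithmetic,
so a site at an exon start position is inside).

## Sponge scoring

Seed matches are exact reverse complements of miRNA positions 2–7, no
G:U pairing, scanned over the circle with the first five nucleotides
appended so junction-spanning matches are found; positions are
deduplicated modulo the circle length. The predicted target site is the
6 nt seed match plus 7 nt on each flank (~20 nt, configurable) — the
paper-scale analyses derived the site extent from a thermodynamic
hybridisation tool, which this package replaces with the seed scan that
acts as the decisive filter; an external duplex-energy scorer can be
hooked in but is not required. A site is AGO-supported when ≥ 50% of
its length lies inside an AGO footprint extended ±10 nt; a
junction-spanning site is evaluated on the genomic arm with the larger
overlap. Overlapping matches of the same seed at offset positions are
counted as distinct sites (a minimum-spacing option exists for
conservative counting). Per-seed occurrence tables flag seeds present
in at least 8 distinct circRNAs by default.

## NET-seq dwell analysis

Pipeline order is fixed and tested: replicate tracks are averaged
positionwise (a position missing from one replicate counts as zero),
then the combined track is capped at 10 counts per nucleotide, then
densities are computed. The cap is per nucleotide — applying it per
feature region was the alternative reading; per-nucleotide was chosen
because the outliers being blunted are single-locus pileups, and the
choice is a configurable argument. Region density is signal per
nucleotide over the half-open region; densities over concatenated
regions are length-weighted.

Position-adjusted comparisons sample, for each (class, role, kind) cell
of circRNA features, a reference feature set of equal size whose
ordinal-position distribution matches the circRNA features', drawn from
the non-circ gene pool, and compare Pol II/nt densities by Mann-Whitney
U. In the toy pipeline the pool is the non-circ genes directly rather
than an expression-matched subset: the generator gives every gene the
same NET-seq gene rate, so expression adjustment would be a no-op; with
real data the pool should first be filtered to expression-matched genes.
Metagene profiles aggregate 300 nt of intron flank at natural per-nt
scale on both sides of each exon (transcription order; positions
outside the chromosome are excluded from the mean, not zero-filled) and
rescale the exon to 100 bins by length-weighted linear rebinning, which
maps a constant track to an exactly constant profile.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:
multi-exon genes (default 4–8 exons; first/internal/last exon lengths
uniform on 120–400/80–220/150–500 nt around the ~150 nt internal-exon
scale; introns uniform on 200–1,400 nt with intron 1 scaled 3× to
mirror the long-first-intron trend), planted circRNAs with
acceptor-position bias (default mass 0.05/0.55/0.25/0.15 on ordinals
1–4, peaking at the second exon), an exon-span law peaking at two exons
(0.25/0.45/0.20/0.10 for spans 1–4), and flanking introns drawn 5×
longer than the baseline law — the structural signatures the analyses
are designed to detect. Read pairs are drawn from spliced linear
isoforms (gene weights log-normal) and from circular sequences, where
junction-crossing reads arise naturally when a fragment wraps past the
back-splice point; read IDs carry truth tags (class, gene, junction
key) so detection can be evaluated without alignment. Default library:
~48,000 linear pairs plus 120–200 pairs per circle, read length 50,
fragment 170 ± 30 nt, error rate 0 (an optional uniform substitution
model exists for anchor-robustness experiments). Mapped totals are the
reads actually written, so planted JPMs are self-consistent.

The nine fraction libraries allocate each molecule's pairs
multinomially over the eight fractions plus a free residue; circRNA
loading concentrates on the mono- to tetrasome fractions
(0.22/0.18/0.14/0.10/0.06/0.04/0.03/0.03, free 0.20), mRNA loading on
the heavy fractions, and a configurable share of circles (default 30%)
is made entirely ribosome-free so the tc/non-ribosomal contrast exists.
NET-seq expected signal is gene rate × dwell, with exon dwell 3× intron
dwell by default, additive boundary stalls (height 4, width 15 nt on
each side of every exon edge), an optional linear acceleration toward
the 3′ end, and per-circ-gene dwell multipliers for recovery
experiments; replicates are independent Poisson draws. Regulatory-site
simulation mutates the genome to plant exact seed-target motifs inside
circle exons — with covering AGO2 footprints, without (kept at least
40 nt from any planted footprint so filter negatives are well defined),
or straddling the junction — and scatters non-AGO RBP footprints and
single-nucleotide m6A sites over exons at configurable densities.

All randomness flows from a single seed through per-stage child
generators (numpy SeedSequence spawning), making every output
byte-identical across runs and platforms.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequence composition biases (uniform
random nucleotides, so no repeats, no reverse complementary motifs or
Alu-driven looping), RNA editing, splice-site motifs, fragment GC
bias, multi-mapping ambiguity at paralogs, expression-dependent
NET-seq rates, or RBP binding kinetics. Detection performance on this
generator measures the correctness of the junction logic, not
real-world sensitivity at 30–200 million-read scale.

## Problem sizes and numerical choices

The default study conditions are 20 genes with 10 planted circRNAs and
~50k read pairs — large enough that every planted junction receives
≥ 20 junction-crossing pairs, small enough that the whole detection
path runs in seconds. Recovery experiments use 50–100 genes with 20–30
circles and lighter read sets (~2–2.5k linear pairs, 40–60 pairs per
circle, exact matching), with sharper planted laws
(acceptor 0.05/0.65/0.20/0.10, span 0.10/0.60/0.20/0.10, minimum exon
count 5 to avoid span clipping at short genes) so that the mode and
argmax statistics are identifiable from ~30 circles; dwell-recovery
runs keep expected signal below the count cap so planted multipliers
remain measurable on the capped track. Threshold comparisons are
inclusive with a 1e-9 relative epsilon; ties in mode/argmax extraction
break toward the smaller ordinal; the proportion test returns P = 1 on
degenerate margins.

## Known limitations

- The uniqueness rule ("unique best junction") is an explicit stand-in
  for whatever filtering the original aligner chain enforced.
- Mismatch tolerance counts substitutions only (Hamming); indels in
  reads are not modelled or matched.
- Union-exon FPKM ignores isoform-level apportionment.
- The expression-adjusted pool for NET-seq references degenerates to
  the non-circ pool under the generator's uniform expression model.
- No de novo (annotation-free) junction discovery, fusion calling,
  intron retention, IRES prediction, or conservation scoring.
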