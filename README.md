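# backsplice

Detection and characterisation of exonic circular RNAs (circRNAs) from
paired-end RNA-seq, with the downstream analyses used to study their
biogenesis and potential functions: matched reference gene sets,
positional and length statistics of circRNA loci, polysome-fraction
translation-candidate calling, AGO-anchored miRNA sponge scoring, and
NET-seq RNA polymerase II dwell analysis. A deterministic synthetic-data
generator produces a complete toy study (genome, annotation, read sets,
coverage tracks, regulatory sites) so every stage runs and is testable
without any external data.

It is written for computational RNA biologists who want a transparent,
annotation-anchored re-implementation of this analysis stack at desk
scale — as a library (`import backsplice`) or a command-line tool
(`backsplice simulate | detect | refsets | features | ribo | sponge |
netseq | report`).

## The method

**Back-splice detection.** Back-splicing joins the 3′ end of a
downstream (donor) exon to the 5′ start of an upstream (acceptor) exon,
producing a covalently closed circle. For every transcript the caller
enumerates candidate junctions over all exon pairs (acceptor ordinal ≤
donor ordinal) and builds each junction's flank sequence — the donor
exon's terminal *k*-mer followed by the acceptor exon's initial
*k*-mer, in transcript orientation. Read pairs matching the linear
transcriptome (or genome) contiguously are discarded; a remaining read
is a junction hit when it aligns across the junction point with at
least `min_anchor` nucleotides on both sides, at most `max_mismatches`
substitutions, and a unique best junction. A hit is counted only if its
mate lies inside the predicted circle (or crosses the junction itself).
Counts are normalised per library to junctions per million mapped reads:

```
JPM = verified pairs / (mapped reads / 10^6)
```

A circRNA is kept when its mean JPM across a cell type's samples is
≥ 0.1 (inclusive), or — rescue rule — when its mean JPM across the
eight polysome fractions is ≥ 0.1.

**Downstream analyses.**

- *Positional statistics*: acceptor/donor ordinal profiles normalised
  to the exon frequency at each ordinal position
  (`profile_N ∝ count_N / exons_N`), circle exon spans, and exon/intron
  length tables (single- vs multi-exon circles, acceptor/internal/donor
  roles) against internal features of a reference gene set, compared by
  two-sided Mann-Whitney U tests.
- *Polysome fractions*: per-fraction JPM matrix over the total
  cytoplasmic library and fractions F1–F8, the calculated free pool
  `Free* = 9 × total − Σ(F1..F8)`, translation candidates
  (tc-circRNAs) as mean fraction JPM ≥ 0.1, circular ORF scanning with
  AUG/CUG/GUG starts walking up to three passes of the circle
  (stop-free frames are flagged as infinite-loop ORFs), and m6A-site
  overlap.
- *Sponge scoring*: exact Watson-Crick seed matches (miRNA positions
  2–7) over the circular sequence including junction-spanning matches;
  a ~20 nt predicted site is AGO-supported when ≥ 50% of it overlaps an
  AGO CLIP footprint extended ±10 nt; per-circRNA site counts and
  per-seed occurrence tables summarise collective sponge potential.
- *NET-seq*: replicate coverage tracks are averaged, capped at 10
  counts per nucleotide, and converted to Pol II/nt densities; circRNA
  exons and introns are compared against ordinal-position-adjusted
  reference features, and metagene profiles aggregate 300 nt intron
  flanks at natural scale around exons rescaled to a fixed bin count.

## Worked example

```python
from backsplice.simulate import SimConfig
from backsplice.pipeline import simulate_bundle, detect_bundle, evaluate_detection
from backsplice import ribo

config = SimConfig(seed=1)          # 20 genes, 10 planted circRNAs, ~50k pairs
bundle = simulate_bundle(config, with_fractions=True)
records = detect_bundle(bundle)
ev = evaluate_detection(records, bundle.truth)
print(f"detected {ev['n_detected']} circRNAs "
      f"(recall {ev['recall']:.2f}, precision {ev['precision']:.2f})")

matrix = ribo.build_fraction_matrix(records)
tc = ribo.select_tc_circrnas(matrix)
print(f"{len(tc)} of {len(matrix)} circRNAs are translation candidates")

key = sorted(records)[0]
rec = records[key]
print(f"{key}: exon span {rec.exon_span}, total JPM {rec.jpm['total']:.2f}")
```

prints

```
detected 10 circRNAs (recall 1.00, precision 1.00)
7 of 10 circRNAs are translation candidates
chr1:114129-117703:-: exon span 2, total JPM 181.23
```

All ten planted back-splice junctions are recovered with no false
calls; seven load onto ribosomal fractions and pass the tc threshold
(the other three were simulated as ribosome-free); the first record is
a two-exon circle whose JPM reflects the small toy library depth. The
same pipeline runs from the shell:

```sh
backsplice simulate --seed 1 --out sim/
backsplice detect --genome sim/genome.fa --annotation sim/annotation.refflat \
    --sample-sheet sim/sample_sheet.tsv --out calls/
backsplice report --simdir sim/ --out report/
```

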