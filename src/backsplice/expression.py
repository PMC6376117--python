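"""Linear-transcript expression quantification (FPKM / RPM).

FPKM here is computed on the union of exons across a gene's isoforms:
FPKM = count / (exonic_kb * mapped_millions). A gene is flagged
``expressed`` when its mean FPKM across the cell type's samples is >= 1
(the conventional total-RNA-seq cut-off, applied inclusively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, union_length
from .models import GeneModel

DEFAULT_FPKM_THRESHOLD = 1.0


@dataclass
class ExpressionTable:
    """Per-gene, per-sample counts and FPKM plus per-sample mapped totals."""

    counts: pd.DataFrame  # genes x samples, raw read counts
    fpkm: pd.DataFrame  # genes x samples
    mapped_reads: dict[str, float] = field(default_factory=dict)

    def mean_fpkm(self, samples: Optional[Sequence[str]] = None) -> pd.Series:
        cols = list(samples) if samples is not None else list(self.fpkm.columns)
        return self.fpkm[cols].mean(axis=1)

    def expressed_genes(
        self,
        samples: Optional[Sequence[str]] = None,
        threshold: float = DEFAULT_FPKM_THRESHOLD,
    ) -> set[str]:
        mean = self.mean_fpkm(samples)
        return set(mean.index[mean >= threshold])


def _masked_exonic_length(
    gene: GeneModel, mask: Optional[Sequence[GenomicInterval]]
) -> int:
    exons = gene.exon_union()
    if not mask:
        return sum(e.length for e in exons)
    total = 0
    for e in exons:
        covered = 0
        for m in mask:
            covered += e.overlap_nt(m)
        total += max(0, e.length - covered)
    return total


def compute_fpkm(
    genes: Mapping[str, GeneModel],
    counts: Mapping[str, Mapping[str, float]],
    mapped_reads: Mapping[str, float],
    mask: Optional[Sequence[GenomicInterval]] = None,
) -> ExpressionTable:
    """Build an ExpressionTable from per-gene per-sample counts.

    ``counts`` maps sample -> {gene_symbol: count}; genes absent from a
    sample count as 0. ``mask`` optionally excludes intervals (e.g.
    rRNA/tRNA/chrM loci) from the exonic length.
    """
    samples = list(counts)
    for s in samples:
        if s not in mapped_reads or mapped_reads[s] <= 0:
            raise ValueError(f"sample {s}: mapped reads must be > 0")
    gene_names = list(genes)
    exonic_len = {}
    for g in gene_names:
        length = _masked_exonic_length(genes[g], mask)
        if length <= 0:
            raise ValueError(f"gene {g}: zero exonic length after masking")
        exonic_len[g] = length
    count_df = pd.DataFrame(
        {s: [float(counts[s].get(g, 0.0)) for g in gene_names] for s in samples},
        index=gene_names,
    )
    fpkm_df = count_df.copy()
    for s in samples:
        denom = mapped_reads[s] / 1e6
        fpkm_df[s] = [
            count_df.at[g, s] / (exonic_len[g] / 1000.0) / denom
            for g in gene_names
        ]
    return ExpressionTable(count_df, fpkm_df, dict(mapped_reads))


def compute_rpm(
    counts: Mapping[str, Mapping[str, float]], mapped_reads: Mapping[str, float]
) -> pd.DataFrame:
    """Reads-per-million table (genes x samples)."""
    samples = list(counts)
    genes = sorted({g for s in samples for g in counts[s]})
    data = {}
    for s in samples:
        if mapped_reads.get(s, 0) <= 0:
            raise ValueError(f"sample {s}: mapped reads must be > 0")
        denom = mapped_reads[s] / 1e6
        data[s] = [counts[s].get(g, 0.0) / denom for g in genes]
    return pd.DataFrame(data, index=genes)
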