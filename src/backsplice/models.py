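"""Gene and transcript models with strand-aware ordinal positions.

Ordinal positions follow transcription order: exon 1 is the 5'-most exon
of the transcript, so on the minus strand exon 1 is the right-most exon
in genomic coordinates. Intron N lies between exons N and N+1 in
transcription order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]  # sorted by genomic start

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(
                f"transcript {self.transcript_id}: exons not sorted by start"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0].start

    @property
    def tx_end(self) -> int:
        return self.exons[-1].end

    @property
    def ordinal_map(self) -> dict[int, int]:
        """Genomic exon index -> ordinal position (1 = 5'-most transcribed)."""
        n = len(self.exons)
        if self.strand == "+":
            return {i: i + 1 for i in range(n)}
        return {i: n - i for i in range(n)}

    def exon_by_ordinal(self, ordinal: int) -> GenomicInterval:
        n = len(self.exons)
        if not 1 <= ordinal <= n:
            raise KeyError(f"ordinal {ordinal} out of range 1..{n}")
        idx = ordinal - 1 if self.strand == "+" else n - ordinal
        return self.exons[idx]

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


def derive_introns(transcript: TranscriptModel) -> list[tuple[int, GenomicInterval]]:
    """Return [(ordinal, interval), ...] introns in transcription order.

    Intron N sits between exons of ordinal N and N+1; a single-exon
    transcript has no introns.
    """
    exons = transcript.exons
    genomic_introns = [
        GenomicInterval(transcript.chrom, a.end, b.start, transcript.strand)
        for a, b in zip(exons, exons[1:])
        if b.start > a.end
    ]
    # zero-length gaps between abutting exons are skipped above; annotation
    # from the simulator never produces them, RefFlat input may.
    if transcript.strand == "-":
        genomic_introns.reverse()
    return [(i + 1, iv) for i, iv in enumerate(genomic_introns)]


def intron_by_ordinal(transcript: TranscriptModel, ordinal: int) -> GenomicInterval:
    for ordn, iv in derive_introns(transcript):
        if ordn == ordinal:
            return iv
    raise KeyError(
        f"transcript {transcript.transcript_id} has no intron {ordinal}"
    )


@dataclass
class GeneModel:
    gene_symbol: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_symbol} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_symbol}: transcripts span multiple "
                "chromosomes or strands"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def gene_span(self) -> GenomicInterval:
        start = min(t.tx_start for t in self.transcripts)
        end = max(t.tx_end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def gene_length(self) -> int:
        return self.gene_span.length

    def exon_union(self) -> list[GenomicInterval]:
        """Merged exon intervals across all isoforms."""
        spans = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged]

    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exon_union())

    @property
    def max_exon_count(self) -> int:
        return max(t.n_exons for t in self.transcripts)


def group_into_genes(transcripts: list[TranscriptModel]) -> dict[str, GeneModel]:
    """Group transcripts by gene symbol, preserving first-seen order."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_symbol, []).append(t)
    return {g: GeneModel(g, ts) for g, ts in by_gene.items()}


def spliced_sequence(transcript: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced (mature) transcript sequence, 5'->3' in transcript orientation."""
    seq = "".join(
        genome[transcript.chrom][e.start:e.end] for e in transcript.exons
    )
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
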