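"""Exonic circRNA detection from paired-end reads.

The caller is annotation-anchored: every candidate back-splice junction
joins the 3' end of a downstream (donor) exon to the 5' start of an
upstream (acceptor) exon of the same transcript. A library of junction
flank sequences is built from the genome and annotation, read pairs
that match the linear transcriptome (or genome) contiguously are
discarded, the remainder are searched against the junction library
(requiring a minimum anchor on both sides of the junction point and a
unique best junction), the mate of a junction read must fall inside the
predicted circle, and verified pair counts are normalised to junctions
per million mapped reads (JPM).

String matching is exact-first (substring search) with a pigeonhole
seed-and-extend Hamming fallback when mismatches are allowed, so the
whole path runs without external aligners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import GenomicInterval
from .models import TranscriptModel, reverse_complement
from .simulate import SampleReads

DEFAULT_JPM_THRESHOLD = 0.1


@dataclass
class DetectorConfig:
    k: int = 42  # junction flank length per side
    min_anchor: int = 8
    max_mismatches: int = 1
    jpm_threshold: float = DEFAULT_JPM_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.min_anchor <= self.k:
            raise ValueError("require 0 < min_anchor <= k")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class BackSpliceJunction:
    gene_symbol: str
    transcript_ids: list[str]
    chrom: str
    strand: str
    acceptor_exon: GenomicInterval
    acceptor_ordinal: int
    donor_exon: GenomicInterval
    donor_ordinal: int
    junction_seq: str  # donor 3' flank + acceptor 5' flank, transcript sense
    junction_point: int  # offset of the junction inside junction_seq
    circle_seq: str  # spliced circular sequence, junction at the wrap

    @property
    def span_start(self) -> int:
        return min(self.acceptor_exon.start, self.donor_exon.start)

    @property
    def span_end(self) -> int:
        return max(self.acceptor_exon.end, self.donor_exon.end)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.span_start}-{self.span_end}:{self.strand}"

    @property
    def exon_span(self) -> int:
        return self.donor_ordinal - self.acceptor_ordinal + 1


@dataclass
class CircRNARecord:
    junction: BackSpliceJunction
    counts: dict[str, int] = field(default_factory=dict)
    jpm: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return self.junction.key

    @property
    def exon_span(self) -> int:
        return self.junction.exon_span

    def mean_jpm(self, samples: Sequence[str]) -> float:
        return sum(self.jpm.get(s, 0.0) for s in samples) / len(samples)


# --------------------------------------------------------------------------
# sequence matching


class SubstringIndex:
    """Exact-first substring membership with a pigeonhole Hamming
    fallback for <= max_mismatches substitutions.

    The reference is a '#'-separated concatenation of sequences; a match
    must not cross a separator.
    """

    def __init__(self, sequences: Iterable[str]):
        self.text = "#".join(sequences)
        self._qgram_cache: dict[int, dict[str, list[int]]] = {}

    def _qgram_index(self, q: int) -> dict[str, list[int]]:
        idx = self._qgram_cache.get(q)
        if idx is None:
            idx = {}
            text = self.text
            for i in range(len(text) - q + 1):
                gram = text[i : i + q]
                if "#" in gram:
                    continue
                idx.setdefault(gram, []).append(i)
            self._qgram_cache[q] = idx
        return idx

    def contains(self, read: str, max_mismatches: int = 0) -> bool:
        if read in self.text:
            return True
        if max_mismatches <= 0:
            return False
        q = len(read) // (max_mismatches + 1)
        if q < 8:
            return self._scan(read, max_mismatches)
        idx = self._qgram_index(q)
        text = self.text
        n = len(text)
        seen: set[int] = set()
        for chunk_no in range(max_mismatches + 1):
            off = chunk_no * q
            for pos in idx.get(read[off : off + q], ()):
                start = pos - off
                if start < 0 or start + len(read) > n or start in seen:
                    continue
                seen.add(start)
                window = text[start : start + len(read)]
                if "#" in window:
                    continue
                mm = sum(a != b for a, b in zip(read, window))
                if mm <= max_mismatches:
                    return True
        return False

    def _scan(self, read: str, max_mismatches: int) -> bool:
        text = self.text
        m = len(read)
        for start in range(len(text) - m + 1):
            window = text[start : start + m]
            if "#" in window:
                continue
            if sum(a != b for a, b in zip(read, window)) <= max_mismatches:
                return True
        return False


def build_linear_reference(
    transcripts: Sequence[TranscriptModel], genome: Mapping[str, str]
) -> SubstringIndex:
    """Linear transcriptome (spliced isoforms, both orientations) plus
    the genome, against which read pairs are classified as linear."""
    from .models import spliced_sequence

    seqs: list[str] = []
    for t in transcripts:
        s = spliced_sequence(t, genome)
        seqs.append(s)
        seqs.append(reverse_complement(s))
    for chrom in sorted(genome):
        seqs.append(genome[chrom])
        seqs.append(reverse_complement(genome[chrom]))
    return SubstringIndex(seqs)


# --------------------------------------------------------------------------
# junction library


def build_backsplice_index(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    k: int = 42,
) -> dict[str, BackSpliceJunction]:
    """Enumerate one candidate junction per exon pair (acceptor ordinal
    <= donor ordinal) within each transcript; junctions shared between
    isoforms are deduplicated by key with transcript ids merged.

    The junction sequence is the donor exon's 3'-terminal k nt followed
    by the acceptor exon's 5'-initial k nt, in transcript orientation
    (flanks truncate to the exon when the exon is shorter than k).
    """
    index: dict[str, BackSpliceJunction] = {}
    for tx in transcripts:
        order = tx.exons_in_transcription_order()
        n = len(order)
        sense = [
            genome[tx.chrom][e.start:e.end]
            if tx.strand == "+"
            else reverse_complement(genome[tx.chrom][e.start:e.end])
            for e in order
        ]
        for a in range(n):
            for d in range(a, n):
                acc_exon, don_exon = order[a], order[d]
                span_start = min(acc_exon.start, don_exon.start)
                span_end = max(acc_exon.end, don_exon.end)
                key = f"{tx.chrom}:{span_start}-{span_end}:{tx.strand}"
                existing = index.get(key)
                if existing is not None:
                    if tx.transcript_id not in existing.transcript_ids:
                        existing.transcript_ids.append(tx.transcript_id)
                    continue
                donor_flank = sense[d][-k:]
                acceptor_flank = sense[a][:k]
                circle = "".join(sense[a : d + 1])
                index[key] = BackSpliceJunction(
                    gene_symbol=tx.gene_symbol,
                    transcript_ids=[tx.transcript_id],
                    chrom=tx.chrom,
                    strand=tx.strand,
                    acceptor_exon=acc_exon,
                    acceptor_ordinal=a + 1,
                    donor_exon=don_exon,
                    donor_ordinal=d + 1,
                    junction_seq=donor_flank + acceptor_flank,
                    junction_point=len(donor_flank),
                    circle_seq=circle,
                )
    return index


def cognate_linear_isoforms(
    junction: BackSpliceJunction, transcripts: Sequence[TranscriptModel]
) -> list[str]:
    """All isoforms whose exon structure fully covers the circle span:
    the acceptor exon's 5' boundary and the donor exon's 3' boundary
    must both be exon boundaries of the isoform, and the circle span
    must lie inside the transcript (inclusive assignment)."""
    out = []
    for t in transcripts:
        if t.chrom != junction.chrom or t.strand != junction.strand:
            continue
        if t.tx_start > junction.span_start or t.tx_end < junction.span_end:
            continue
        starts = {e.start for e in t.exons}
        ends = {e.end for e in t.exons}
        acc, don = junction.acceptor_exon, junction.donor_exon
        if junction.strand == "+":
            if acc.start in starts and don.end in ends:
                out.append(t.transcript_id)
        else:
            if acc.end in ends and don.start in starts:
                out.append(t.transcript_id)
    return out


# --------------------------------------------------------------------------
# read classification and junction hits


def classify_linear(
    read1: str,
    read2: str,
    linear_ref: SubstringIndex,
    config: DetectorConfig,
) -> str:
    """'linear' iff both mates match a linear transcript or the genome
    contiguously within max_mismatches, else 'candidate'."""
    if linear_ref.contains(read1, config.max_mismatches) and linear_ref.contains(
        read2, config.max_mismatches
    ):
        return "linear"
    return "candidate"


class JunctionMatcher:
    """Seed-and-extend matcher of reads against the junction library."""

    def __init__(self, index: Mapping[str, BackSpliceJunction], config: DetectorConfig):
        self.index = index
        self.config = config
        # q-gram map over junction windows: gram -> [(key, window_pos)]
        self._grams: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _gram_index(self, q: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._grams.get(q)
        if idx is None:
            idx = {}
            for key, j in self.index.items():
                seq = j.junction_seq
                for i in range(len(seq) - q + 1):
                    idx.setdefault(seq[i : i + q], []).append((key, i))
            self._grams[q] = idx
        return idx

    def _alignments(self, read: str) -> list[tuple[str, int, int]]:
        """All (junction_key, window_offset, mismatches) placements of
        the read that cross the junction point with sufficient anchors."""
        cfg = self.config
        q = max(8, len(read) // (cfg.max_mismatches + 1))
        idx = self._gram_index(q)
        candidates: set[tuple[str, int]] = set()
        n_chunks = max(1, len(read) // q)
        for chunk_no in range(min(n_chunks, cfg.max_mismatches + 1)):
            off = chunk_no * q
            for key, pos in idx.get(read[off : off + q], ()):
                candidates.add((key, pos - off))
        out = []
        for key, start in candidates:
            j = self.index[key]
            if start < 0 or start + len(read) > len(j.junction_seq):
                continue
            left = j.junction_point - start
            right = start + len(read) - j.junction_point
            if left < cfg.min_anchor or right < cfg.min_anchor:
                continue
            window = j.junction_seq[start : start + len(read)]
            mm = sum(a != b for a, b in zip(read, window))
            if mm <= cfg.max_mismatches:
                out.append((key, start, mm))
        return out

    def best_junction(self, read: str) -> Optional[str]:
        """Unique best-scoring junction for the read (either
        orientation), or None if no hit / ambiguous."""
        hits = self._alignments(read) + self._alignments(reverse_complement(read))
        if not hits:
            return None
        best = min(mm for _, _, mm in hits)
        keys = {key for key, _, mm in hits if mm == best}
        if len(keys) != 1:
            return None  # multi-mapping read discarded (uniqueness rule)
        return keys.pop()


def _matches_circle(seq: str, circle_doubled: str, max_mismatches: int) -> bool:
    if seq in circle_doubled or reverse_complement(seq) in circle_doubled:
        return True
    if max_mismatches <= 0:
        return False
    for probe in (seq, reverse_complement(seq)):
        m = len(probe)
        for start in range(len(circle_doubled) - m + 1):
            window = circle_doubled[start : start + m]
            if sum(a != b for a, b in zip(probe, window)) <= max_mismatches:
                return True
    return False


def verify_mate_inside(
    mate: str, junction: BackSpliceJunction, config: DetectorConfig
) -> bool:
    """The mate must lie inside the anticipated circle: it matches the
    circular (wrap-doubled) sequence in either orientation, which also
    accepts mates that themselves cross the junction."""
    doubled = junction.circle_seq + junction.circle_seq
    return _matches_circle(mate, doubled, config.max_mismatches)


def detect_junction_pairs(
    sample: SampleReads,
    linear_ref: SubstringIndex,
    matcher: JunctionMatcher,
    config: DetectorConfig,
) -> dict[str, int]:
    """Count verified circRNA pairs per junction key in one library.

    A pair contributes when it is not linear, at least one mate maps
    uniquely across a junction with min_anchor on both sides, and the
    other mate is inside the circle. A pair whose two mates map uniquely
    to different junctions is ambiguous and dropped.
    """
    counts: dict[str, int] = {}
    for (rid1, r1), (rid2, r2) in zip(sample.reads1, sample.reads2):
        if classify_linear(r1, r2, linear_ref, config) == "linear":
            continue
        k1 = matcher.best_junction(r1)
        k2 = matcher.best_junction(r2)
        if k1 and k2 and k1 != k2:
            continue
        key = k1 or k2
        if key is None:
            continue
        junction = matcher.index[key]
        if k1 and k2:
            verified = True  # both mates cross the junction
        elif k1:
            verified = verify_mate_inside(r2, junction, config)
        else:
            verified = verify_mate_inside(r1, junction, config)
        if verified:
            counts[key] = counts.get(key, 0) + 1
    return counts


# --------------------------------------------------------------------------
# counting, normalisation, thresholding


def count_and_normalize(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    mapped_reads: Mapping[str, float],
    index: Mapping[str, BackSpliceJunction],
) -> dict[str, CircRNARecord]:
    """JPM(sample) = verified pairs / (mapped reads / 1e6); junctions
    with zero pairs in every sample are omitted."""
    records: dict[str, CircRNARecord] = {}
    for sample, counts in per_sample_counts.items():
        total = mapped_reads.get(sample)
        if total is None or total <= 0:
            raise ValueError(f"sample {sample}: mapped reads must be > 0")
        for key, n in counts.items():
            if n <= 0:
                continue
            rec = records.setdefault(key, CircRNARecord(index[key]))
            rec.counts[sample] = n
    for rec in records.values():
        for sample in per_sample_counts:
            n = rec.counts.get(sample, 0)
            rec.jpm[sample] = n / (mapped_reads[sample] / 1e6)
    return records


def filter_by_abundance(
    records: Mapping[str, CircRNARecord],
    samples_by_cell_type: Mapping[str, Sequence[str]],
    threshold: float = DEFAULT_JPM_THRESHOLD,
    fraction_jpm: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> dict[str, CircRNARecord]:
    """Keep a circRNA iff its mean JPM over some cell type's samples is
    >= threshold (inclusive), or — rescue rule — its mean JPM across the
    eight polysome fractions is >= threshold when fraction data are
    supplied."""
    kept: dict[str, CircRNARecord] = {}
    # inclusive boundary, robust to float summation error
    eps = 1e-9 * max(1.0, abs(threshold))
    for key, rec in records.items():
        keep = any(
            rec.mean_jpm(samples) >= threshold - eps
            for samples in samples_by_cell_type.values()
            if samples
        )
        if not keep and fraction_jpm is not None:
            fr = fraction_jpm.get(key)
            if fr:
                vals = list(fr.values())
                if sum(vals) / len(vals) >= threshold - eps:
                    keep = True
        if keep:
            kept[key] = rec
    return kept


def overlap_summary(
    set_a: Iterable, set_b: Iterable, denominator_set: Iterable
) -> tuple[int, int, int]:
    """(|A intersect B|, |denominator|, percentage rounded to nearest
    integer). Raises on an empty denominator."""
    a, b, d = set(set_a), set(set_b), set(denominator_set)
    if not d:
        raise ValueError("empty denominator set")
    inter = len(a & b)
    pct = int(math.floor(100.0 * inter / len(d) + 0.5))
    return inter, len(d), pct


def overlap_percentage(intersection: int, denominator: int) -> int:
    """Percentage from printed counts, rounded to the nearest integer."""
    if denominator <= 0:
        raise ValueError("empty denominator")
    return int(math.floor(100.0 * intersection / denominator + 0.5))


# --------------------------------------------------------------------------
# one-call pipeline


def run_detection(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    samples: Mapping[str, SampleReads],
    config: Optional[DetectorConfig] = None,
    mapped_reads: Optional[Mapping[str, float]] = None,
) -> dict[str, CircRNARecord]:
    """Detect, verify and normalise circRNAs across libraries (no
    abundance filtering; apply :func:`filter_by_abundance` after)."""
    config = config or DetectorConfig()
    linear_ref = build_linear_reference(transcripts, genome)
    index = build_backsplice_index(transcripts, genome, config.k)
    matcher = JunctionMatcher(index, config)
    per_sample = {
        name: detect_junction_pairs(s, linear_ref, matcher, config)
        for name, s in samples.items()
    }
    totals = (
        dict(mapped_reads)
        if mapped_reads is not None
        else {name: float(s.mapped_reads) for name, s in samples.items()}
    )
    return count_and_normalize(per_sample, totals, index)
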