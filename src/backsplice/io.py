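"""Readers and writers for the text formats the pipeline consumes.

RefFlat, GTF (exon features), BED6, bedgraph, FASTA and FASTQ, all with
transparent gzip support. Internally everything is converted to 0-based
half-open coordinates; GTF's 1-based inclusive coordinates are shifted
on read.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .models import TranscriptModel

PathOrStream = Union[str, Path, IO[str]]


def xopen(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _as_stream(source: PathOrStream, mode: str = "rt") -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return xopen(source, mode), True
    return source, False


class MalformedRecordError(ValueError):
    pass


# --------------------------------------------------------------------------
# RefFlat

_REFFLAT_COLS = 11


def parse_refflat(source: PathOrStream) -> list[TranscriptModel]:
    """Parse RefFlat (geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds) into transcript
    models. Exon coordinates are already 0-based half-open in RefFlat."""
    stream, close = _as_stream(source)
    transcripts: list[TranscriptModel] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _REFFLAT_COLS:
                raise MalformedRecordError(
                    f"refFlat line {lineno}: expected {_REFFLAT_COLS} "
                    f"tab-separated fields, got {len(fields)}"
                )
            gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            if strand not in {"+", "-"}:
                raise MalformedRecordError(
                    f"refFlat line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                exon_count = int(fields[8])
                starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
                ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise MalformedRecordError(
                    f"refFlat line {lineno}: non-integer coordinate ({exc})"
                ) from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                raise MalformedRecordError(
                    f"refFlat line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends listed"
                )
            exons = [
                GenomicInterval(chrom, s, e, strand)
                for s, e in zip(starts, ends)
            ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_symbol=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    finally:
        if close:
            stream.close()
    return transcripts


def write_refflat(transcripts: Iterable[TranscriptModel], dest: PathOrStream) -> None:
    stream, close = _as_stream(dest, "wt")
    try:
        for t in transcripts:
            starts = ",".join(str(e.start) for e in t.exons) + ","
            ends = ",".join(str(e.end) for e in t.exons) + ","
            stream.write(
                "\t".join(
                    [
                        t.gene_symbol,
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.tx_start),
                        str(t.tx_start),
                        str(t.n_exons),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            stream.close()


# --------------------------------------------------------------------------
# GTF (exon features only)


def parse_gtf_exons(source: PathOrStream) -> list[TranscriptModel]:
    """Build transcript models from a GTF's exon features.

    GTF is 1-based inclusive; coordinates are converted to 0-based
    half-open on read. Requires gene_id/gene_name and transcript_id
    attributes.
    """
    stream, close = _as_stream(source)
    collected: dict[str, dict] = {}
    try:
        for line in stream:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attr: dict[str, str] = {}
            for chunk in attrs.strip().split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                key, _, val = chunk.partition(" ")
                attr[key] = val.strip().strip('"')
            tid = attr.get("transcript_id")
            gene = attr.get("gene_name", attr.get("gene_id", ""))
            if tid is None:
                raise MalformedRecordError("GTF exon without transcript_id")
            rec = collected.setdefault(
                tid, {"gene": gene, "chrom": chrom, "strand": strand, "exons": []}
            )
            rec["exons"].append((int(start) - 1, int(end)))
    finally:
        if close:
            stream.close()
    out = []
    for tid, rec in collected.items():
        exons = [
            GenomicInterval(rec["chrom"], s, e, rec["strand"])
            for s, e in sorted(rec["exons"])
        ]
        out.append(
            TranscriptModel(tid, rec["gene"], rec["chrom"], rec["strand"], exons)
        )
    return out


# --------------------------------------------------------------------------
# BED6 / bedgraph


def read_bed6(source: PathOrStream) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED6 -> [(interval, name, score), ...]; shorter BED is padded."""
    stream, close = _as_stream(source)
    out = []
    try:
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    finally:
        if close:
            stream.close()
    return out


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, float]], dest: PathOrStream
) -> None:
    stream, close = _as_stream(dest, "wt")
    try:
        for iv, name, score in records:
            stream.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
    finally:
        if close:
            stream.close()


def read_bedgraph(source: PathOrStream) -> list[tuple[str, int, int, float]]:
    stream, close = _as_stream(source)
    out = []
    try:
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.append((chrom, int(start), int(end), float(value)))
    finally:
        if close:
            stream.close()
    return out


def write_bedgraph(
    records: Iterable[tuple[str, int, int, float]], dest: PathOrStream
) -> None:
    stream, close = _as_stream(dest, "wt")
    try:
        for chrom, start, end, value in records:
            stream.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
    finally:
        if close:
            stream.close()


# --------------------------------------------------------------------------
# FASTA / FASTQ (Biopython-backed)


def read_fasta(source: Union[str, Path]) -> dict[str, str]:
    with xopen(source) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], dest: Union[str, Path], width: int = 70) -> None:
    with xopen(dest, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    reads: Iterable[tuple[str, str]], dest: Union[str, Path], quality: int = 40
) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    with xopen(dest, "wt") as fh:
        records = (
            SeqRecord(
                Seq(seq),
                id=rid,
                description="",
                letter_annotations={"phred_quality": [quality] * len(seq)},
            )
            for rid, seq in reads
        )
        SeqIO.write(records, fh, "fastq")


def read_fastq(source: Union[str, Path]) -> Iterator[tuple[str, str]]:
    with xopen(source) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()
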