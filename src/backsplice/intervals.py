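"""Genomic intervals and overlap arithmetic.

All coordinates in the package are 0-based half-open (BED convention):
an interval covers positions ``start .. end-1`` and has length
``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotides (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total nt covered by the union of intervals (per chromosome)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def intersect_intervals(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_fraction_of_query: float = 1e-9,
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """Report (query, subject, overlap_nt) pairs where the overlap covers at
    least ``min_fraction_of_query`` of the query's length.

    Mirrors ``intersectBed -f`` semantics: the fraction is taken of the
    *query* interval. The default fraction requires any overlap (>=1 nt).
    """
    if not (0 < min_fraction_of_query <= 1 or min_fraction_of_query < 1e-6):
        raise ValueError("min_fraction_of_query must be in (0, 1]")
    if not query or not subject:
        return []
    trees: dict[str, IntervalTree] = {}
    for iv in subject:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    out: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        needed = min_fraction_of_query * q.length
        for hit in sorted(tree.overlap(q.start, q.end)):
            s = hit.data
            ov = q.overlap_nt(s)
            if ov >= needed:
                out.append((q, s, ov))
    return out
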