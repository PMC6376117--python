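"""Polysome-fraction (TrIP-seq style) analysis of circRNAs.

Builds the circRNA x fraction JPM matrix (total cytoplasmic + eight
ribosomal fractions), derives the calculated ribosome-non-associated
pool Free* = 9 x total - sum(eight fractions), selects translation-
candidate (tc-)circRNAs by mean fraction JPM >= 0.1, scans circular
sequences for ORFs (AUG plus near-cognate CUG/GUG starts, stop search
over at most three passes of the circle, infinite-loop flag), overlaps
m6A sites with circularised exons and tests binary-feature enrichment
between tc and non-ribosomal circRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import CircRNARecord, cognate_linear_isoforms
from .features import _ordinal_in_isoform
from .intervals import GenomicInterval, intersect_intervals
from .models import TranscriptModel
from .stats import PropTestResult, two_sample_proportion_test

FRACTION_COLUMNS = [f"F{i}" for i in range(1, 9)]
TOTAL_COLUMN = "total"
FREE_COLUMN = "free_star"

START_CODONS = ("ATG", "CTG", "GTG")
STOP_CODONS = ("TAG", "TAA", "TGA")
MAX_PASSES = 3


def compute_free(total: float, fractions: Sequence[float]) -> tuple[float, float]:
    """Free* = 9 x total - sum of the eight fraction values, exactly as
    defined; returns (raw, reported) where a negative raw value is
    floored at 0 for reporting."""
    if len(fractions) != 8:
        raise ValueError(f"expected 8 fraction values, got {len(fractions)}")
    raw = 9.0 * total - float(sum(fractions))
    return raw, max(0.0, raw)


def build_fraction_matrix(
    records: Mapping[str, CircRNARecord],
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """CircRNA x (total, F1..F8, free_star, free_star_negative) JPM
    matrix. Column matching is by sample label, so input column order is
    irrelevant. Each column's JPM was normalised with that library's own
    mapped total upstream."""
    required = [TOTAL_COLUMN] + FRACTION_COLUMNS
    if samples is not None:
        missing = [c for c in required if c not in samples]
        if missing:
            raise ValueError(f"missing fraction column(s): {', '.join(missing)}")
    rows = {}
    flags = {}
    for key, rec in records.items():
        vals = {c: rec.jpm.get(c, 0.0) for c in required}
        raw, reported = compute_free(
            vals[TOTAL_COLUMN], [vals[c] for c in FRACTION_COLUMNS]
        )
        vals[FREE_COLUMN] = reported
        flags[key] = raw < 0
        rows[key] = vals
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=required + [FREE_COLUMN]
    )
    matrix["free_star_negative"] = pd.Series(flags, dtype=bool)
    return matrix


def select_tc_circrnas(
    matrix: pd.DataFrame, threshold: float = 0.1
) -> list[str]:
    """Translation candidates: mean JPM over the eight ribosomal
    fractions >= threshold (inclusive); the total column plays no role."""
    mean_fraction = matrix[FRACTION_COLUMNS].mean(axis=1)
    # inclusive boundary, robust to float summation error
    eps = 1e-9 * max(1.0, abs(threshold))
    return sorted(matrix.index[mean_fraction >= threshold - eps])


# --------------------------------------------------------------------------
# circular ORF scanning


@dataclass
class OrfRecord:
    start: int  # position on the circle, 0-based
    start_codon: str
    context: str  # 3 nt either side of the start codon (circular)
    frame: int
    stop: Optional[int]  # circle position of the stop codon, None if looping
    infinite_loop: bool
    length_codons: int  # start through last codon before the stop
    crosses_junction: bool


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_circ_orfs(sequence: str) -> list[OrfRecord]:
    """Scan a circular spliced sequence (junction implicit between the
    last and first nucleotide) for ORFs.

    Every AUG/CUG/GUG position opens an ORF; the codon walk proceeds
    circularly for at most three full passes of the sequence and stops
    at the first in-frame UAG/UAA/UGA. If no stop appears the ORF is
    flagged as an infinite loop (possible whenever the circle length is
    a multiple of 3). ``crosses_junction`` is set when the walk passes
    the back-splice point (position 0).
    """
    seq = _normalise(sequence)
    L = len(seq)
    if L < 3:
        raise ValueError("circular sequence must be at least 3 nt")
    ext = seq * (MAX_PASSES + 1)
    out: list[OrfRecord] = []
    for p in range(L):
        codon = ext[p : p + 3]
        if codon not in START_CODONS:
            continue
        stop_offset = None
        q = p + 3
        while q + 3 <= p + MAX_PASSES * L:
            c = ext[q : q + 3]
            if c in STOP_CODONS:
                stop_offset = q
                break
            q += 3
        context = (seq * 3)[p + L - 3 : p + L + 6]
        if stop_offset is None:
            out.append(
                OrfRecord(
                    start=p,
                    start_codon=codon,
                    context=context,
                    frame=p % 3,
                    stop=None,
                    infinite_loop=True,
                    length_codons=0,
                    crosses_junction=True,
                )
            )
        else:
            out.append(
                OrfRecord(
                    start=p,
                    start_codon=codon,
                    context=context,
                    frame=p % 3,
                    stop=stop_offset % L,
                    infinite_loop=False,
                    length_codons=(stop_offset - p) // 3,
                    crosses_junction=stop_offset + 3 > L,
                )
            )
    return out


def orf_table(records_orfs: Mapping[str, list[OrfRecord]]) -> pd.DataFrame:
    rows = []
    for key, orfs in records_orfs.items():
        for o in orfs:
            rows.append(
                {
                    "junction_key": key,
                    "start": o.start,
                    "start_codon": o.start_codon,
                    "context": o.context,
                    "frame": o.frame,
                    "stop": o.stop,
                    "infinite_loop": o.infinite_loop,
                    "length_codons": o.length_codons,
                    "crosses_junction": o.crosses_junction,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# m6A overlap


def circle_exon_intervals(
    record: CircRNARecord, transcripts: Sequence[TranscriptModel]
) -> list[GenomicInterval]:
    """Genomic exon intervals of the circle, from the first cognate
    isoform covering it."""
    j = record.junction
    tx_by_id = {t.transcript_id: t for t in transcripts}
    for tid in cognate_linear_isoforms(j, transcripts):
        tx = tx_by_id[tid]
        a = _ordinal_in_isoform(j, tx, "acceptor")
        d = _ordinal_in_isoform(j, tx, "donor")
        if a is None or d is None or a > d:
            continue
        return [tx.exon_by_ordinal(o) for o in range(a, d + 1)]
    return []


def m6a_overlap(
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
    m6a_sites: Iterable[GenomicInterval],
) -> dict[str, int]:
    """Per-circRNA count of (pooled, deduplicated) m6A sites falling
    within the circle's exons; any overlap counts."""
    unique_sites = sorted(set(m6a_sites))
    counts: dict[str, int] = {}
    for key, rec in records.items():
        exons = circle_exon_intervals(rec, transcripts)
        hits = intersect_intervals(unique_sites, exons)
        counts[key] = len({q for q, _, _ in hits})
    return counts


# --------------------------------------------------------------------------
# tc vs non-ribosomal feature enrichment


def feature_enrichment(
    tc_set: Iterable[str],
    non_ribosomal_set: Iterable[str],
    feature: Mapping[str, bool],
) -> PropTestResult:
    """Two-sample proportion test (continuity-corrected) of a binary
    per-circRNA feature between translation candidates and circRNAs
    absent from the ribosomal fractions."""
    tc = list(tc_set)
    nr = list(non_ribosomal_set)
    if not tc or not nr:
        raise ValueError("both groups must be non-empty")
    c1 = sum(bool(feature[k]) for k in tc)
    c2 = sum(bool(feature[k]) for k in nr)
    if c1 == len(tc) and c2 == len(nr):
        return PropTestResult(1.0, 1.0, 0.0, 1.0, "none")
    return two_sample_proportion_test(c1, len(tc), c2, len(nr))
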