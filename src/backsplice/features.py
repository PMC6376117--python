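"""Structural statistics of circRNA-producing loci.

Positional profiles of back-splice acceptor and donor exons (normalised
to the ordinal-position exon frequency of the gene set), circRNA exon
spans, exon/intron length tables for single- and multi-exon circRNAs
against a matched reference, and per-gene isoform diversity. Cognate
linear isoforms are assigned inclusively: every isoform whose exon
structure covers the circle contributes once per (circRNA, isoform)
pair, which avoids choosing a parent isoform arbitrarily at the cost of
occasional ordinal-1 assignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import BackSpliceJunction, CircRNARecord, cognate_linear_isoforms
from .models import GeneModel, TranscriptModel, derive_introns
from .stats import StatResult, mann_whitney_u

__all__ = [
    "PositionProfile",
    "exon_position_frequency",
    "backsplice_ordinal_counts",
    "backsplice_position_profile",
    "circ_exon_span_distribution",
    "length_stats",
    "reference_internal_features",
    "isoform_diversity",
    "mann_whitney_u",
    "StatResult",
]


@dataclass
class PositionProfile:
    role: str  # 'acceptor' or 'donor'
    raw_counts: dict[int, int]
    profile: dict[int, float] = field(default_factory=dict)

    @property
    def argmax(self) -> int:
        source = self.profile or self.raw_counts
        return max(source, key=lambda k: (source[k], -k))


def exon_position_frequency(
    transcripts: Iterable[TranscriptModel],
) -> dict[int, int]:
    """How many transcripts possess an exon at each ordinal position
    (a transcript with N exons contributes to positions 1..N)."""
    counts: Counter[int] = Counter()
    for t in transcripts:
        for pos in range(1, t.n_exons + 1):
            counts[pos] += 1
    return dict(counts)


def _ordinal_in_isoform(
    junction: BackSpliceJunction, tx: TranscriptModel, role: str
) -> Optional[int]:
    """Ordinal position of the junction's acceptor/donor exon within a
    cognate isoform, matched by the junction-side exon boundary."""
    exon = junction.acceptor_exon if role == "acceptor" else junction.donor_exon
    order = tx.exons_in_transcription_order()
    for i, e in enumerate(order, start=1):
        if role == "acceptor":
            boundary_ok = (
                e.start == exon.start if tx.strand == "+" else e.end == exon.end
            )
        else:
            boundary_ok = (
                e.end == exon.end if tx.strand == "+" else e.start == exon.start
            )
        if boundary_ok:
            return i
    return None


def backsplice_ordinal_counts(
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
    role: str,
) -> dict[int, int]:
    """Acceptor or donor ordinal counts with inclusive isoform
    assignment: each (circRNA, cognate isoform) pair contributes once."""
    if role not in {"acceptor", "donor"}:
        raise ValueError("role must be 'acceptor' or 'donor'")
    tx_by_id = {t.transcript_id: t for t in transcripts}
    counts: Counter[int] = Counter()
    for rec in records.values():
        for tid in cognate_linear_isoforms(rec.junction, transcripts):
            ordn = _ordinal_in_isoform(rec.junction, tx_by_id[tid], role)
            if ordn is not None:
                counts[ordn] += 1
    return dict(counts)


def backsplice_position_profile(
    role_counts: Mapping[int, int],
    exon_counts: Mapping[int, int],
    role: str = "acceptor",
) -> PositionProfile:
    """Normalise acceptor/donor counts to exon frequency: the per-
    position ratio count/exon_count is rescaled to sum to 1 over the
    positions where exons exist."""
    ratios = {
        pos: role_counts.get(pos, 0) / exon_counts[pos]
        for pos in sorted(exon_counts)
        if exon_counts[pos] > 0
    }
    total = sum(ratios.values())
    if total == 0:
        raise ValueError("all position ratios are zero")
    profile = {pos: r / total for pos, r in ratios.items()}
    return PositionProfile(role, dict(role_counts), profile)


def circ_exon_span_distribution(
    records: Mapping[str, CircRNARecord],
) -> dict[int, int]:
    """Histogram of circRNA exon spans (donor - acceptor + 1)."""
    return dict(Counter(rec.exon_span for rec in records.values()))


# --------------------------------------------------------------------------
# length statistics (Table-1-style)


def reference_internal_features(
    genes: Iterable[GeneModel],
) -> tuple[list[int], list[int]]:
    """(internal exon lengths, intron lengths) pooled over all isoforms
    of the reference genes; first and last exons are excluded."""
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    for gene in genes:
        for tx in gene.transcripts:
            order = tx.exons_in_transcription_order()
            exon_lengths.extend(e.length for e in order[1:-1])
            intron_lengths.extend(iv.length for _, iv in derive_introns(tx))
    return exon_lengths, intron_lengths


def _circ_feature_lengths(
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
) -> dict[tuple[str, str, str], list[int]]:
    """Lengths keyed by (class, role, kind); class in {single_exon,
    multi_exon}, role in {acceptor, internal, donor}, kind in
    {exon, intron}. Flanking introns: the intron immediately upstream of
    the acceptor exon and immediately downstream of the donor exon in
    transcription order."""
    tx_by_id = {t.transcript_id: t for t in transcripts}
    out: dict[tuple[str, str, str], list[int]] = {}

    def add(cls: str, role: str, kind: str, value: int) -> None:
        out.setdefault((cls, role, kind), []).append(value)

    for rec in records.values():
        j = rec.junction
        for tid in cognate_linear_isoforms(j, transcripts):
            tx = tx_by_id[tid]
            a = _ordinal_in_isoform(j, tx, "acceptor")
            d = _ordinal_in_isoform(j, tx, "donor")
            if a is None or d is None or a > d:
                continue
            cls = "single_exon" if a == d else "multi_exon"
            introns = dict(derive_introns(tx))
            if cls == "single_exon":
                length = tx.exon_by_ordinal(a).length
                add(cls, "acceptor", "exon", length)
                add(cls, "donor", "exon", length)
            else:
                add(cls, "acceptor", "exon", tx.exon_by_ordinal(a).length)
                add(cls, "donor", "exon", tx.exon_by_ordinal(d).length)
                for o in range(a + 1, d):
                    add(cls, "internal", "exon", tx.exon_by_ordinal(o).length)
                for o in range(a, d):
                    if o in introns:
                        add(cls, "internal", "intron", introns[o].length)
            if a - 1 in introns:  # upstream flank of the acceptor
                add(cls, "acceptor", "intron", introns[a - 1].length)
            if d in introns:  # downstream flank of the donor
                add(cls, "donor", "intron", introns[d].length)
    return out


def length_stats(
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
    reference_genes: Iterable[GeneModel],
) -> pd.DataFrame:
    """Table of mean/median/n per (class, role, kind) with a two-sided
    Mann-Whitney P against the matching reference row (reference =
    internal exons / introns of the reference gene set)."""
    ref_exons, ref_introns = reference_internal_features(reference_genes)
    lengths = _circ_feature_lengths(records, transcripts)
    rows = []
    for kind, ref in (("exon", ref_exons), ("intron", ref_introns)):
        if ref:
            rows.append(
                {
                    "class": "reference",
                    "role": "internal",
                    "kind": kind,
                    "mean": float(np.mean(ref)),
                    "median": float(np.median(ref)),
                    "n": len(ref),
                    "p_vs_reference": np.nan,
                }
            )
    for (cls, role, kind), vals in sorted(lengths.items()):
        ref = ref_exons if kind == "exon" else ref_introns
        p = np.nan
        if vals and ref:
            p = mann_whitney_u(vals, ref).p
        rows.append(
            {
                "class": cls,
                "role": role,
                "kind": kind,
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "n": len(vals),
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# isoform diversity


def isoform_diversity(
    genes: Mapping[str, GeneModel],
    records: Mapping[str, CircRNARecord],
    include_circ_as_isoform: bool = False,
) -> pd.Series:
    """Per-gene isoform count: annotated mRNA isoforms, optionally
    plus the number of distinct circRNAs the gene produces."""
    circ_per_gene: Counter[str] = Counter(
        rec.junction.gene_symbol for rec in records.values()
    )
    counts = {}
    for symbol, gene in genes.items():
        n = len(gene.transcripts)
        if include_circ_as_isoform:
            n += circ_per_gene.get(symbol, 0)
        counts[symbol] = n
    return pd.Series(counts, dtype=int)


def compare_isoform_diversity(
    diversity: pd.Series, circ_genes: Iterable[str], reference_genes: Iterable[str]
) -> StatResult:
    """Mann-Whitney comparison of isoform counts between circRNA-
    producing genes and a reference gene set."""
    circ_vals = [diversity[g] for g in circ_genes if g in diversity.index]
    ref_vals = [diversity[g] for g in reference_genes if g in diversity.index]
    return mann_whitney_u(circ_vals, ref_vals)
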