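"""Pol II dwell analysis from NET-seq coverage.

NET-seq signal per nucleotide is a surrogate for Pol II dwell time
(inverse elongation speed). The pipeline order is fixed: replicate
tracks are averaged positionwise, the combined track is capped at 10
counts per nucleotide to blunt outlier loci, and densities (signal per
nt, "Pol II/nt") are computed over exon/intron regions. Position-
adjusted comparisons contrast circRNA features with reference features
sampled at matching ordinal positions; metagene profiles aggregate 300
nt intron flanks at natural scale around exons rescaled to a fixed bin
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import CircRNARecord
from .features import _circ_feature_lengths  # noqa: F401  (shared convention)
from .features import _ordinal_in_isoform
from .detect import cognate_linear_isoforms
from .intervals import GenomicInterval
from .models import GeneModel, TranscriptModel, derive_introns
from .stats import mann_whitney_u

DEFAULT_CAP = 10.0
DEFAULT_FLANK = 300
DEFAULT_EXON_BINS = 100


@dataclass
class CoverageTrack:
    data: dict[str, np.ndarray]
    replicates: list[str] = field(default_factory=list)
    capped: bool = False

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])


def track_from_bedgraph(
    records: Iterable[tuple[str, int, int, float]],
    chrom_lengths: Optional[Mapping[str, int]] = None,
    name: str = "",
) -> CoverageTrack:
    records = list(records)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for chrom, _, end, _ in records:
        lengths[chrom] = max(lengths.get(chrom, 0), end)
    data = {c: np.zeros(n) for c, n in lengths.items()}
    for chrom, start, end, value in records:
        data[chrom][start:end] = value
    return CoverageTrack(data, replicates=[name] if name else [])


def combine_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Positionwise arithmetic mean of replicate tracks; a position
    present in fewer replicates is treated as 0 in the missing ones."""
    if not tracks:
        raise ValueError("need at least one track")
    chroms = set(tracks[0].data)
    for t in tracks[1:]:
        if set(t.data) != chroms:
            raise ValueError(
                "chromosome name mismatch between replicates: "
                f"{sorted(chroms)} vs {sorted(t.data)}"
            )
    out: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n = max(len(t.data[chrom]) for t in tracks)
        acc = np.zeros(n)
        for t in tracks:
            arr = t.data[chrom]
            acc[: len(arr)] += arr
        out[chrom] = acc / len(tracks)
    reps = [r for t in tracks for r in (t.replicates or ["?"])]
    return CoverageTrack(out, replicates=reps)


def cap_track(track: CoverageTrack, cap: float = DEFAULT_CAP) -> CoverageTrack:
    """Per-nucleotide cap: value' = min(value, cap). Idempotent."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return CoverageTrack(
        {c: np.minimum(arr, cap) for c, arr in track.data.items()},
        replicates=list(track.replicates),
        capped=True,
    )


def region_density(track: CoverageTrack, region: GenomicInterval) -> float:
    """Mean signal per nucleotide over [start, end)."""
    if region.length <= 0:
        raise ValueError("zero-length region")
    arr = track.data[region.chrom]
    window = arr[region.start : min(region.end, len(arr))]
    return float(window.sum()) / region.length


def regions_density(
    track: CoverageTrack, regions: Sequence[GenomicInterval]
) -> float:
    """Density over the concatenation of regions (length-weighted)."""
    total_len = sum(r.length for r in regions)
    if total_len == 0:
        raise ValueError("zero-length region set")
    total = sum(
        track.data[r.chrom][r.start : min(r.end, len(track.data[r.chrom]))].sum()
        for r in regions
    )
    return float(total) / total_len


# --------------------------------------------------------------------------
# circRNA feature regions and position-adjusted comparison


def circ_feature_regions(
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
) -> dict[tuple[str, str, str], list[tuple[int, GenomicInterval]]]:
    """(class, role, kind) -> [(ordinal, interval), ...] for the exons
    and introns of circRNA loci, with inclusive isoform assignment.
    class in {single_exon, multi_exon}; role in {acceptor, internal,
    donor}; kind in {exon, intron}."""
    tx_by_id = {t.transcript_id: t for t in transcripts}
    out: dict[tuple[str, str, str], list[tuple[int, GenomicInterval]]] = {}

    def add(cls, role, kind, ordinal, iv):
        out.setdefault((cls, role, kind), []).append((ordinal, iv))

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
                add(cls, "acceptor", "exon", a, tx.exon_by_ordinal(a))
            else:
                add(cls, "acceptor", "exon", a, tx.exon_by_ordinal(a))
                add(cls, "donor", "exon", d, tx.exon_by_ordinal(d))
                for o in range(a + 1, d):
                    add(cls, "internal", "exon", o, tx.exon_by_ordinal(o))
                for o in range(a, d):
                    if o in introns:
                        add(cls, "internal", "intron", o, introns[o])
            if a - 1 in introns:
                add(cls, "acceptor", "intron", a - 1, introns[a - 1])
            if d in introns:
                add(cls, "donor", "intron", d, introns[d])
    return out


def reference_feature_pool(
    genes: Iterable[GeneModel],
) -> dict[str, dict[int, list[GenomicInterval]]]:
    """kind ('exon'/'intron') -> ordinal -> intervals, pooled over all
    isoforms of the reference genes."""
    pool: dict[str, dict[int, list[GenomicInterval]]] = {"exon": {}, "intron": {}}
    for gene in genes:
        for tx in gene.transcripts:
            for i, e in enumerate(tx.exons_in_transcription_order(), start=1):
                pool["exon"].setdefault(i, []).append(e)
            for ordn, iv in derive_introns(tx):
                pool["intron"].setdefault(ordn, []).append(iv)
    return pool


def compare_position_adjusted(
    track: CoverageTrack,
    circ_regions: Mapping[tuple[str, str, str], Sequence[tuple[int, GenomicInterval]]],
    reference_pool: Mapping[str, Mapping[int, Sequence[GenomicInterval]]],
    seed: int = 0,
) -> pd.DataFrame:
    """Table-2-style comparison: per (class, role, kind) cell, the mean
    and median Pol II/nt density of circRNA features against a
    position-adjusted reference sample of equal size drawn from the
    expression-matched pool, with a two-sided Mann-Whitney P."""
    from .refsets import position_adjusted_sample

    rows = []
    for (cls, role, kind), feats in sorted(circ_regions.items()):
        if not feats:
            raise ValueError(f"empty circRNA cell ({cls}, {role}, {kind})")
        ordinals = [o for o, _ in feats]
        target = {
            o: ordinals.count(o) / len(ordinals) for o in sorted(set(ordinals))
        }
        pool = reference_pool[kind]
        matched = position_adjusted_sample(
            {o: list(pool.get(o, [])) for o in target},
            target,
            n=len(feats),
            seed=seed,
        )
        circ_dens = [region_density(track, iv) for _, iv in feats]
        ref_dens = [region_density(track, iv) for _, iv in matched.members]
        if not ref_dens:
            raise ValueError(f"empty reference cell ({cls}, {role}, {kind})")
        res = mann_whitney_u(circ_dens, ref_dens)
        rows.append(
            {
                "class": cls,
                "role": role,
                "kind": kind,
                "n_circ": len(circ_dens),
                "circ_mean": float(np.mean(circ_dens)),
                "circ_median": float(np.median(circ_dens)),
                "ref_mean": float(np.mean(ref_dens)),
                "ref_median": float(np.median(ref_dens)),
                "p": res.p,
                "direction": {"x": "circ-higher", "y": "circ-lower",
                              "none": "none"}[res.direction],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    group: str
    upstream: np.ndarray  # flank nt, transcription order, ending at the exon
    exon: np.ndarray  # exon_bins values
    downstream: np.ndarray  # flank nt, starting at the exon end
    n_regions: int


def _rebin(values: np.ndarray, bins: int) -> np.ndarray:
    """Length-weighted linear rebinning of a per-nt signal to a fixed
    number of bins (fractional nucleotides split proportionally)."""
    n = len(values)
    cum = np.concatenate(([0.0], np.cumsum(values)))
    edges = np.linspace(0.0, n, bins + 1)
    cum_at = np.interp(edges, np.arange(n + 1), cum)
    widths = np.diff(edges)
    return np.diff(cum_at) / widths


def metagene_profile(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    group: str = "",
    exon_bins: int = DEFAULT_EXON_BINS,
    flank: int = DEFAULT_FLANK,
) -> MetageneProfile:
    """Average signal around a group of exons: ``flank`` nt of the
    adjacent sequence at natural per-nt scale on both sides
    (transcription order) and the exon rescaled to ``exon_bins`` bins.
    Flank positions outside the chromosome are excluded from the mean
    rather than zero-filled."""
    if not regions:
        raise ValueError("empty region group")
    up = np.full((len(regions), flank), np.nan)
    ex = np.zeros((len(regions), exon_bins))
    down = np.full((len(regions), flank), np.nan)
    for i, region in enumerate(regions):
        arr = track.data[region.chrom]
        n = len(arr)
        exon_vals = arr[region.start : min(region.end, n)]
        if len(exon_vals) < region.length:
            exon_vals = np.concatenate(
                [exon_vals, np.zeros(region.length - len(exon_vals))]
            )
        left_lo = max(0, region.start - flank)
        left = arr[left_lo : region.start]
        right = arr[region.end : min(n, region.end + flank)]
        if region.strand == "-":
            exon_vals = exon_vals[::-1]
            upstream, downstream = right[::-1], left[::-1]
        else:
            upstream, downstream = left, right
        # upstream array ends at the exon edge; downstream starts at it
        up[i, flank - len(upstream):] = upstream
        down[i, : len(downstream)] = downstream
        ex[i] = _rebin(exon_vals.astype(float), exon_bins)
    return MetageneProfile(
        group=group,
        upstream=np.nanmean(up, axis=0),
        exon=ex.mean(axis=0),
        downstream=np.nanmean(down, axis=0),
        n_regions=len(regions),
    )


def acceptor_groups(
    circ_regions: Mapping[tuple[str, str, str], Sequence[tuple[int, GenomicInterval]]],
) -> dict[str, list[GenomicInterval]]:
    """The three standard metagene groups: acceptor exons at ordinal 2,
    acceptor exons at ordinal >= 3, and internal/donor exons."""
    groups: dict[str, list[GenomicInterval]] = {
        "acceptor_at_2": [],
        "acceptor_ge_3": [],
        "internal_donor": [],
    }
    for (cls, role, kind), feats in circ_regions.items():
        if kind != "exon":
            continue
        for ordinal, iv in feats:
            if role == "acceptor":
                if ordinal == 2:
                    groups["acceptor_at_2"].append(iv)
                elif ordinal >= 3:
                    groups["acceptor_ge_3"].append(iv)
            else:
                groups["internal_donor"].append(iv)
    return groups
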