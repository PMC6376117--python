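"""miRNA sponge scoring and RBP footprint analysis on circRNA exons.

Seed matches are exact reverse complements of miRNA positions 2-7
(Watson-Crick only, no G:U), scanned over the circular spliced
sequence including matches that straddle the back-splice junction. A
predicted target site (a ~20 nt footprint centred on the seed match)
is AGO-supported when at least half of it overlaps an AGO1-4 CLIP
interval extended 10 nt on both sides; junction-spanning sites are
evaluated on their larger genomic arm.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import CircRNARecord
from .intervals import GenomicInterval, intersect_intervals
from .models import TranscriptModel, reverse_complement
from .ribo import circle_exon_intervals
from .stats import PropTestResult, two_sample_proportion_test

SEED_START = 1  # 0-based: miRNA positions 2-7
SEED_END = 7
DEFAULT_AGO_EXTENSION = 10
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_SITE_FLANK = 7  # 6 nt seed + 7 nt each side ~ 20 nt site


@dataclass
class FootprintSite:
    protein: str
    interval: GenomicInterval
    source: str = ""

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("protein name must be non-empty")


@dataclass
class SeedMatch:
    mirna: str
    seed: str  # miRNA positions 2-7, 5'->3' (RNA alphabet)
    circ_key: str
    start: int  # 0-based circle coordinate of the 6-mer
    spans_junction: bool
    ago_supported: bool = False


def seed_of(mirna_sequence: str) -> str:
    return mirna_sequence.upper().replace("T", "U")[SEED_START:SEED_END]


def seed_target_dna(seed: str) -> str:
    """The 6-nt DNA sequence a target must contain: the reverse
    complement of the seed."""
    return reverse_complement(seed.upper().replace("U", "T"))


def scan_seed_matches(
    mirnas: Mapping[str, str],
    circ_sequences: Mapping[str, str],
) -> list[SeedMatch]:
    """All positions of each miRNA's 6-nt seed target on each circular
    sequence, wrap-aware (a match may straddle the back-splice point).
    miRNAs shorter than 7 nt are skipped with a warning."""
    matches: list[SeedMatch] = []
    for name in sorted(mirnas):
        seq = mirnas[name]
        if len(seq) < SEED_END:
            warnings.warn(f"miRNA {name} shorter than 7 nt; skipped")
            continue
        seed = seed_of(seq)
        target = seed_target_dna(seed)
        for key in sorted(circ_sequences):
            circ = circ_sequences[key].upper().replace("U", "T")
            L = len(circ)
            if L < len(target):
                continue
            extended = circ + circ[: len(target) - 1]
            pos = extended.find(target)
            while pos != -1:
                matches.append(
                    SeedMatch(
                        mirna=name,
                        seed=seed,
                        circ_key=key,
                        start=pos,
                        spans_junction=pos + len(target) > L,
                    )
                )
                pos = extended.find(target, pos + 1)
    return matches


# --------------------------------------------------------------------------
# circle coordinate -> genome


def circle_position_map(
    record: CircRNARecord, transcripts: Sequence[TranscriptModel]
) -> list[int]:
    """Genomic position of every circle coordinate, walking the circle
    exons in transcription order."""
    exons = circle_exon_intervals(record, transcripts)
    strand = record.junction.strand
    positions: list[int] = []
    for e in exons:  # transcription (ordinal) order from circle_exon_intervals
        if strand == "+":
            positions.extend(range(e.start, e.end))
        else:
            positions.extend(range(e.end - 1, e.start - 1, -1))
    return positions


def _genomic_arms(
    positions: Sequence[int], chrom: str, strand: str, start: int, length: int
) -> list[GenomicInterval]:
    L = len(positions)
    pos = sorted(positions[(start + i) % L] for i in range(length))
    arms = []
    run_start = prev = pos[0]
    for p in pos[1:]:
        if p != prev + 1:
            arms.append(GenomicInterval(chrom, run_start, prev + 1, strand))
            run_start = p
        prev = p
    arms.append(GenomicInterval(chrom, run_start, prev + 1, strand))
    return arms


def filter_by_ago(
    matches: Iterable[SeedMatch],
    records: Mapping[str, CircRNARecord],
    transcripts: Sequence[TranscriptModel],
    ago_sites: Iterable[GenomicInterval],
    extension: int = DEFAULT_AGO_EXTENSION,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    site_flank: int = DEFAULT_SITE_FLANK,
) -> list[SeedMatch]:
    """Set ``ago_supported`` on each match: the predicted target site
    (seed match plus ``site_flank`` nt on both sides, ~20 nt) must have
    >= ``min_fraction`` of its length inside some AGO interval extended
    by ``extension`` nt up- and downstream. Junction-spanning sites are
    judged on the arm with the larger overlap."""
    extended_sites = [
        GenomicInterval(s.chrom, max(0, s.start - extension), s.end + extension,
                        s.strand)
        for s in ago_sites
    ]
    pos_maps: dict[str, list[int]] = {}
    out = []
    for m in matches:
        rec = records.get(m.circ_key)
        if rec is None:
            out.append(m)
            continue
        if m.circ_key not in pos_maps:
            pos_maps[m.circ_key] = circle_position_map(rec, transcripts)
        positions = pos_maps[m.circ_key]
        L = len(positions)
        site_start = (m.start - site_flank) % L
        site_len = min(L, 6 + 2 * site_flank)
        arms = _genomic_arms(
            positions, rec.junction.chrom, rec.junction.strand, site_start,
            site_len,
        )
        needed = min_fraction * site_len
        best = 0
        for arm in arms:
            for s in extended_sites:
                best = max(best, arm.overlap_nt(s))
        m.ago_supported = best >= needed
        out.append(m)
    return out


# --------------------------------------------------------------------------
# summaries


def sponge_summary(
    matches: Iterable[SeedMatch],
    occurrence_threshold: int = 8,
    supported_only: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """(per-circRNA count of supported sites at distinct positions,
    per-seed table of distinct circRNAs carrying >= 1 supported site,
    flagged when at or above the occurrence threshold).

    Overlapping matches of the same seed at offset positions count as
    distinct sites.
    """
    use = [m for m in matches if m.ago_supported or not supported_only]
    per_circ: Counter[str] = Counter()
    seen: set[tuple[str, str, int]] = set()
    seed_circs: dict[str, set[str]] = {}
    for m in use:
        token = (m.circ_key, m.seed, m.start)
        if token in seen:
            continue
        seen.add(token)
        per_circ[m.circ_key] += 1
        seed_circs.setdefault(m.seed, set()).add(m.circ_key)
    per_circ_series = pd.Series(per_circ, dtype=int).sort_index()
    rows = [
        {
            "seed": seed,
            "n_circrnas": len(circs),
            "listed": len(circs) >= occurrence_threshold,
        }
        for seed, circs in sorted(seed_circs.items())
    ]
    return per_circ_series, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# RBP footprint class comparison


def rbp_footprint_comparison(
    sites_by_protein: Mapping[str, Sequence[GenomicInterval]],
    circ_exons: Sequence[GenomicInterval],
    non_circ_exons: Sequence[GenomicInterval],
    min_fraction: float = 0.75,
) -> pd.DataFrame:
    """Assign each footprint to the circularised or non-circularised
    exon class when >= ``min_fraction`` of the site overlaps an exon of
    that class, then per protein run the continuity-corrected proportion
    test between the classes. Site counts are normalised per exon by
    testing the proportion of exons that carry at least one footprint
    (raw per-class site totals are reported alongside)."""
    rows = []
    n_circ, n_non = len(circ_exons), len(non_circ_exons)
    for protein in sorted(sites_by_protein):
        sites = list(sites_by_protein[protein])
        if not sites:
            warnings.warn(f"protein {protein}: no sites; skipped")
            continue
        circ_hits = intersect_intervals(sites, circ_exons, min_fraction)
        non_hits = intersect_intervals(sites, non_circ_exons, min_fraction)
        in_circ = len({id(q) for q, _, _ in circ_hits})
        in_non = len({id(q) for q, _, _ in non_hits})
        exons_with_circ = len({(s.start, s.end) for _, s, _ in circ_hits})
        exons_with_non = len({(s.start, s.end) for _, s, _ in non_hits})
        result: PropTestResult = two_sample_proportion_test(
            exons_with_circ, n_circ, exons_with_non, n_non
        )
        rows.append(
            {
                "protein": protein,
                "sites_circ": in_circ,
                "sites_non_circ": in_non,
                "exons_circ": n_circ,
                "exons_non_circ": n_non,
                "prop_circ": result.prop1,
                "prop_non_circ": result.prop2,
                "p": result.p,
                "direction": {"first": "circ-higher", "second": "circ-lower",
                              "none": "none"}[result.direction],
            }
        )
    return pd.DataFrame(rows)
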