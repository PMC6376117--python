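"""End-to-end orchestration of the toy analysis.

Bundles the synthetic-data stages and runs detection, feature,
polysome, sponge and NET-seq analyses over them. Both the command-line
interface and the reproduction script drive these functions; tests use
them to exercise the whole stack at small problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import detect as det
from . import features as feat
from . import netseq as ns
from . import refsets
from . import ribo
from . import simulate as sim
from . import sponge as sp
from .models import GeneModel, TranscriptModel, group_into_genes


@dataclass
class SimBundle:
    config: sim.SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    truth: sim.TruthSet
    regulatory: Optional[sim.RegulatorySites] = None
    samples: dict[str, sim.SampleReads] = field(default_factory=dict)
    netseq_tracks: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def genes(self) -> dict[str, GeneModel]:
        return group_into_genes(self.transcripts)


def simulate_bundle(
    config: sim.SimConfig,
    with_reads: bool = True,
    with_fractions: bool = False,
    with_netseq: bool = False,
    with_regulatory: bool = False,
) -> SimBundle:
    genome, transcripts, truth = sim.generate_genome_and_annotation(config)
    bundle = SimBundle(config, genome, transcripts, truth)
    if with_regulatory:
        # mutates the genome (plants seed-match motifs), so run before reads
        bundle.regulatory = sim.simulate_regulatory_sites(
            genome, transcripts, truth, config
        )
    if with_fractions:
        bundle.samples = sim.simulate_fractions(genome, transcripts, truth, config)
    elif with_reads:
        bundle.samples = {
            sim.TOTAL_SAMPLE: sim.simulate_read_pairs(
                genome, transcripts, truth, config
            )
        }
    if with_netseq:
        chrom_len = len(genome[config.chrom])
        bundle.netseq_tracks = sim.simulate_netseq(
            transcripts, truth, config, chrom_len
        )
    return bundle


def detect_bundle(
    bundle: SimBundle,
    detector: Optional[det.DetectorConfig] = None,
    apply_filter: bool = True,
) -> dict[str, det.CircRNARecord]:
    detector = detector or det.DetectorConfig()
    records = det.run_detection(
        bundle.genome, bundle.transcripts, bundle.samples, detector
    )
    if not apply_filter:
        return records
    total_samples = [
        s for s in bundle.samples if s == sim.TOTAL_SAMPLE
    ] or list(bundle.samples)
    fraction_jpm = None
    if all(f in bundle.samples for f in sim.FRACTION_SAMPLES):
        fraction_jpm = {
            key: {f: rec.jpm.get(f, 0.0) for f in sim.FRACTION_SAMPLES}
            for key, rec in records.items()
        }
    return det.filter_by_abundance(
        records,
        {"toy": total_samples},
        detector.jpm_threshold,
        fraction_jpm=fraction_jpm,
    )


def evaluate_detection(
    records: dict[str, det.CircRNARecord], truth: sim.TruthSet
) -> dict[str, float]:
    """Junction-level recall and precision against the planted truth."""
    truth_keys = {c.junction_key for c in truth.circles if c.n_pairs > 0}
    detected = set(records)
    tp = len(detected & truth_keys)
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    precision = tp / len(detected) if detected else float("nan")
    return {
        "n_detected": len(detected),
        "n_planted": len(truth_keys),
        "true_positives": tp,
        "recall": recall,
        "precision": precision,
    }


def feature_signatures(
    bundle: SimBundle, records: dict[str, det.CircRNARecord]
) -> dict[str, object]:
    """Acceptor-position profile, span histogram and flanking-intron
    statistics for a detected circRNA set."""
    exon_counts = feat.exon_position_frequency(bundle.transcripts)
    acc_counts = feat.backsplice_ordinal_counts(
        records, bundle.transcripts, "acceptor"
    )
    profile = feat.backsplice_position_profile(acc_counts, exon_counts, "acceptor")
    spans = feat.circ_exon_span_distribution(records)
    genes = bundle.genes
    circ_genes = {rec.junction.gene_symbol for rec in records.values()}
    reference = [g for name, g in genes.items() if name not in circ_genes]
    table = feat.length_stats(records, bundle.transcripts, reference)
    flank = table[
        (table["kind"] == "intron") & table["role"].isin(["acceptor", "donor"])
        & (table["class"] != "reference")
    ]
    flank_p = float(flank["p_vs_reference"].min()) if len(flank) else float("nan")
    return {
        "profile": profile,
        "acceptor_argmax": profile.argmax,
        "spans": spans,
        "span_mode": max(spans, key=lambda k: (spans[k], -k)) if spans else None,
        "length_table": table,
        "flanking_intron_min_p": flank_p,
    }


def netseq_comparison(
    bundle: SimBundle, records: dict[str, det.CircRNARecord], seed: int = 0
):
    """Combine replicates, cap, and produce the position-adjusted
    density comparison table plus metagene groups."""
    tracks = [
        ns.CoverageTrack({c: a.astype(float) for c, a in t.items()},
                         replicates=[f"rep{i+1}"])
        for i, t in enumerate(bundle.netseq_tracks)
    ]
    combined = ns.cap_track(ns.combine_replicates(tracks))
    circ_regions = ns.circ_feature_regions(records, bundle.transcripts)
    circ_genes = {rec.junction.gene_symbol for rec in records.values()}
    reference_genes = [
        g for name, g in bundle.genes.items() if name not in circ_genes
    ]
    pool = ns.reference_feature_pool(reference_genes)
    table = ns.compare_position_adjusted(combined, circ_regions, pool, seed=seed)
    return combined, table, circ_regions


def records_from_truth(bundle: SimBundle) -> dict[str, det.CircRNARecord]:
    """CircRNA records taken directly from the planted truth (used by
    stages that need circle definitions without re-running detection)."""
    index = det.build_backsplice_index(
        bundle.transcripts, bundle.genome, k=42
    )
    out = {}
    for c in bundle.truth.circles:
        j = index.get(c.junction_key)
        if j is not None:
            out[c.junction_key] = det.CircRNARecord(j)
    return out


def circ_sequences(
    bundle: SimBundle, records: dict[str, det.CircRNARecord]
) -> dict[str, str]:
    return {key: rec.junction.circle_seq for key, rec in records.items()}
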