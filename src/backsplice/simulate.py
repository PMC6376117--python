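"""Synthetic dataset generator for the circRNA pipeline.

Generates a toy genome with multi-exon genes, plants back-spliced
circRNAs with configurable acceptor-position bias, exon-span law and
flanking-intron inflation, and simulates the read sets and coverage
tracks every downstream stage consumes:

* paired-end total-RNA reads (linear background + circular molecules,
  junction-crossing reads arise naturally from fragments drawn on the
  circle),
* nine polysome-profiling libraries (total cytoplasmic + eight
  ribosomal fractions) with a per-molecule multinomial loading model,
* NET-seq coverage for two replicates with exon/intron dwell factors
  and boundary stalls,
* AGO/RBP footprints, planted miRNA seed matches and m6A sites.

Every read ID carries a truth tag (class and origin) so detection can
be evaluated without any alignment. All randomness flows from
``SimConfig.seed`` through per-stage child generators, so outputs are
byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import IO, Optional, Sequence, Union

import numpy as np
import yaml

from .intervals import GenomicInterval
from .models import (
    GeneModel,
    TranscriptModel,
    group_into_genes,
    reverse_complement,
    spliced_sequence,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FRACTION_SAMPLES = [f"F{i}" for i in range(1, 9)]
TOTAL_SAMPLE = "total"

# mature miRNA sequences planted by default: a let-7 family member
# (seed GAGGUA at positions 2-7) and a miR-16 family member (seed AGCAGC)
DEFAULT_MIRNAS = {
    "let-7-like": "UGAGGUAGUAGGUUGUAUAGUU",
    "miR-16-like": "UAGCAGCACGUAAAUAUUGGCG",
}


@dataclass
class SimConfig:
    seed: int = 1
    chrom: str = "chr1"
    # gene architecture
    n_genes: int = 20
    n_circ_genes: int = 10
    exon_count_min: int = 4
    exon_count_max: int = 8
    exon_len_first: tuple[int, int] = (120, 400)
    exon_len_internal: tuple[int, int] = (80, 220)
    exon_len_last: tuple[int, int] = (150, 500)
    intron_len: tuple[int, int] = (200, 1400)
    first_intron_factor: float = 3.0
    flanking_intron_factor: float = 5.0
    intergenic_gap: int = 300
    max_extra_isoforms: int = 2
    extra_isoform_prob: float = 0.4
    # planted circRNAs: probability mass over acceptor ordinal 1..len(list)
    circ_acceptor_probs: tuple[float, ...] = (0.05, 0.55, 0.25, 0.15)
    # probability mass over exon span 1..len(list)
    circ_span_probs: tuple[float, ...] = (0.25, 0.45, 0.20, 0.10)
    circ_pairs_min: int = 120
    circ_pairs_max: int = 200
    # read simulation
    read_length: int = 50
    fragment_mean: int = 170
    fragment_sd: int = 30
    n_read_pairs: int = 48_000
    error_rate: float = 0.0
    # polysome fractions: P(molecule lands in fraction i), residue = free
    circ_fraction_probs: tuple[float, ...] = (
        0.22, 0.18, 0.14, 0.10, 0.06, 0.04, 0.03, 0.03,
    )
    mrna_fraction_probs: tuple[float, ...] = (
        0.04, 0.05, 0.06, 0.08, 0.10, 0.12, 0.15, 0.25,
    )
    circ_ribo_free_fraction: float = 0.3  # circles with no ribosome loading
    n_fraction_read_pairs: int = 48_000  # linear budget across the 8 fractions
    # NET-seq dwell model (expected signal = gene_rate * dwell(position))
    netseq_gene_rate: float = 3.0
    netseq_exon_dwell: float = 3.0
    netseq_intron_dwell: float = 1.0
    netseq_stall_height: float = 4.0
    netseq_stall_width: int = 15
    netseq_accel: float = 0.0  # linear dwell decline toward gene 3' end (0..1)
    circ_exon_dwell_multiplier: float = 1.0
    circ_intron_dwell_multiplier: float = 1.0
    # regulatory sites
    ago_site_width: int = 20
    n_supported_matches: int = 8
    n_unsupported_matches: int = 4
    n_junction_matches: int = 2
    rbp_sites_per_kb: float = 0.5
    rbp_proteins: tuple[str, ...] = ("HNRNPC", "ELAVL1", "PTBP1")
    rbp_circ_density_multiplier: float = 1.0
    m6a_sites_per_kb: float = 0.6
    mirnas: dict = field(default_factory=lambda: dict(DEFAULT_MIRNAS))

    def __post_init__(self) -> None:
        for name in ("circ_acceptor_probs", "circ_span_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("circ_fraction_probs", "mrna_fraction_probs"):
            probs = getattr(self, name)
            if len(probs) != 8:
                raise ValueError(f"{name} must have 8 entries")
            if sum(probs) > 1.0 + 1e-9:
                raise ValueError(f"{name} must sum to <= 1 (residue = free)")
        for name in ("exon_len_first", "exon_len_internal", "exon_len_last",
                     "intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}: lengths must be positive, lo <= hi")
        if self.n_circ_genes > self.n_genes:
            raise ValueError("n_circ_genes cannot exceed n_genes")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage child generator."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,))
        )

    def to_yaml(self, dest: Union[str, IO[str]]) -> None:
        data = asdict(self)
        text = yaml.safe_dump(data, sort_keys=True)
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "wt") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, source: Union[str, IO[str]]) -> "SimConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        for key, val in list(data.items()):
            if isinstance(val, list):
                data[key] = tuple(val)
        return cls(**data)


@dataclass
class CircTruth:
    gene: str
    transcript_id: str
    acceptor_ordinal: int
    donor_ordinal: int
    chrom: str
    span_start: int
    span_end: int
    strand: str
    circle_length: int
    n_pairs: int

    @property
    def junction_key(self) -> str:
        return f"{self.chrom}:{self.span_start}-{self.span_end}:{self.strand}"

    @property
    def exon_span(self) -> int:
        return self.donor_ordinal - self.acceptor_ordinal + 1


@dataclass
class TruthSet:
    circles: list[CircTruth] = field(default_factory=list)
    gene_weights: dict[str, float] = field(default_factory=dict)

    @property
    def circ_genes(self) -> set[str]:
        return {c.gene for c in self.circles}

    def to_tsv(self, dest: Union[str, IO[str]]) -> None:
        header = (
            "gene\ttranscript_id\tacceptor_ordinal\tdonor_ordinal\tchrom\t"
            "span_start\tspan_end\tstrand\tcircle_length\tn_pairs\n"
        )
        lines = [header]
        for c in self.circles:
            lines.append(
                f"{c.gene}\t{c.transcript_id}\t{c.acceptor_ordinal}\t"
                f"{c.donor_ordinal}\t{c.chrom}\t{c.span_start}\t{c.span_end}\t"
                f"{c.strand}\t{c.circle_length}\t{c.n_pairs}\n"
            )
        lines.append("#gene_weights\t" + ",".join(
            f"{g}:{w:.6g}" for g, w in self.gene_weights.items()) + "\n")
        text = "".join(lines)
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "wt") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, source: Union[str, IO[str]]) -> "TruthSet":
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source) as fh:
                lines = fh.read().splitlines()
        truth = cls()
        for line in lines[1:]:
            if not line:
                continue
            if line.startswith("#gene_weights"):
                _, _, payload = line.partition("\t")
                for item in payload.split(","):
                    if item:
                        g, _, w = item.rpartition(":")
                        truth.gene_weights[g] = float(w)
                continue
            f = line.split("\t")
            truth.circles.append(
                CircTruth(f[0], f[1], int(f[2]), int(f[3]), f[4], int(f[5]),
                          int(f[6]), f[7], int(f[8]), int(f[9]))
            )
        return truth


@dataclass
class SampleReads:
    """One sequencing library: paired reads plus its mapped-read total."""

    sample: str
    reads1: list[tuple[str, str]] = field(default_factory=list)
    reads2: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mapped_reads(self) -> int:
        return len(self.reads1) + len(self.reads2)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _uniform_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


# --------------------------------------------------------------------------
# genome + annotation


def generate_genome_and_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], TruthSet]:
    """Build the toy genome, its RefFlat-style annotation and the truth
    skeleton of planted circRNAs (read counts assigned here, reads drawn
    later).

    Genes are laid left-to-right on one chromosome, non-overlapping,
    with random strands. circRNA-designated genes draw the introns
    flanking the planted circle from a ``flanking_intron_factor``-scaled
    length law; intron 1 is scaled by ``first_intron_factor`` in every
    gene, mirroring the long-first-intron trend of mammalian genes.
    """
    rng = config.rng(stage=0)
    truth = TruthSet()
    transcripts: list[TranscriptModel] = []
    chrom_parts: list[str] = []
    cursor = 0

    if config.n_genes == 0:
        return {config.chrom: _random_seq(rng, 100)}, [], truth

    circ_flags = np.zeros(config.n_genes, dtype=bool)
    circ_flags[
        rng.choice(config.n_genes, size=config.n_circ_genes, replace=False)
    ] = True

    for gi in range(config.n_genes):
        gene = f"G{gi + 1:03d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_exons = int(
            rng.integers(config.exon_count_min, config.exon_count_max + 1)
        )
        # lengths in transcription order
        exon_lens = [_uniform_len(rng, config.exon_len_first)]
        exon_lens += [
            _uniform_len(rng, config.exon_len_internal)
            for _ in range(max(0, n_exons - 2))
        ]
        if n_exons > 1:
            exon_lens.append(_uniform_len(rng, config.exon_len_last))
        intron_lens = [
            _uniform_len(rng, config.intron_len) for _ in range(n_exons - 1)
        ]
        if intron_lens:
            intron_lens[0] = int(intron_lens[0] * config.first_intron_factor)

        acceptor = donor = None
        if circ_flags[gi] and n_exons >= 2:
            probs = np.asarray(config.circ_acceptor_probs)
            k = min(len(probs), n_exons)
            p = probs[:k] / probs[:k].sum()
            acceptor = int(rng.choice(np.arange(1, k + 1), p=p))
            span_probs = np.asarray(config.circ_span_probs)
            sp = span_probs / span_probs.sum()
            span = int(rng.choice(np.arange(1, len(sp) + 1), p=sp))
            donor = min(acceptor + span - 1, n_exons)
            # inflate the flanking introns (upstream of acceptor, downstream
            # of donor, in transcription order)
            if acceptor >= 2:
                intron_lens[acceptor - 2] = int(
                    intron_lens[acceptor - 2] * config.flanking_intron_factor
                )
            if donor < n_exons:
                intron_lens[donor - 1] = int(
                    intron_lens[donor - 1] * config.flanking_intron_factor
                )

        # lay out genomically: transcription order equals genomic order on +,
        # is reversed on -
        if strand == "-":
            exon_lens_genomic = exon_lens[::-1]
            intron_lens_genomic = intron_lens[::-1]
        else:
            exon_lens_genomic = exon_lens
            intron_lens_genomic = intron_lens

        gene_start = cursor + config.intergenic_gap
        pos = gene_start
        exons = []
        for i, elen in enumerate(exon_lens_genomic):
            exons.append(GenomicInterval(config.chrom, pos, pos + elen, strand))
            pos += elen
            if i < len(intron_lens_genomic):
                pos += intron_lens_genomic[i]
        gene_end = pos
        gene_len = gene_end - gene_start
        chrom_parts.append(_random_seq(rng, config.intergenic_gap))
        chrom_parts.append(_random_seq(rng, gene_len))
        cursor = gene_end

        tx_main = TranscriptModel(f"{gene}.t1", gene, config.chrom, strand, exons)
        transcripts.append(tx_main)
        # extra isoforms: drop one internal exon each (never a circle exon)
        n_extra = int(
            rng.binomial(config.max_extra_isoforms, config.extra_isoform_prob)
        )
        protected: set[int] = set()
        if acceptor is not None:
            protected = set(range(acceptor, donor + 1))
        droppable = [
            o for o in range(2, n_exons) if o not in protected
        ]
        for j in range(n_extra):
            if not droppable:
                break
            drop_ord = int(rng.choice(droppable))
            keep = [
                e
                for idx, e in enumerate(exons)
                if tx_main.ordinal_map[idx] != drop_ord
            ]
            transcripts.append(
                TranscriptModel(f"{gene}.t{j + 2}", gene, config.chrom, strand, keep)
            )

        truth.gene_weights[gene] = float(rng.lognormal(0.0, 0.8))

        if acceptor is not None:
            span_exons = [
                tx_main.exon_by_ordinal(o) for o in range(acceptor, donor + 1)
            ]
            span_start = min(e.start for e in span_exons)
            span_end = max(e.end for e in span_exons)
            circle_len = sum(e.length for e in span_exons)
            n_pairs = int(
                rng.integers(config.circ_pairs_min, config.circ_pairs_max + 1)
            )
            truth.circles.append(
                CircTruth(
                    gene=gene,
                    transcript_id=tx_main.transcript_id,
                    acceptor_ordinal=acceptor,
                    donor_ordinal=donor,
                    chrom=config.chrom,
                    span_start=span_start,
                    span_end=span_end,
                    strand=strand,
                    circle_length=circle_len,
                    n_pairs=n_pairs,
                )
            )

    chrom_parts.append(_random_seq(rng, config.intergenic_gap))
    genome = {config.chrom: "".join(chrom_parts)}
    return genome, transcripts, truth


# --------------------------------------------------------------------------
# reads


def circle_sequence(
    circ: CircTruth, transcripts: Sequence[TranscriptModel], genome: dict[str, str]
) -> str:
    """Spliced circular sequence, 5'->3'; the back-splice junction sits
    between the last and first nucleotide."""
    tx = next(t for t in transcripts if t.transcript_id == circ.transcript_id)
    parts = [
        genome[tx.chrom][e.start:e.end]
        for o in range(circ.acceptor_ordinal, circ.donor_ordinal + 1)
        for e in [tx.exon_by_ordinal(o)]
    ]
    if tx.strand == "+":
        return "".join(parts)
    # parts are already in transcription (ordinal) order; each genomic
    # slice just needs strand correction
    return "".join(reverse_complement(p) for p in parts)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _pair_from_fragment(fragment: str, read_length: int) -> tuple[str, str]:
    r1 = fragment[:read_length]
    r2 = reverse_complement(fragment[-read_length:])
    return r1, r2


def _draw_fragment_length(
    config: SimConfig, rng: np.random.Generator, max_len: int
) -> int:
    f = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
    return max(config.read_length, min(f, max_len))


def simulate_read_pairs(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
    sample: str = TOTAL_SAMPLE,
    stage: int = 1,
    circ_pair_counts: Optional[dict[str, int]] = None,
    n_linear_pairs: Optional[int] = None,
) -> SampleReads:
    """Simulate one paired-end library.

    Linear pairs follow annotated splicing (gene chosen by abundance
    weight, isoform uniform); circular pairs are fragments of the
    circular sequence, so junction-crossing reads arise naturally when a
    fragment wraps past the back-splice point. Read IDs encode the truth
    class: ``sim|circ|<gene>|<junction_key>|<serial>`` or
    ``sim|linear|<gene>|-|<serial>``.
    """
    rng = config.rng(stage)
    out = SampleReads(sample)
    serial = 0

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_symbol, []).append(t)

    # circular molecules
    for circ in truth.circles:
        n_pairs = (
            circ_pair_counts.get(circ.junction_key, 0)
            if circ_pair_counts is not None
            else circ.n_pairs
        )
        if n_pairs <= 0:
            continue
        seq = circle_sequence(circ, transcripts, genome)
        L = len(seq)
        if config.read_length > L:
            import warnings

            warnings.warn(
                f"read length {config.read_length} exceeds circle "
                f"{circ.junction_key} ({L} nt); skipped"
            )
            continue
        doubled = seq + seq
        for _ in range(n_pairs):
            frag_len = _draw_fragment_length(config, rng, L)
            start = int(rng.integers(0, L))
            fragment = doubled[start : start + frag_len]
            r1, r2 = _pair_from_fragment(fragment, config.read_length)
            rid = f"sim|circ|{circ.gene}|{circ.junction_key}|{serial}"
            serial += 1
            out.reads1.append((rid, _apply_errors(r1, config.error_rate, rng)))
            out.reads2.append((rid, _apply_errors(r2, config.error_rate, rng)))

    # linear background
    n_linear = config.n_read_pairs if n_linear_pairs is None else n_linear_pairs
    genes = sorted(truth.gene_weights) or sorted(by_gene)
    if genes and n_linear > 0:
        weights = np.array(
            [truth.gene_weights.get(g, 1.0) for g in genes], dtype=float
        )
        weights /= weights.sum()
        gene_draws = rng.choice(len(genes), size=n_linear, p=weights)
        spliced_cache: dict[str, str] = {}
        for gidx in gene_draws:
            gene = genes[int(gidx)]
            isoforms = by_gene.get(gene)
            if not isoforms:
                continue
            tx = isoforms[int(rng.integers(0, len(isoforms)))]
            seq = spliced_cache.get(tx.transcript_id)
            if seq is None:
                seq = spliced_sequence(tx, genome)
                spliced_cache[tx.transcript_id] = seq
            if len(seq) < config.read_length:
                continue
            frag_len = _draw_fragment_length(config, rng, len(seq))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            fragment = seq[start : start + frag_len]
            r1, r2 = _pair_from_fragment(fragment, config.read_length)
            rid = f"sim|linear|{gene}|-|{serial}"
            serial += 1
            out.reads1.append((rid, _apply_errors(r1, config.error_rate, rng)))
            out.reads2.append((rid, _apply_errors(r2, config.error_rate, rng)))
    return out


def simulate_fractions(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
) -> dict[str, SampleReads]:
    """Simulate the nine polysome-profiling libraries.

    Each circular/linear molecule's read pairs are allocated over the
    eight ribosomal fractions by a multinomial draw from the class's
    loading probabilities; the residual mass is the free (non-ribosomal)
    pool, which is sequenced only in the total-cytoplasmic library.
    """
    rng = config.rng(stage=2)
    circ_p = np.asarray(config.circ_fraction_probs, dtype=float)
    n_free = int(round(config.circ_ribo_free_fraction * len(truth.circles)))
    free_idx = set(
        rng.choice(len(truth.circles), size=n_free, replace=False).tolist()
    ) if n_free else set()
    circ_alloc: dict[str, np.ndarray] = {}
    for i, circ in enumerate(truth.circles):
        if i in free_idx:  # entirely ribosome-non-associated
            alloc = np.zeros(9, dtype=int)
            alloc[8] = circ.n_pairs
        else:
            probs = np.append(circ_p, max(0.0, 1.0 - circ_p.sum()))
            alloc = rng.multinomial(circ.n_pairs, probs)
        circ_alloc[circ.junction_key] = alloc

    mrna_p = np.asarray(config.mrna_fraction_probs, dtype=float)
    mrna_probs = np.append(mrna_p, max(0.0, 1.0 - mrna_p.sum()))
    linear_alloc = rng.multinomial(config.n_fraction_read_pairs, mrna_probs)

    samples: dict[str, SampleReads] = {}
    samples[TOTAL_SAMPLE] = simulate_read_pairs(
        genome, transcripts, truth, config, sample=TOTAL_SAMPLE, stage=10
    )
    for i, name in enumerate(FRACTION_SAMPLES):
        circ_counts = {k: int(a[i]) for k, a in circ_alloc.items()}
        samples[name] = simulate_read_pairs(
            genome,
            transcripts,
            truth,
            config,
            sample=name,
            stage=11 + i,
            circ_pair_counts=circ_counts,
            n_linear_pairs=int(linear_alloc[i]),
        )
    return samples


# --------------------------------------------------------------------------
# NET-seq


def expected_netseq_profile(
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
    chrom_length: int,
) -> np.ndarray:
    """Noise-free expected NET-seq signal per nucleotide.

    dwell(position) = exon or intron dwell factor (scaled on circRNA
    genes by the circ multipliers) * (1 - accel * relative_position),
    plus a ``stall_height`` bump within ``stall_width`` nt on both sides
    of every exon-intron boundary. Expected signal = gene_rate * dwell.
    """
    expected = np.zeros(chrom_length)
    genes = group_into_genes(list(transcripts))
    circ_genes = truth.circ_genes
    for gene in genes.values():
        tx = max(gene.transcripts, key=lambda t: t.n_exons)
        span = gene.gene_span
        is_circ = gene.gene_symbol in circ_genes
        exon_f = config.netseq_exon_dwell * (
            config.circ_exon_dwell_multiplier if is_circ else 1.0
        )
        intron_f = config.netseq_intron_dwell * (
            config.circ_intron_dwell_multiplier if is_circ else 1.0
        )
        dwell = np.full(span.length, intron_f)
        for e in tx.exons:
            dwell[e.start - span.start : e.end - span.start] = exon_f
        # boundary stalls
        w = config.netseq_stall_width
        if config.netseq_stall_height > 0 and w > 0:
            bump = np.zeros(span.length)
            for e in tx.exons:
                for edge in (e.start - span.start, e.end - span.start):
                    lo = max(0, edge - w)
                    hi = min(span.length, edge + w)
                    bump[lo:hi] = config.netseq_stall_height
            dwell = dwell + bump
        if config.netseq_accel > 0:
            rel = np.arange(span.length) / max(1, span.length - 1)
            if tx.strand == "-":
                rel = rel[::-1]
            dwell = dwell * (1.0 - config.netseq_accel * rel)
        expected[span.start : span.end] += config.netseq_gene_rate * dwell
    return expected


def simulate_netseq(
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
    chrom_length: int,
    n_replicates: int = 2,
) -> list[dict[str, np.ndarray]]:
    """Poisson-sample replicate coverage tracks around the expected
    dwell profile."""
    expected = expected_netseq_profile(transcripts, truth, config, chrom_length)
    tracks = []
    for rep in range(n_replicates):
        rng = config.rng(stage=30 + rep)
        tracks.append({config.chrom: rng.poisson(expected).astype(float)})
    return tracks


def track_to_bedgraph(track: dict[str, np.ndarray]) -> list[tuple[str, int, int, float]]:
    """Run-length encode a per-nt track as bedgraph records (zeros skipped)."""
    out = []
    for chrom, arr in track.items():
        if len(arr) == 0:
            continue
        change = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for s, e in zip(starts, ends):
            v = float(arr[s])
            if v != 0.0:
                out.append((chrom, int(s), int(e), v))
    return out


# --------------------------------------------------------------------------
# regulatory sites (AGO/RBP footprints, miRNA seed matches, m6A)


@dataclass
class PlantedMatch:
    mirna: str
    seed: str  # miRNA positions 2-7, 5'->3'
    circ_key: str
    circle_offset: int  # 0-based position of the 6-mer on the circle
    ago_supported: bool
    spans_junction: bool


@dataclass
class RegulatorySites:
    ago_sites: dict[str, list[GenomicInterval]]
    m6a_sites: list[GenomicInterval]
    mirnas: dict[str, str]
    planted_matches: list[PlantedMatch]
    rbp_sites: dict[str, list[GenomicInterval]]


def _seed_of(mirna_seq: str) -> str:
    return mirna_seq[1:7]


def _target_site_dna(seed: str) -> str:
    """DNA sequence a transcript must contain to seed-match (reverse
    complement of the RNA seed, written as DNA)."""
    rna_rc = reverse_complement(seed.replace("U", "T"))
    return rna_rc


def _write_sense_motif(
    genome: dict[str, str],
    tx: TranscriptModel,
    circ: CircTruth,
    circle_offset: int,
    motif: str,
) -> None:
    """Write ``motif`` (transcript-sense DNA) at a circle coordinate,
    mutating the genome. Handles motifs that wrap past the junction."""
    exons = [
        tx.exon_by_ordinal(o)
        for o in range(circ.acceptor_ordinal, circ.donor_ordinal + 1)
    ]
    # circle coordinate -> (chrom position) walking exons in transcription order
    positions: list[int] = []
    for e in exons:  # already in transcription (ordinal) order
        if tx.strand == "+":
            positions.extend(range(e.start, e.end))
        else:
            positions.extend(range(e.end - 1, e.start - 1, -1))
    L = len(positions)
    seq = genome[tx.chrom]
    chars = list(seq)
    for i, base in enumerate(motif):
        gpos = positions[(circle_offset + i) % L]
        chars[gpos] = base if tx.strand == "+" else reverse_complement(base)
    genome[tx.chrom] = "".join(chars)


def _genomic_interval_of_circle_slice(
    tx: TranscriptModel, circ: CircTruth, circle_offset: int, length: int
) -> list[GenomicInterval]:
    """Genomic interval(s) covered by a circle-coordinate slice (two arms
    when the slice wraps the junction)."""
    exons = [
        tx.exon_by_ordinal(o)
        for o in range(circ.acceptor_ordinal, circ.donor_ordinal + 1)
    ]
    positions: list[int] = []
    for e in exons:  # transcription (ordinal) order
        if tx.strand == "+":
            positions.extend(range(e.start, e.end))
        else:
            positions.extend(range(e.end - 1, e.start - 1, -1))
    L = len(positions)
    pos = [positions[(circle_offset + i) % L] for i in range(length)]
    pos.sort()
    out = []
    run_start = pos[0]
    prev = pos[0]
    for p in pos[1:]:
        if p != prev + 1:
            out.append(GenomicInterval(circ.chrom, run_start, prev + 1, tx.strand))
            run_start = p
        prev = p
    out.append(GenomicInterval(circ.chrom, run_start, prev + 1, tx.strand))
    return out


def simulate_regulatory_sites(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
) -> RegulatorySites:
    """Plant exact miRNA seed matches inside circle exons (with or
    without covering AGO footprints, plus junction-spanning cases),
    scatter per-protein RBP footprints and single-nt m6A sites.

    Mutates the genome in place, so call before read simulation.
    """
    rng = config.rng(stage=40)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    mirna_names = sorted(config.mirnas)
    ago: dict[str, list[GenomicInterval]] = {"AGO2": []}
    planted: list[PlantedMatch] = []
    circles = list(truth.circles)
    half = config.ago_site_width // 2
    # circle-coordinate spans already covered (or reachable) by a planted
    # AGO footprint, per circle; unsupported sites must stay clear of them
    ago_reach = 40  # site flank + AGO half-width + extension, with margin
    covered: dict[str, list[tuple[int, int]]] = {}

    def _clear_of_ago(circ: CircTruth, offset: int) -> bool:
        L = circ.circle_length
        for lo, hi in covered.get(circ.junction_key, ()):
            for shift in (-L, 0, L):  # circular distance
                if lo - ago_reach < offset + shift < hi + ago_reach:
                    return False
        return True

    def plant(circ: CircTruth, supported: bool, spans_junction: bool) -> None:
        tx = tx_by_id[circ.transcript_id]
        name = mirna_names[int(rng.integers(0, len(mirna_names)))]
        seed = _seed_of(config.mirnas[name])
        motif = _target_site_dna(seed)
        L = circ.circle_length
        if L < 12:
            return
        if spans_junction:
            offset = L - 3  # 3 nt each side of the wrap
        else:
            offset = int(rng.integers(0, max(1, L - 6)))
            if not supported:
                for _ in range(30):  # keep known negatives clear of AGO
                    if _clear_of_ago(circ, offset):
                        break
                    offset = int(rng.integers(0, max(1, L - 6)))
                else:
                    return
        _write_sense_motif(genome, tx, circ, offset, motif)
        if supported:
            arms = _genomic_interval_of_circle_slice(tx, circ, offset, 6)
            arm = max(arms, key=lambda a: a.length)
            centre = (arm.start + arm.end) // 2
            ago["AGO2"].append(
                GenomicInterval(
                    circ.chrom, max(0, centre - half), centre + half, tx.strand
                )
            )
            covered.setdefault(circ.junction_key, []).append(
                (offset - half, offset + 6 + half)
            )
        planted.append(
            PlantedMatch(name, seed, circ.junction_key, offset, supported,
                         spans_junction)
        )

    if circles:
        for i in range(config.n_supported_matches):
            plant(circles[i % len(circles)], supported=True, spans_junction=False)
        for i in range(config.n_junction_matches):
            plant(circles[i % len(circles)], supported=True, spans_junction=True)
        for i in range(config.n_unsupported_matches):
            plant(circles[-1 - (i % len(circles))], supported=False,
                  spans_junction=False)

    # random RBP footprints over exonic space, density optionally boosted on
    # circularized exons
    genes = group_into_genes(list(transcripts))
    circ_spans = {
        c.junction_key: GenomicInterval(c.chrom, c.span_start, c.span_end, c.strand)
        for c in circles
    }
    rbp: dict[str, list[GenomicInterval]] = {p: [] for p in config.rbp_proteins}
    m6a: list[GenomicInterval] = []
    for gene in genes.values():
        is_circ = gene.gene_symbol in truth.circ_genes
        for exon in gene.exon_union():
            in_circle = any(
                exon.overlap_nt(sp) > 0 for sp in circ_spans.values()
            )
            dens = config.rbp_sites_per_kb * (
                config.rbp_circ_density_multiplier if (is_circ and in_circle) else 1.0
            )
            for protein in config.rbp_proteins:
                n_sites = rng.poisson(dens * exon.length / 1000.0)
                for _ in range(n_sites):
                    if exon.length <= config.ago_site_width:
                        s = exon.start
                    else:
                        s = int(
                            rng.integers(exon.start,
                                         exon.end - config.ago_site_width)
                        )
                    rbp[protein].append(
                        GenomicInterval(exon.chrom, s,
                                        s + config.ago_site_width, exon.strand)
                    )
            n_m6a = rng.poisson(config.m6a_sites_per_kb * exon.length / 1000.0)
            for _ in range(n_m6a):
                p = int(rng.integers(exon.start, exon.end))
                m6a.append(GenomicInterval(exon.chrom, p, p + 1, exon.strand))

    all_sites = dict(rbp)
    all_sites["AGO2"] = list(ago["AGO2"])
    return RegulatorySites(
        ago_sites={"AGO2": list(ago["AGO2"])},  # planted footprints only
        m6a_sites=m6a,
        mirnas=dict(config.mirnas),
        planted_matches=planted,
        rbp_sites=all_sites,
    )
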