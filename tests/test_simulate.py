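"""Properties of the synthetic-data generator."""

import io

import numpy as np
import pytest

from backsplice.io import write_fasta, write_refflat
from backsplice.models import reverse_complement, spliced_sequence
from backsplice.simulate import (
    FRACTION_SAMPLES,
    SimConfig,
    circle_sequence,
    expected_netseq_profile,
    generate_genome_and_annotation,
    simulate_fractions,
    simulate_netseq,
    simulate_read_pairs,
    simulate_regulatory_sites,
    track_to_bedgraph,
)


def render(genome, transcripts):
    fa, rf = io.StringIO(), io.StringIO()
    names = {c: genome[c] for c in sorted(genome)}
    write_fasta_to = fa
    for name, seq in names.items():
        write_fasta_to.write(f">{name}\n{seq}\n")
    write_refflat(transcripts, rf)
    return fa.getvalue(), rf.getvalue()


class TestGenomeGeneration:
    def test_identical_seed_gives_byte_identical_outputs(self):
        a = generate_genome_and_annotation(SimConfig(seed=1))
        b = generate_genome_and_annotation(SimConfig(seed=1))
        assert render(a[0], a[1]) == render(b[0], b[1])
        assert [c.__dict__ for c in a[2].circles] == [
            c.__dict__ for c in b[2].circles
        ]

    def test_zero_genes_is_not_an_error(self):
        genome, transcripts, truth = generate_genome_and_annotation(
            SimConfig(seed=1, n_genes=0, n_circ_genes=0)
        )
        assert transcripts == [] and truth.circles == []

    def test_genes_do_not_overlap(self):
        _, transcripts, _ = generate_genome_and_annotation(SimConfig(seed=2))
        spans = sorted(
            (t.tx_start, t.tx_end)
            for t in transcripts
            if t.transcript_id.endswith(".t1")
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_flanking_intron_inflation_is_recovered(self):
        config = SimConfig(
            seed=3, n_genes=200, n_circ_genes=100, flanking_intron_factor=10.0
        )
        _, transcripts, truth = generate_genome_and_annotation(config)
        tx_by_id = {t.transcript_id: t for t in transcripts}
        from backsplice.models import derive_introns

        flank, other = [], []
        for c in truth.circles:
            introns = dict(derive_introns(tx_by_id[c.transcript_id]))
            for o, iv in introns.items():
                if o == c.acceptor_ordinal - 1 or o == c.donor_ordinal:
                    flank.append(iv.length)
                elif o != 1:  # intron 1 carries its own inflation factor
                    other.append(iv.length)
        ratio = np.mean(flank) / np.mean(other)
        assert 5.0 < ratio < 20.0  # within 2x of the planted 10x

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(circ_span_probs=(0.5, 0.6))
        with pytest.raises(ValueError):
            SimConfig(intron_len=(0, 10))

    def test_config_yaml_roundtrip(self):
        cfg = SimConfig(seed=9, n_genes=5, n_circ_genes=2)
        buf = io.StringIO()
        cfg.to_yaml(buf)
        again = SimConfig.from_yaml(io.StringIO(buf.getvalue()))
        assert again == cfg


class TestReadSimulation:
    def test_zero_abundance_circle_emits_no_tagged_reads(self):
        config = SimConfig(seed=4, n_read_pairs=500)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        key = truth.circles[0].junction_key
        reads = simulate_read_pairs(
            genome, transcripts, truth, config,
            circ_pair_counts={key: 0},
        )
        assert not any(key in rid for rid, _ in reads.reads1)

    def test_fragment_equal_to_read_length_gives_identical_mates(self):
        config = SimConfig(
            seed=5, n_read_pairs=200, fragment_mean=50, fragment_sd=0,
            read_length=50,
        )
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reads = simulate_read_pairs(genome, transcripts, truth, config)
        for (_, r1), (_, r2) in zip(reads.reads1, reads.reads2):
            assert r2 == reverse_complement(r1)

    def test_linear_reads_are_substrings_of_spliced_isoforms(self):
        config = SimConfig(seed=6, n_read_pairs=300)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reads = simulate_read_pairs(genome, transcripts, truth, config)
        spliced = {
            t.transcript_id: spliced_sequence(t, genome) for t in transcripts
        }
        by_gene = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_symbol, []).append(t.transcript_id)
        checked = 0
        for rid, seq in reads.reads1:
            _, cls, gene, _, _ = rid.split("|")
            if cls != "linear":
                continue
            assert any(seq in spliced[tid] for tid in by_gene[gene])
            checked += 1
            if checked >= 100:
                break
        assert checked > 0

    def test_junction_read_count_matches_string_search_oracle(self):
        config = SimConfig(seed=7, n_read_pairs=0)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reads = simulate_read_pairs(genome, transcripts, truth, config)
        circ = truth.circles[0]
        seq = circle_sequence(circ, transcripts, genome)
        junction_window = seq[-49:] + seq[:49]
        expected = 0
        for pair in zip(reads.reads1, reads.reads2):
            if not any(circ.junction_key in rid for rid, _ in pair):
                continue
            hit = False
            for _, r in pair:
                for probe in (r, reverse_complement(r)):
                    pos = junction_window.find(probe)
                    if pos != -1 and pos < 49 and pos + len(probe) > 49:
                        hit = True
            expected += hit
        # every planted pair comes from the circle; a deterministic share
        # crosses the junction
        assert expected > 0
        assert sum(
            1 for rid, _ in reads.reads1 if circ.junction_key in rid
        ) == circ.n_pairs


class TestFractions:
    def _bundle(self, **kw):
        config = SimConfig(seed=8, n_read_pairs=300, n_fraction_read_pairs=300,
                           **kw)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        return config, genome, transcripts, truth

    def test_all_mass_on_fraction_one(self):
        config, genome, transcripts, truth = self._bundle(
            circ_fraction_probs=(1.0, 0, 0, 0, 0, 0, 0, 0),
            circ_ribo_free_fraction=0.0,
        )
        samples = simulate_fractions(genome, transcripts, truth, config)
        for name in FRACTION_SAMPLES[1:]:
            assert not any(
                "|circ|" in rid for rid, _ in samples[name].reads1
            )
        assert any("|circ|" in rid for rid, _ in samples["F1"].reads1)

    def test_free_mass_one_keeps_circ_reads_in_total_only(self):
        config, genome, transcripts, truth = self._bundle(
            circ_fraction_probs=(0.0,) * 8, circ_ribo_free_fraction=0.0
        )
        samples = simulate_fractions(genome, transcripts, truth, config)
        for name in FRACTION_SAMPLES:
            assert not any("|circ|" in rid for rid, _ in samples[name].reads1)
        assert any("|circ|" in rid for rid, _ in samples["total"].reads1)

    def test_multinomial_split_within_three_sigma(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(10_000, [0.5, 0.5] + [0.0] * 7)
        sigma = np.sqrt(10_000 * 0.25)
        assert abs(counts[0] - 5_000) < 3 * sigma
        assert counts[2:].sum() == 0


class TestNetseq:
    def test_flat_profile_when_factors_equal_and_no_stalls(self):
        config = SimConfig(
            seed=9, n_genes=5, n_circ_genes=2,
            netseq_exon_dwell=1.0, netseq_intron_dwell=1.0,
            netseq_stall_height=0.0,
        )
        genome, transcripts, truth = generate_genome_and_annotation(config)
        expected = expected_netseq_profile(
            transcripts, truth, config, len(genome[config.chrom])
        )
        inside = expected[expected > 0]
        assert np.allclose(inside, inside[0])

    def test_exon_intron_ratio_recovery(self):
        config = SimConfig(
            seed=10, n_genes=100, n_circ_genes=0,
            netseq_exon_dwell=3.0, netseq_intron_dwell=1.0,
            netseq_stall_height=0.0, netseq_gene_rate=2.0,
        )
        genome, transcripts, truth = generate_genome_and_annotation(config)
        tracks = simulate_netseq(
            transcripts, truth, config, len(genome[config.chrom])
        )
        arr = (tracks[0][config.chrom] + tracks[1][config.chrom]) / 2
        exon_vals, intron_vals = [], []
        from backsplice.models import derive_introns

        for t in transcripts:
            if not t.transcript_id.endswith(".t1"):
                continue
            for e in t.exons:
                exon_vals.append(arr[e.start:e.end].mean())
            for _, ivl in derive_introns(t):
                intron_vals.append(arr[ivl.start:ivl.end].mean())
        ratio = np.mean(exon_vals) / np.mean(intron_vals)
        assert abs(ratio - 3.0) < 0.3  # within 10% of the planted 3x

    def test_replicate_averaging_halves_variance(self):
        config = SimConfig(seed=11, n_genes=60, n_circ_genes=0,
                           netseq_stall_height=0.0)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        chrom_len = len(genome[config.chrom])
        tracks = simulate_netseq(transcripts, truth, config, chrom_len)
        expected = expected_netseq_profile(transcripts, truth, config, chrom_len)
        mask = expected > 0
        single = tracks[0][config.chrom][mask] - expected[mask]
        mean_rep = (
            tracks[0][config.chrom][mask] + tracks[1][config.chrom][mask]
        ) / 2 - expected[mask]
        ratio = np.var(mean_rep) / np.var(single)
        assert 0.4 < ratio < 0.6  # 0.5 +/- 20%

    def test_bedgraph_runlength_encoding_roundtrips(self):
        track = {"chr1": np.array([0, 0, 2, 2, 3, 0, 1], dtype=float)}
        records = track_to_bedgraph(track)
        rebuilt = np.zeros(7)
        for _, s, e, v in records:
            rebuilt[s:e] = v
        assert np.array_equal(rebuilt, track["chr1"])


class TestRegulatorySites:
    def test_let7_seed_plant_leaves_tacctc_in_circle(self):
        config = SimConfig(seed=12, mirnas={"let-7-like": "UGAGGUAGUAGGUUGUAUAGUU"},
                           n_supported_matches=3, n_unsupported_matches=0,
                           n_junction_matches=0)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reg = simulate_regulatory_sites(genome, transcripts, truth, config)
        circles = {c.junction_key: c for c in truth.circles}
        assert reg.planted_matches
        for m in reg.planted_matches:
            assert m.seed == "GAGGUA"
            seq = circle_sequence(circles[m.circ_key], transcripts, genome)
            window = (seq + seq)[m.circle_offset : m.circle_offset + 6]
            assert window == "TACCTC"

    def test_junction_spanning_plant_wraps(self):
        config = SimConfig(seed=13, n_supported_matches=0,
                           n_unsupported_matches=0, n_junction_matches=2)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reg = simulate_regulatory_sites(genome, transcripts, truth, config)
        circles = {c.junction_key: c for c in truth.circles}
        spanning = [m for m in reg.planted_matches if m.spans_junction]
        assert spanning
        for m in spanning:
            assert m.circle_offset == circles[m.circ_key].circle_length - 3

    def test_unsupported_plants_are_recorded_as_filter_negatives(self):
        config = SimConfig(seed=14, n_supported_matches=4,
                           n_unsupported_matches=3, n_junction_matches=0)
        genome, transcripts, truth = generate_genome_and_annotation(config)
        reg = simulate_regulatory_sites(genome, transcripts, truth, config)
        kinds = {m.ago_supported for m in reg.planted_matches}
        assert kinds == {True, False}
        assert reg.ago_sites["AGO2"]
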