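"""Back-splice junction detection, counting, normalisation, filtering."""

import pytest

from backsplice.detect import (
    BackSpliceJunction,
    CircRNARecord,
    DetectorConfig,
    JunctionMatcher,
    build_backsplice_index,
    build_linear_reference,
    classify_linear,
    cognate_linear_isoforms,
    count_and_normalize,
    filter_by_abundance,
    overlap_percentage,
    overlap_summary,
    verify_mate_inside,
)
from backsplice.intervals import GenomicInterval
from backsplice.models import TranscriptModel, reverse_complement


def make_tx(starts_ends, strand="+", tid="T1", gene="G1"):
    exons = [GenomicInterval("chr1", s, e, strand) for s, e in starts_ends]
    return TranscriptModel(tid, gene, "chr1", strand, exons)


@pytest.fixture(scope="module")
def toy_genome():
    import numpy as np

    rng = np.random.default_rng(123)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {"chr1": bases[rng.integers(0, 4, 3000)].tobytes().decode()}


class TestBuildIndex:
    def test_four_exon_transcript_gives_ten_candidates(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300), (400, 500), (600, 700)])
        index = build_backsplice_index([tx], toy_genome, k=30)
        assert len(index) == 10  # pairs with acceptor <= donor: 4+3+2+1

    def test_short_exon_truncates_flank(self, toy_genome):
        tx = make_tx([(0, 30), (200, 300)])
        index = build_backsplice_index([tx], toy_genome, k=50)
        single = next(
            j for j in index.values()
            if j.acceptor_ordinal == j.donor_ordinal == 1
        )
        # both flanks come from the 30 nt exon
        assert len(single.junction_seq) == 60

    def test_isoforms_sharing_a_pair_are_merged(self, toy_genome):
        t1 = make_tx([(0, 100), (200, 300)], tid="T1")
        t2 = make_tx([(0, 100), (200, 300), (400, 500)], tid="T2")
        index = build_backsplice_index([t1, t2], toy_genome, k=30)
        shared = index["chr1:0-300:+"]
        assert set(shared.transcript_ids) == {"T1", "T2"}

    def test_minus_strand_circle_sequence_is_transcript_sense(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300), (400, 500)], strand="-")
        index = build_backsplice_index([tx], toy_genome, k=30)
        j = index["chr1:0-500:-"]  # full three-exon circle
        expected = (
            reverse_complement(toy_genome["chr1"][400:500])
            + reverse_complement(toy_genome["chr1"][200:300])
            + reverse_complement(toy_genome["chr1"][0:100])
        )
        assert j.circle_seq == expected


class TestClassifyAndDetect:
    def test_pair_inside_one_exon_is_linear(self, toy_genome):
        tx = make_tx([(0, 200), (400, 600)])
        ref = build_linear_reference([tx], toy_genome)
        cfg = DetectorConfig()
        r1 = toy_genome["chr1"][10:60]
        r2 = reverse_complement(toy_genome["chr1"][100:150])
        assert classify_linear(r1, r2, ref, cfg) == "linear"

    def test_read_spanning_canonical_splice_is_linear(self, toy_genome):
        tx = make_tx([(0, 200), (400, 600)])
        ref = build_linear_reference([tx], toy_genome)
        cfg = DetectorConfig()
        spliced = toy_genome["chr1"][0:200] + toy_genome["chr1"][400:600]
        r1 = spliced[180:230]  # crosses the forward splice junction
        r2 = reverse_complement(spliced[250:300])
        assert classify_linear(r1, r2, ref, cfg) == "linear"

    def test_backsplice_read_is_a_candidate(self, toy_genome):
        tx = make_tx([(0, 200), (400, 600)])
        ref = build_linear_reference([tx], toy_genome)
        cfg = DetectorConfig()
        index = build_backsplice_index([tx], toy_genome, cfg.k)
        j = index["chr1:0-600:+"]
        read = j.circle_seq[-25:] + j.circle_seq[:25]
        mate = reverse_complement(j.circle_seq[30:80])
        assert classify_linear(read, mate, ref, cfg) == "candidate"
        matcher = JunctionMatcher(index, cfg)
        assert matcher.best_junction(read) == "chr1:0-600:+"

    def test_anchor_shorter_than_minimum_is_rejected(self, toy_genome):
        tx = make_tx([(0, 200), (400, 600)])
        cfg = DetectorConfig(min_anchor=8)
        index = build_backsplice_index([tx], toy_genome, cfg.k)
        j = index["chr1:0-600:+"]
        read = j.circle_seq[-5:] + j.circle_seq[:45]  # 5 nt left anchor
        matcher = JunctionMatcher(index, cfg)
        assert matcher.best_junction(read) is None

    def test_mate_verification(self, toy_genome):
        tx = make_tx([(0, 200), (400, 600)])
        cfg = DetectorConfig()
        index = build_backsplice_index([tx], toy_genome, cfg.k)
        j = index["chr1:0-600:+"]
        inside = reverse_complement(j.circle_seq[50:100])
        outside = toy_genome["chr1"][2000:2050]
        crossing = j.circle_seq[-20:] + j.circle_seq[:30]
        assert verify_mate_inside(inside, j, cfg)
        assert not verify_mate_inside(outside, j, cfg)
        assert verify_mate_inside(crossing, j, cfg)

    def test_cognate_isoforms_assigned_inclusively(self, toy_genome):
        t1 = make_tx([(0, 100), (200, 300), (400, 500)], tid="T1")
        t2 = make_tx([(0, 100), (200, 300), (400, 500), (600, 700)], tid="T2")
        # same junction-side boundaries, different internal structure:
        # still cognate under the inclusive rule
        t3 = make_tx([(200, 320), (400, 500)], tid="T3")
        # junction-side acceptor boundary differs: not cognate
        t4 = make_tx([(210, 300), (400, 500)], tid="T4")
        index = build_backsplice_index([t1, t2], toy_genome, k=30)
        j = index["chr1:200-500:+"]
        assert set(cognate_linear_isoforms(j, [t1, t2, t3, t4])) == {
            "T1", "T2", "T3"
        }


def _record(key="chr1:0-300:+", **jpm):
    tx = make_tx([(0, 100), (200, 300)])
    j = BackSpliceJunction(
        gene_symbol="G1", transcript_ids=["T1"], chrom="chr1", strand="+",
        acceptor_exon=tx.exons[0], acceptor_ordinal=1,
        donor_exon=tx.exons[1], donor_ordinal=2,
        junction_seq="A" * 20, junction_point=10, circle_seq="A" * 200,
    )
    rec = CircRNARecord(j, jpm={k: v for k, v in jpm.items()})
    return rec


class TestCountingAndFiltering:
    def test_jpm_arithmetic(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300)])
        index = build_backsplice_index([tx], toy_genome, k=30)
        key = "chr1:0-300:+"
        records = count_and_normalize(
            {"s1": {key: 5}, "s2": {key: 18}},
            {"s1": 50e6, "s2": 90e6},
            index,
        )
        assert records[key].jpm["s1"] == pytest.approx(0.1)
        assert records[key].jpm["s2"] == pytest.approx(0.2)

    def test_zero_count_junctions_are_omitted(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300)])
        index = build_backsplice_index([tx], toy_genome, k=30)
        records = count_and_normalize(
            {"s1": {"chr1:0-300:+": 0}}, {"s1": 1e6}, index
        )
        assert records == {}

    def test_zero_mapped_reads_is_an_error(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300)])
        index = build_backsplice_index([tx], toy_genome, k=30)
        with pytest.raises(ValueError, match="mapped reads"):
            count_and_normalize(
                {"s1": {"chr1:0-300:+": 3}}, {"s1": 0}, index
            )

    def test_jpm_invariant_under_duplication(self, toy_genome):
        tx = make_tx([(0, 100), (200, 300)])
        index = build_backsplice_index([tx], toy_genome, k=30)
        key = "chr1:0-300:+"
        once = count_and_normalize({"s": {key: 7}}, {"s": 10e6}, index)
        twice = count_and_normalize({"s": {key: 14}}, {"s": 20e6}, index)
        assert once[key].jpm["s"] == pytest.approx(twice[key].jpm["s"])

    def test_mean_filter_keeps_above_threshold(self):
        rec = _record(s1=0.05, s2=0.20)
        kept = filter_by_abundance({rec.key: rec}, {"hek": ["s1", "s2"]})
        assert rec.key in kept  # mean 0.125 >= 0.1

    def test_boundary_mean_is_kept_inclusively(self):
        rec = _record(s1=0.1)
        assert rec.key in filter_by_abundance({rec.key: rec}, {"hek": ["s1"]})

    def test_fraction_rescue_rule(self):
        rec = _record(s1=0.05)
        fraction_jpm = {rec.key: {f"F{i}": 0.12 for i in range(1, 9)}}
        dropped = filter_by_abundance({rec.key: rec}, {"hek": ["s1"]})
        rescued = filter_by_abundance(
            {rec.key: rec}, {"hek": ["s1"]}, fraction_jpm=fraction_jpm
        )
        assert rec.key not in dropped
        assert rec.key in rescued


class TestOverlapSummary:
    @pytest.mark.parametrize(
        "inter,denom,pct",
        [(395, 621, 64), (111, 239, 46), (422, 843, 50), (231, 626, 37),
         (810, 2561, 32), (97, 794, 12), (177, 794, 22)],
    )
    def test_printed_count_percentages(self, inter, denom, pct):
        assert overlap_percentage(inter, denom) == pct

    def test_identical_sets_give_100(self):
        a = {"x", "y", "z"}
        assert overlap_summary(a, a, a) == (3, 3, 100)

    def test_empty_denominator_is_an_error(self):
        with pytest.raises(ValueError):
            overlap_summary({"a"}, {"a"}, set())


class TestEndToEnd:
    def test_default_simulation_recall_and_precision(
        self, default_bundle, default_records
    ):
        from backsplice.pipeline import evaluate_detection

        ev = evaluate_detection(default_records, default_bundle.truth)
        assert ev["recall"] >= 0.9
        assert ev["precision"] >= 0.9

    def test_all_calls_are_annotation_anchored(
        self, default_bundle, default_records
    ):
        cfg = DetectorConfig()
        index = build_backsplice_index(
            default_bundle.transcripts, default_bundle.genome, cfg.k
        )
        assert set(default_records) <= set(index)
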