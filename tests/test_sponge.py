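"""Seed-match scanning, AGO support filtering, sponge summaries."""

import numpy as np
import pytest

from backsplice.detect import DetectorConfig, build_backsplice_index, CircRNARecord
from backsplice.intervals import GenomicInterval
from backsplice.models import TranscriptModel, reverse_complement
from backsplice.pipeline import circ_sequences
from backsplice.sponge import (
    SeedMatch,
    filter_by_ago,
    rbp_footprint_comparison,
    scan_seed_matches,
    seed_of,
    seed_target_dna,
    sponge_summary,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
MIR16 = "UAGCAGCACGUAAAUAUUGGCG"


class TestSeedExtraction:
    def test_let7_seed_and_target(self):
        assert seed_of(LET7) == "GAGGUA"
        assert seed_target_dna("GAGGUA") == "TACCTC"

    def test_mir16_seed_and_target(self):
        assert seed_of(MIR16) == "AGCAGC"
        assert seed_target_dna("AGCAGC") == "GCTGCT"


def wrap_oracle(target: str, circ: str) -> set[int]:
    """Naive oracle: positions of target in the doubled sequence, taken
    modulo the circle length, deduplicated."""
    doubled = circ + circ
    hits = set()
    for i in range(len(circ)):
        if doubled[i : i + len(target)] == target:
            hits.add(i)
    return hits


class TestScanSeedMatches:
    def test_every_tacctc_is_reported(self):
        circ = "TACCTC" + "G" * 20 + "TACCTC" + "A" * 10
        matches = scan_seed_matches({"let7": LET7}, {"c1": circ})
        assert {m.start for m in matches} == {0, 26}
        assert all(not m.spans_junction for m in matches)

    def test_junction_spanning_match_found_once(self):
        # TAC at the circle end, CTC at the start
        circ = "CTC" + "G" * 30 + "TAC"
        matches = scan_seed_matches({"let7": LET7}, {"c1": circ})
        assert len(matches) == 1
        assert matches[0].start == 33
        assert matches[0].spans_junction

    def test_short_mirna_is_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert scan_seed_matches({"tiny": "UGAGG"}, {"c": "A" * 30}) == []

    def test_agrees_with_wrap_oracle_on_random_circles(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        mirnas = {"let7": LET7, "mir16": MIR16}
        for _ in range(60):
            circ = "".join(rng.choice(bases, int(rng.integers(40, 200))))
            matches = scan_seed_matches(mirnas, {"c": circ})
            for name, mir in mirnas.items():
                got = {m.start for m in matches if m.mirna == name}
                expected = wrap_oracle(seed_target_dna(seed_of(mir)), circ)
                assert got == expected

    def test_strand_symmetry_of_the_scan(self):
        # reverse-complementing the circle and the seed together must
        # preserve the match count
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        circ = "".join(rng.choice(bases, 150))
        fwd = scan_seed_matches({"m": LET7}, {"c": circ})
        seed_rc = reverse_complement(seed_of(LET7).replace("U", "T")).replace(
            "T", "U"
        )
        mir_rc = "A" + seed_rc + "AAAAAAAAAAAAAAA"  # positions 2-7 = rc(seed)
        rev = scan_seed_matches({"m": mir_rc}, {"c": reverse_complement(circ)})
        assert len(fwd) == len(rev)


def _single_exon_record(genome, exon=(100, 200)):
    tx = TranscriptModel(
        "T1", "G1", "chr1", "+",
        [GenomicInterval("chr1", exon[0], exon[1], "+"),
         GenomicInterval("chr1", 300, 400, "+")],
    )
    index = build_backsplice_index([tx], genome, k=42)
    key = f"chr1:{exon[0]}-{exon[1]}:+"
    return tx, {key: CircRNARecord(index[key])}, key


class TestAgoFilter:
    @pytest.fixture()
    def genome(self):
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        return {"chr1": bases[rng.integers(0, 4, 600)].tobytes().decode()}

    def _match_at(self, key, start):
        return SeedMatch("m", "GAGGUA", key, start, spans_junction=False)

    def test_half_overlap_is_supported(self, genome):
        tx, records, key = _single_exon_record(genome)
        # site spans circle coords [13, 33) -> genomic [113, 133)
        m = self._match_at(key, 20)
        # extended AGO interval covers exactly 10 nt of the 20 nt site
        ago = [GenomicInterval("chr1", 123 + 10, 180, "+")]
        (out,) = filter_by_ago([m], records, [tx], ago)
        assert out.ago_supported

    def test_nine_nt_overlap_is_unsupported(self, genome):
        tx, records, key = _single_exon_record(genome)
        m = self._match_at(key, 20)
        ago = [GenomicInterval("chr1", 124 + 10, 180, "+")]
        (out,) = filter_by_ago([m], records, [tx], ago)
        assert not out.ago_supported

    def test_extension_bridges_a_gap(self, genome):
        tx, records, key = _single_exon_record(genome)
        m = self._match_at(key, 20)
        # AGO site ends 10 nt before the site start (113); the +/-10 nt
        # extension reaches exactly to 113, and a long site overlaps half
        ago = [GenomicInterval("chr1", 50, 123, "+")]
        (out,) = filter_by_ago([m], records, [tx], ago)
        assert out.ago_supported

    def test_planted_sites_recovered_exactly(self, small_bundle, small_records):
        reg = small_bundle.regulatory
        seqs = circ_sequences(small_bundle, small_records)
        matches = scan_seed_matches(reg.mirnas, seqs)
        matches = filter_by_ago(
            matches, small_records, small_bundle.transcripts,
            reg.ago_sites["AGO2"],
        )
        found_supported = {(m.circ_key, m.start) for m in matches
                           if m.ago_supported}
        planted_supported = {
            (p.circ_key, p.circle_offset)
            for p in reg.planted_matches if p.ago_supported
        }
        planted_negative = {
            (p.circ_key, p.circle_offset)
            for p in reg.planted_matches if not p.ago_supported
        }
        assert planted_supported <= found_supported  # recall 1.0
        assert not planted_negative & found_supported  # filter precision 1.0


class TestSpongeSummary:
    def test_twelve_dispersed_sites_counted(self):
        matches = [
            SeedMatch("m", "GGUGGA", "circ1", 10 * i, False, ago_supported=True)
            for i in range(12)
        ]
        per_circ, per_seed = sponge_summary(matches)
        assert per_circ["circ1"] == 12

    def test_occurrence_threshold_lists_seeds(self):
        matches = [
            SeedMatch("m", "GAGGUA", f"c{i}", 0, False, ago_supported=True)
            for i in range(9)
        ] + [
            SeedMatch("m", "AGCAGC", f"c{i}", 0, False, ago_supported=True)
            for i in range(3)
        ]
        _, per_seed = sponge_summary(matches, occurrence_threshold=8)
        listed = dict(zip(per_seed["seed"], per_seed["listed"]))
        assert listed["GAGGUA"] and not listed["AGCAGC"]

    def test_overlapping_offsets_are_distinct_sites(self):
        matches = [
            SeedMatch("m", "GAGGUA", "c", 5, False, True),
            SeedMatch("m", "GAGGUA", "c", 7, False, True),
            SeedMatch("m", "GAGGUA", "c", 7, False, True),  # duplicate
        ]
        per_circ, _ = sponge_summary(matches)
        assert per_circ["c"] == 2


class TestRbpComparison:
    def test_planted_double_density_is_detected(self):
        rng = np.random.default_rng(8)
        circ_exons = [
            GenomicInterval("chr1", 1000 * i, 1000 * i + 500) for i in range(80)
        ]
        non_exons = [
            GenomicInterval("chr1", 200_000 + 1000 * i, 200_000 + 1000 * i + 500)
            for i in range(80)
        ]
        sites = []
        for e in circ_exons:  # ~2 sites per circ exon
            for _ in range(rng.poisson(2.0)):
                s = int(rng.integers(e.start, e.end - 20))
                sites.append(GenomicInterval("chr1", s, s + 20))
        for e in non_exons:  # ~0.5 per non-circ exon
            for _ in range(rng.poisson(0.5)):
                s = int(rng.integers(e.start, e.end - 20))
                sites.append(GenomicInterval("chr1", s, s + 20))
        table = rbp_footprint_comparison(
            {"RBPX": sites}, circ_exons, non_exons
        )
        row = table.iloc[0]
        assert row["p"] < 0.05
        assert row["direction"] == "circ-higher"

    def test_equal_densities_not_significant(self):
        exons_a = [GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
                   for i in range(30)]
        exons_b = [GenomicInterval("chr1", 50_000 + 1000 * i,
                                   50_000 + 1000 * i + 500)
                   for i in range(30)]
        sites = [GenomicInterval("chr1", e.start + 10, e.start + 30)
                 for e in exons_a + exons_b]
        table = rbp_footprint_comparison({"RBPY": sites}, exons_a, exons_b)
        assert table.iloc[0]["p"] > 0.9

    def test_zero_site_protein_is_skipped(self):
        with pytest.warns(UserWarning, match="no sites"):
            table = rbp_footprint_comparison(
                {"EMPTY": []},
                [GenomicInterval("chr1", 0, 100)],
                [GenomicInterval("chr1", 200, 300)],
            )
        assert len(table) == 0
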