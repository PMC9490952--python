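"""Generator contracts: determinism, planted truth, exact mutation counts, depth."""

import numpy as np
import pytest

from curupira import simdata
from curupira.simdata import (
    PlantedCluster,
    mutate_te_copy,
    simulate_genome,
    simulate_srna_library,
    simulate_wgs,
)


class TestSimulateGenome:
    def test_empty_case_two_contigs(self, tmp_path):
        truth = simulate_genome(2, 10_000, seed=1)
        assert [(n, L) for n, L in truth.contigs] == [
            ("contig_1", 10_000),
            ("contig_2", 10_000),
        ]
        assert not truth.planted_clusters and not truth.b_specific_snps
        paths = simdata.write_truth(truth, tmp_path)
        assert paths["clusters"].read_text() == ""

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        spec = [PlantedCluster("contig_1", 2000, 3500)]
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        for p in (p1, p2):
            truth = simulate_genome(2, 10_000, cluster_spec=spec, seed=7)
            simdata.write_genome_fasta(truth, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        truth = simulate_genome(2, 5_000, seed=3)
        path = tmp_path / "g.fa"
        simdata.write_genome_fasta(truth, path)
        back = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert back == truth.sequences

    def test_truth_bed_records_planted_cluster(self, tmp_path):
        truth = simulate_genome(
            1, 10_000, cluster_spec=[PlantedCluster("contig_1", 2000, 3500)], seed=1
        )
        paths = simdata.write_truth(truth, tmp_path)
        (rec,) = simdata.read_truth_clusters(paths["clusters"])
        assert (rec.contig, rec.start, rec.end) == ("contig_1", 2000, 3500)

    def test_truth_round_trip(self, small_truth, tmp_path):
        paths = simdata.write_truth(small_truth, tmp_path)
        clusters = simdata.read_truth_clusters(paths["clusters"])
        assert [(c.contig, c.start, c.end, c.directionality, c.b_exclusive) for c in clusters] == [
            (c.contig, c.start, c.end, c.directionality, c.b_exclusive)
            for c in small_truth.planted_clusters
        ]
        mirnas = simdata.read_truth_mirnas(paths["mirnas"])
        assert [(m.contig, m.start, m.end, m.strand) for m in mirnas] == [
            (m.contig, m.start, m.end, m.strand) for m in small_truth.planted_mirnas
        ]

    def test_overlapping_same_strand_clusters_rejected(self):
        spec = [
            PlantedCluster("contig_1", 2000, 3500, directionality="mono:+"),
            PlantedCluster("contig_1", 3000, 4500, directionality="mono:+"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(1, 10_000, cluster_spec=spec, seed=1)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            simulate_genome(
                1, 3_000, cluster_spec=[PlantedCluster("contig_1", 2000, 3500)], seed=1
            )

    def test_alphabet_is_acgt(self, small_truth):
        for seq in small_truth.sequences.values():
            assert set(seq) <= set("ACGT")


class TestMutateTECopy:
    def test_zero_rates_identity(self):
        seq = "ACGT" * 20
        out, p, q = mutate_te_copy(seq, 0.0, 0.0, seed=1)
        assert out == seq and p == 0.0 and q == 0.0

    def test_exact_substitution_counts(self):
        consensus = "ACGT" * 25
        out, p, q = mutate_te_copy(consensus, 0.10, 0.05, seed=3)
        assert len(out) == 100 and (p, q) == (0.10, 0.05)
        from curupira._sequtil import is_transition

        ts = sum(1 for a, b in zip(consensus, out) if a != b and is_transition(a, b))
        tv = sum(1 for a, b in zip(consensus, out) if a != b and not is_transition(a, b))
        assert (ts, tv) == (10, 5)

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError, match="short"):
            mutate_te_copy("A" * 49, 0.1, 0.0, seed=1)

    def test_rates_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mutate_te_copy("ACGT" * 25, 0.5, 0.3, seed=1)


class TestSrnaLibrary:
    def test_zero_reads(self, small_truth):
        assert simulate_srna_library(small_truth, "FB-", 0, seed=1) == []

    def test_read_count_conserved(self, small_truth):
        recs = simulate_srna_library(small_truth, "MB+", 5_000, seed=2)
        assert len(recs) == 5_000

    def test_forced_5prime_u(self, small_truth):
        recs = simulate_srna_library(
            small_truth, "FB+", 1_000, u1_prob=1.0, noise_frac=0.0, mirna_frac=0.0, seed=3
        )
        assert all(seq[0] == "T" for _id, seq in recs if ":pirna:" in _id)

    def test_point_mass_length_profile(self, small_truth):
        recs = simulate_srna_library(
            small_truth, "FB+", 500, length_profile={28: 1.0},
            noise_frac=0.0, mirna_frac=0.0, seed=4,
        )
        assert {len(seq) for _id, seq in recs} == {28}

    def test_unknown_group_rejected(self, small_truth):
        with pytest.raises(ValueError, match="group"):
            simulate_srna_library(small_truth, "XB+", 10, seed=1)

    def test_bminus_groups_skip_b_exclusive_clusters(self, small_truth):
        b_excl = [c for c in small_truth.planted_clusters if c.b_exclusive]
        assert b_excl, "layout must plant at least one B-exclusive cluster"
        recs = simulate_srna_library(
            small_truth, "MB-", 5_000, noise_frac=0.0, mirna_frac=0.0, seed=5
        )
        spans = {
            c.contig: (c.start, c.end) for c in b_excl
        }
        # no read sequence may originate inside a B-exclusive cluster: check by
        # exact match (either orientation) against the planted windows
        for contig, (start, end) in spans.items():
            window = small_truth.sequences[contig][start:end]
            for _id, seq in recs:
                assert seq not in window and simdata.revcomp(seq) not in window

    def test_typographic_minus_accepted(self, small_truth):
        recs = simulate_srna_library(small_truth, "FB−", 10, seed=6)
        assert len(recs) == 10


class TestWGS:
    @staticmethod
    def _truth_depth(records, contig, contig_len, read_length):
        covered = 0
        for rid, _seq in records:
            _b, c, start, _strand, _i = rid.split(":")
            if c == contig:
                covered += read_length
        return covered / contig_len

    def test_bminus_ignores_multiplier(self):
        truth = simulate_genome(2, 10_000, b_contigs={"contig_2": 3}, seed=1)
        recs = simulate_wgs(truth, 20, 100, "B-", seed=2)
        d = self._truth_depth(recs, "contig_2", 10_000, 100)
        assert 20 * 0.85 <= d <= 20 * 1.15

    def test_bplus_scales_depth_by_multiplier(self):
        truth = simulate_genome(2, 10_000, b_contigs={"contig_2": 3}, seed=1)
        recs = simulate_wgs(truth, 20, 100, "B+", seed=2)
        d1 = self._truth_depth(recs, "contig_1", 10_000, 100)
        d2 = self._truth_depth(recs, "contig_2", 10_000, 100)
        assert 20 * 0.85 <= d1 <= 20 * 1.15
        assert 60 * 0.85 <= d2 <= 60 * 1.15

    def test_alt_allele_frequency_half_at_multiplier_two(self):
        truth = simulate_genome(
            1, 10_000, b_contigs={"contig_1": 2}, snps_per_b_contig=1, seed=9
        )
        (snp,) = truth.b_specific_snps
        recs = simulate_wgs(truth, 50, 100, "B+", seed=3)
        alt = ref = 0
        for rid, seq in recs:
            _b, _c, start, strand, _i = rid.split(":")
            start = int(start)
            if start <= snp.position < start + 100:
                fwd = seq if strand == "+" else simdata.revcomp(seq)
                base = fwd[snp.position - start]
                alt += base == snp.alt
                ref += base == snp.ref
        depth = alt + ref
        assert depth >= 40
        assert abs(alt / depth - 0.5) <= 0.1

    def test_bminus_never_emits_alt(self):
        truth = simulate_genome(
            1, 10_000, b_contigs={"contig_1": 2}, snps_per_b_contig=1, seed=9
        )
        (snp,) = truth.b_specific_snps
        recs = simulate_wgs(truth, 30, 100, "B-", seed=4)
        for rid, seq in recs:
            _b, _c, start, strand, _i = rid.split(":")
            start = int(start)
            if start <= snp.position < start + 100:
                fwd = seq if strand == "+" else simdata.revcomp(seq)
                assert fwd[snp.position - start] == snp.ref

    def test_determinism(self):
        truth = simulate_genome(1, 5_000, seed=1)
        a = simulate_wgs(truth, 10, 100, "B-", seed=5)
        b = simulate_wgs(truth, 10, 100, "B-", seed=5)
        assert a == b

    def test_nonpositive_depth_rejected(self):
        truth = simulate_genome(1, 5_000, seed=1)
        with pytest.raises(ValueError):
            simulate_wgs(truth, 0, 100, "B-", seed=1)
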