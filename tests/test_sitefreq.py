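"""Frequency tallying, file I/O and diversity statistics."""

from collections import Counter

import numpy as np
import pytest

from serialfreq.sitefreq import (
    SamplingDesign,
    SiteFrequencyMatrix,
    frequency_matrix_from_sequences,
    inter_diversity_site,
    intra_diversity_site,
    mean_diversities,
    read_aligned_reads_sam,
    read_alignment_fasta,
    read_frequency_table,
    write_frequency_table,
)
from serialfreq.coalsim import SimParams, simulate

from conftest import random_freq_matrix


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">seq{i}\n{s}\n")


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:ref\tLN:{length}\n"


def write_sam(path, reads, ref_length):
    """reads: list of (name, pos_1based, seq)"""
    with open(path, "w") as fh:
        fh.write(SAM_HEADER.format(length=ref_length))
        for name, pos, seq in reads:
            fh.write(f"{name}\t0\tref\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n")


class TestSamplingDesign:
    def test_pair_and_intra_counts(self):
        d = SamplingDesign.from_times([0, 100, 300, 600])
        assert d.n_timepoints == 4
        assert len(d.pairs) == 4 * 3 // 2
        assert all(d.elapsed(a, b) > 0 for a, b in d.pairs)
        assert d.intervals == [100, 200, 300]

    @pytest.mark.parametrize("times", [[100, 100], [200, 100], [-1, 50]])
    def test_invalid_times_rejected(self, times):
        with pytest.raises(ValueError):
            SamplingDesign.from_times(times)


class TestFastaReading:
    def test_direct_counting(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, ["AC", "AC", "AG", "AT"])
        m = read_alignment_fasta(p, "t0")
        f = m.freqs
        assert f[0, 0] == 1.0  # site 1 all A
        assert f[1].tolist() == [0.0, 0.5, 0.25, 0.25]  # C/G/T split
        assert m.depth.tolist() == [4.0, 4.0]

    def test_single_sequence_identity(self, tmp_path):
        p = tmp_path / "one.fasta"
        write_fasta(p, ["ACGT"])
        m = read_alignment_fasta(p, "t0")
        assert np.allclose(m.freqs.max(axis=1), 1.0)
        assert m.freqs.argmax(axis=1).tolist() == [0, 1, 2, 3]

    def test_unequal_lengths_fatal_with_record_id(self, tmp_path):
        p = tmp_path / "bad.fasta"
        write_fasta(p, ["ACGT", "ACG"])
        with pytest.raises(ValueError, match="seq1"):
            read_alignment_fasta(p, "t0")

    def test_ambiguous_chars_excluded_from_column(self, tmp_path):
        p = tmp_path / "amb.fasta"
        write_fasta(p, ["AN", "A-", "AC"])
        m = read_alignment_fasta(p, "t0")
        assert m.depth.tolist() == [3.0, 1.0]
        assert m.freqs[1, 1] == 1.0  # only the C counted

    def test_all_ambiguous_column_fatal(self, tmp_path):
        p = tmp_path / "gap.fasta"
        write_fasta(p, ["A-", "A-"])
        with pytest.raises(ValueError, match="column 2"):
            read_alignment_fasta(p, "t0")

    def test_empty_fasta_fatal(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_alignment_fasta(p, "t0")

    def test_against_independent_column_counter(self, tmp_path):
        aln = simulate(SimParams.make(N=500, mu=2e-4, times=[0],
                                      n_per_timepoint=40, n_sites=80, seed=5))
        seqs = aln.sequences(0)
        p = tmp_path / "sim.fasta"
        write_fasta(p, seqs)
        m = read_alignment_fasta(p, "t0")
        assert np.allclose(m.freqs.sum(axis=1), 1.0)
        for s in range(80):  # independent oracle: per-column Counter
            col = Counter(seq[s] for seq in seqs)
            for j, base in enumerate("ACGT"):
                assert m.counts[s, j] == col.get(base, 0)


class TestSamReading:
    def test_two_overlapping_reads(self, tmp_path):
        p = tmp_path / "r.sam"
        write_sam(p, [("r1", 1, "ACGTA"), ("r2", 3, "GTACGT")], ref_length=8)
        m, covered = read_aligned_reads_sam(p, 8, "t0")
        assert covered.tolist() == list(range(8))
        assert m.depth.tolist() == [1, 1, 2, 2, 2, 1, 1, 1]
        assert np.allclose(m.freqs.max(axis=1), 1.0)  # identical calls

    def test_empty_sam_fatal(self, tmp_path):
        p = tmp_path / "e.sam"
        p.write_text(SAM_HEADER.format(length=10))
        with pytest.raises(ValueError, match="no mapped reads"):
            read_aligned_reads_sam(p, 10, "t0")

    def test_uncovered_positions_excluded(self, tmp_path):
        p = tmp_path / "part.sam"
        write_sam(p, [("r1", 1, "ACG")], ref_length=6)
        m, covered = read_aligned_reads_sam(p, 6, "t0")
        assert covered.tolist() == [0, 1, 2]
        assert m.n_sites == 3

    def test_fasta_and_fulllength_sam_agree(self, tmp_path):
        aln = simulate(SimParams.make(N=300, mu=3e-4, times=[0],
                                      n_per_timepoint=12, n_sites=50, seed=11))
        seqs = aln.sequences(0)
        fa = tmp_path / "a.fasta"
        write_fasta(fa, seqs)
        sam = tmp_path / "a.sam"
        write_sam(sam, [(f"r{i}", 1, s) for i, s in enumerate(seqs)], ref_length=50)
        mf = read_alignment_fasta(fa, "t0")
        ms, _ = read_aligned_reads_sam(sam, 50, "t0")
        np.testing.assert_array_equal(mf.counts, ms.counts)
        np.testing.assert_array_equal(mf.depth, ms.depth)

    def test_fragmented_reads_match_fulllength_tally(self, tmp_path):
        # fragmenting haplotypes into overlapping reads covering everything
        # must reproduce the full-length column tally exactly
        aln = simulate(SimParams.make(N=300, mu=3e-4, times=[0],
                                      n_per_timepoint=10, n_sites=60, seed=3))
        seqs = aln.sequences(0)
        reads = []
        for i, s in enumerate(seqs):  # tile each haplotype: 2 x 30bp
            reads.append((f"r{i}a", 1, s[:30]))
            reads.append((f"r{i}b", 31, s[30:]))
        sam = tmp_path / "frag.sam"
        write_sam(sam, reads, ref_length=60)
        ms, _ = read_aligned_reads_sam(sam, 60, "t0")
        mf = frequency_matrix_from_sequences(seqs, "t0")
        np.testing.assert_array_equal(mf.counts, ms.counts)


class TestDiversity:
    @pytest.mark.parametrize("row,expected", [
        ((1, 0, 0, 0), 0.0),
        ((0.25, 0.25, 0.25, 0.25), 0.75),
        ((0.5, 0.5, 0, 0), 0.5),
    ])
    def test_intra_cases(self, row, expected):
        assert intra_diversity_site(np.array(row)) == pytest.approx(expected)

    @pytest.mark.parametrize("r1,r2,expected", [
        ((1, 0, 0, 0), (1, 0, 0, 0), 0.0),
        ((1, 0, 0, 0), (0, 1, 0, 0), 1.0),
        ((0.5, 0.5, 0, 0), (0.5, 0.5, 0, 0), 0.5),
    ])
    def test_inter_cases(self, r1, r2, expected):
        assert inter_diversity_site(np.array(r1), np.array(r2)) == pytest.approx(expected)

    def test_inter_of_identical_rows_equals_intra(self, rng):
        rows = rng.dirichlet(np.ones(4) * 0.5, size=1000)
        for row in rows:
            assert inter_diversity_site(row, row) == pytest.approx(
                intra_diversity_site(row), abs=1e-12
            )

    def test_ranges(self, rng):
        rows = rng.dirichlet(np.ones(4) * 0.3, size=500)
        for row in rows:
            assert 0.0 <= intra_diversity_site(row) <= 0.75 + 1e-12
        for r1, r2 in zip(rows[:250], rows[250:]):
            assert 0.0 <= inter_diversity_site(r1, r2) <= 1.0


class TestMeanDiversities:
    def test_arithmetic_mean(self):
        counts = np.array([[4.0, 0, 0, 0], [2.0, 2.0, 0, 0]])
        m = SiteFrequencyMatrix(timepoint="t0", counts=counts)
        d = mean_diversities([m], SamplingDesign.from_times([0]))
        assert d.intra["t0"] == pytest.approx((0.0 + 0.5) / 2)

    def test_monomorphic_identical_all_zero(self):
        counts = np.zeros((10, 4))
        counts[:, 2] = 5.0
        ms = [SiteFrequencyMatrix(timepoint=l, counts=counts.copy())
              for l in ("t0", "t1")]
        d = mean_diversities(ms, SamplingDesign.from_times([0, 100]))
        assert all(v == 0 for v in d.intra.values())
        assert all(v == 0 for v in d.inter.values())

    def test_matches_nested_loop_oracle(self, random_matrices3, design3):
        d = mean_diversities(random_matrices3, design3)
        freqs = [m.freqs for m in random_matrices3]
        n = random_matrices3[0].n_sites
        for t, lab in enumerate(design3.labels):
            acc = sum(1 - sum(freqs[t][s, j] ** 2 for j in range(4))
                      for s in range(n))
            assert d.intra[lab] == pytest.approx(acc / n)
        for a, b in design3.pairs:
            acc = sum(1 - sum(freqs[a][s, j] * freqs[b][s, j] for j in range(4))
                      for s in range(n))
            key = (design3.labels[a], design3.labels[b])
            assert d.inter[key] == pytest.approx(acc / n)

    def test_site_permutation_invariance(self, random_matrices3, design3, rng):
        base = mean_diversities(random_matrices3, design3)
        perm = rng.permutation(random_matrices3[0].n_sites)
        shuffled = [
            SiteFrequencyMatrix(timepoint=m.timepoint, counts=m.counts[perm],
                                depth=m.depth[perm])
            for m in random_matrices3
        ]
        out = mean_diversities(shuffled, design3)
        assert out.intra == pytest.approx(base.intra)
        for k in base.inter:
            assert out.inter[k] == pytest.approx(base.inter[k])

    def test_mismatched_sites_fatal(self, design3, rng):
        ms = [random_freq_matrix(rng, n, lab)
              for n, lab in zip((10, 10, 11), design3.labels)]
        with pytest.raises(ValueError, match="mismatched n_sites"):
            mean_diversities(ms, design3)


class TestFrequencyTable:
    def test_round_trip(self, tmp_path, rng):
        m = random_freq_matrix(rng, 25, "tp_x")
        p = tmp_path / "freq.tsv"
        write_frequency_table(m, p)
        back = read_frequency_table(p)
        assert back.timepoint == "tp_x"
        np.testing.assert_allclose(back.counts, m.counts)
        np.testing.assert_allclose(back.freqs, m.freqs)

    def test_zero_depth_site_rejected(self):
        counts = np.zeros((2, 4))
        counts[0, 0] = 3.0
        with pytest.raises(ValueError, match="site 2"):
            SiteFrequencyMatrix(timepoint="t0", counts=counts)
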