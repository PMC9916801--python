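"""Synthetic genome and read generator: truth bookkeeping, the K2P
substitution process, WGM doubling, and deterministic output."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from skimrepeats.io_utils import revcomp
from skimrepeats.simulate import (GenomeSpec, RepeatFamilySpec, apply_wgm,
                                  build_genome, coverage_percent,
                                  family_consensus, k2p_probabilities,
                                  make_plastid, measure_pairwise_divergence,
                                  mutate, reads_at_coverage, sample_reads,
                                  simulate_ltr_pairs, _decode, _encode)

from conftest import make_family


class TestFamilySpec:
    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            make_family(divergence=0.3)

    def test_age_requires_ltr(self):
        with pytest.raises(ValueError):
            make_family(planted_age_mya=2.0)

    def test_repeat_content_exceeding_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec("x", 1000, [make_family(length=1000, copies=10)])

    def test_burst_must_name_known_family(self):
        with pytest.raises(ValueError):
            GenomeSpec("x", 10_000_000, [make_family()], wgm_factor=2,
                       amplification_bursts=[("Nope", 10, 0.01)])


class TestK2PProcess:
    def test_zero_divergence_copies_identical(self):
        g = build_genome(GenomeSpec("x", 200_000, [
            make_family("F", length=1000, copies=100, divergence=0.0)],
            seed=1))
        fam = g.truth.families["F"]
        assert fam.total_bases == 100_000
        assert fam.mean_pairwise_divergence == 0.0
        assert len(set(g.copies["F"])) == 1

    def test_probabilities_match_rate_matrix_exponential(self):
        # independent oracle: expm of the K2P rate matrix, ts:tv = 2
        beta = 1 / 6
        alpha = 4 / 6  # alpha + 2 beta = 1
        # order A, C, G, T; transitions A<->G, C<->T
        Q = np.array([
            [-(alpha + 2 * beta), beta, alpha, beta],
            [beta, -(alpha + 2 * beta), beta, alpha],
            [alpha, beta, -(alpha + 2 * beta), beta],
            [beta, alpha, beta, -(alpha + 2 * beta)],
        ])
        for branch in (0.01, 0.1, 0.5):
            P = expm(Q * branch)
            p_same, p_ts, p_tv = k2p_probabilities(branch, ts_tv=2.0)
            assert P[0, 0] == pytest.approx(p_same, abs=1e-12)
            assert P[0, 2] == pytest.approx(p_ts, abs=1e-12)
            assert P[0, 1] == pytest.approx(p_tv, abs=1e-12)

    def test_measured_divergence_matches_expectation(self, rng):
        # brute-force oracle on <= 50 copies: mean pairwise mismatch vs the
        # two-branch closed form 1 - p_same(2d)
        d = 0.04
        cons = rng.integers(0, 4, 2000, dtype=np.uint8)
        copies = [mutate(cons, d, rng) for _ in range(50)]
        measured = measure_pairwise_divergence(copies)
        expected = 1.0 - k2p_probabilities(2 * d)[0]
        se = math.sqrt(expected * (1 - expected) / 2000) * 3
        assert abs(measured - expected) < 3 * se

    def test_planted_ltr_age_divergence(self):
        # planted_age 1 Mya, mu 4.79e-9 -> E[LTR-LTR divergence] = 0.00958
        n = 60
        contigs = simulate_ltr_pairs([1.0] * n, ltr_len=2000, seed=3)
        ltrs = [(s[200:2200], s[4200:6200]) for _, s in contigs]
        obs = np.mean([
            np.mean(np.frombuffer(a.encode(), np.uint8)
                    != np.frombuffer(b.encode(), np.uint8))
            for a, b in ltrs])
        expected = 1.0 - k2p_probabilities(0.00958)[0]
        se = math.sqrt(expected / (2000 * n))
        assert obs == pytest.approx(expected, abs=4 * se)


class TestBuildGenome:
    def test_truth_proportions_sum_to_100(self, small_genome):
        total = small_genome.truth.single_copy_pct + sum(
            t.proportion_pct for t in small_genome.truth.families.values())
        assert total == pytest.approx(100.0, abs=0.01)

    def test_genome_length_matches_spec(self, small_genome):
        assert len(small_genome) == 1_000_000

    def test_family_at_agrees_with_block_spans(self, small_genome):
        for fam, spans in small_genome.block_spans.items():
            s, e = spans[0]
            assert small_genome.family_at(s) == fam
            assert small_genome.family_at(e - 1) == fam

    def test_deterministic_given_seed(self):
        spec = lambda: GenomeSpec("x", 100_000, [make_family(copies=50)], seed=9)
        assert build_genome(spec()).sequence == build_genome(spec()).sequence


class TestWGM:
    def _base(self, factor=2, bursts=()):
        return GenomeSpec("x", 500_000, [
            make_family("FamA", length=800, copies=100, divergence=0.03),
            make_family("FamB", length=600, copies=80, divergence=0.02),
        ], wgm_factor=factor, amplification_bursts=list(bursts), seed=5)

    def test_factor_two_doubles_length_and_keeps_proportions(self):
        g = build_genome(self._base())
        w = apply_wgm(g)
        assert len(w) == 2 * len(g)
        for fam in g.truth.families:
            assert w.truth.families[fam].n_copies == \
                2 * g.truth.families[fam].n_copies
            assert w.truth.families[fam].proportion_pct == pytest.approx(
                g.truth.families[fam].proportion_pct, abs=1e-9)

    def test_factor_one_is_identity(self):
        g = build_genome(self._base(factor=1))
        assert apply_wgm(g) is g

    def test_burst_raises_proportion_and_lowers_divergence(self):
        spec = self._base(bursts=[("FamA", 200, 0.003)])
        g = build_genome(GenomeSpec("x", 500_000, spec.families, seed=5))
        w = apply_wgm(g, spec)
        assert w.truth.families["FamA"].proportion_pct > \
            g.truth.families["FamA"].proportion_pct
        assert w.truth.families["FamA"].mean_pairwise_divergence < \
            g.truth.families["FamA"].mean_pairwise_divergence


class TestSampleReads:
    def test_error_free_reads_are_genome_substrings(self, small_genome):
        pairs = sample_reads(small_genome, n_pairs=40, error_rate=0,
                             degraded_tail_fraction=0, seed=2)
        genome = small_genome.sequence
        for p in pairs:
            assert p.seq1 in genome or revcomp(p.seq1) in genome
            assert p.seq2 in genome or revcomp(p.seq2) in genome

    def test_pair_count_follows_coverage(self, small_genome):
        pairs = sample_reads(small_genome, coverage_fraction=0.03, seed=2)
        assert len(pairs) == round(0.03 * 1_000_000 / 300)

    def test_reads_per_coverage_arithmetic_at_full_scale(self):
        # 0.54650% of 73.19 Gbp at 100 nt single-read accounting = 4 million
        assert reads_at_coverage(73.19e9, 0.0054650, 100) == \
            pytest.approx(4e6, rel=1e-3)
        assert coverage_percent(4e6, 147.29e9, 100) == \
            pytest.approx(0.27, abs=0.005)

    def test_plastid_fraction_binomial(self, small_genome):
        plastid = make_plastid(20_000, seed=1)
        n, f = 10_000, 0.05
        pairs = sample_reads(small_genome, n_pairs=n, plastid_ref=plastid,
                             plastid_fraction=f, seed=4)
        got = sum(p.from_plastid for p in pairs)
        sd = math.sqrt(n * f * (1 - f))
        assert abs(got - n * f) <= 3 * sd

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            sample_reads("", n_pairs=1)

    def test_byte_identical_fastq_under_fixed_seed(self, small_genome, tmp_path):
        from skimrepeats.simulate import write_reads

        out = []
        for run in range(2):
            pairs = sample_reads(small_genome, n_pairs=50, seed=11)
            r1 = tmp_path / f"r1_{run}.fastq.gz"
            r2 = tmp_path / f"r2_{run}.fastq.gz"
            write_reads(pairs, str(r1), str(r2))
            out.append((r1.read_bytes(), r2.read_bytes()))
        assert out[0] == out[1]


def test_consensus_shared_across_specs_with_same_seed():
    fam = make_family("Shared", length=600, copies=10)
    a = family_consensus(fam, 42)
    b = family_consensus(fam, 42)
    c = family_consensus(fam, 43)
    assert _decode(a) == _decode(b)
    assert _decode(a) != _decode(c)


def test_encode_decode_roundtrip():
    s = "ACGTTGCA"
    assert _decode(_encode(s)) == s
    with pytest.raises(ValueError):
        _encode("ACGN")
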