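"""LTR-pair harvesting, Kimura two-parameter dating, and age summaries."""

import math

import numpy as np
import pytest

from skimrepeats.ltrclock import (LTRPairRecord, SaturationError,
                                  dedup_contigs, date_records,
                                  detect_ltr_pairs, insertion_time, kimura2p,
                                  summarize_ages, align_ltr_pair)
from skimrepeats.simulate import DEFAULT_MU, simulate_ltr_pairs


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestKimura2P:
    def test_identical(self):
        P, Q, K = kimura2p(("ACGT" * 30, "ACGT" * 30))
        assert (P, Q, K) == (0.0, 0.0, 0.0)

    def test_transitions_only_closed_form(self):
        # 100 sites, 10 transitions: K = -1/2 ln(0.8) ~ 0.11157
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        P, Q, K = kimura2p((a, b))
        assert P == pytest.approx(0.10)
        assert Q == 0.0
        assert K == pytest.approx(0.11157177565710485, abs=1e-12)

    def test_mixed_p_q_closed_form(self):
        # P = Q = 0.05 -> K = -1/2 ln(0.85 sqrt(0.9)) ~ 0.107600
        a = "A" * 100
        b = "G" * 5 + "C" * 5 + "A" * 90
        P, Q, K = kimura2p((a, b))
        assert (P, Q) == (0.05, 0.05)
        assert K == pytest.approx(0.10759959366334404, abs=1e-12)

    def test_gap_columns_excluded(self):
        P, Q, K = kimura2p(("AC-GT", "ACAGT"))
        assert K == 0.0

    def test_correction_never_shrinks_divergence(self, rng):
        for _ in range(20):
            a = rand_seq(rng, 200)
            b = rand_seq(rng, 200)
            raw = sum(x != y for x, y in zip(a, b)) / 200
            try:
                _, _, K = kimura2p((a, b))
            except SaturationError:
                continue
            assert K >= raw - 1e-12

    def test_saturation_raises(self):
        a = "A" * 100
        b = "G" * 60 + "A" * 40  # P = 0.6 -> 1 - 2P - Q < 0
        with pytest.raises(SaturationError):
            kimura2p((a, b))


class TestInsertionTime:
    def test_zero(self):
        assert insertion_time(0.0) == 0.0

    def test_one_mya(self):
        # K = 0.00958 with mu = 4.79e-9 -> exactly 1 Mya
        assert insertion_time(0.00958, 4.79e-9) == pytest.approx(1.0)

    def test_linearity(self):
        assert insertion_time(0.1916) == pytest.approx(20.0)
        for a in (0.5, 2.0, 7.3):
            assert insertion_time(a * 0.01) == pytest.approx(
                a * insertion_time(0.01))

    def test_bad_mu(self):
        with pytest.raises(ValueError):
            insertion_time(0.1, mu=0)


class TestDetect:
    def test_exact_direct_repeat_found(self, rng):
        ltr = rand_seq(rng, 300)
        contig = rand_seq(rng, 100) + ltr + rand_seq(rng, 4000) + ltr + \
            rand_seq(rng, 100)
        recs = detect_ltr_pairs(contig)
        assert len(recs) == 1
        r = recs[0]
        assert r.identity == pytest.approx(100.0)
        s5, e5 = r.ltr5_span
        s3, e3 = r.ltr3_span
        assert e5 <= s3
        assert contig[s5:e5] == contig[s3:e3]

    def test_random_contigs_no_false_pairs(self, rng):
        # shuffle oracle: random sequence has no long direct repeats
        for _ in range(10):
            assert detect_ltr_pairs(rand_seq(rng, 10_000)) == []

    def test_too_short_contig(self, rng):
        assert detect_ltr_pairs(rand_seq(rng, 500)) == []

    def test_planted_two_percent_divergence_dated(self):
        contigs = simulate_ltr_pairs([0.00958 * 2 / (2 * DEFAULT_MU) / 1e6],
                                     ltr_len=1000, seed=9)
        # planted age chosen so 2 mu T ~ 0.019 (about 2% per-site divergence)
        recs = detect_ltr_pairs(contigs[0][1])
        dated, _ = date_records(recs)
        assert len(dated) == 1
        assert dated[0].K == pytest.approx(0.0202, abs=0.006)


class TestDedup:
    def test_identical_contigs_collapse(self, rng):
        s = rand_seq(rng, 2000)
        assert len(dedup_contigs([("a", s), ("b", s)])) == 1

    def test_distant_contigs_kept(self, rng):
        assert len(dedup_contigs([("a", rand_seq(rng, 2000)),
                                  ("b", rand_seq(rng, 2000))])) == 2

    def test_ten_copies_plus_one_distinct(self, rng):
        s, t = rand_seq(rng, 1500), rand_seq(rng, 1500)
        contigs = [(f"c{i}", s) for i in range(10)] + [("x", t)]
        kept = dedup_contigs(contigs)
        assert len(kept) == 2
        assert {seq for _, seq in kept} == {s, t}


class TestSummaries:
    def rec(self, age):
        r = LTRPairRecord("c", (0, 100), (200, 300), ("A", "A"), 100.0)
        r.T_mya = age
        return r

    def test_basic_stats(self):
        s = summarize_ages([self.rec(a) for a in (1.0, 2.0, 3.0)], "sp")
        assert s.median_mya == 2.0
        assert s.mean_mya == 2.0
        assert s.sd_mya == pytest.approx(1.0)
        assert s.max_mya == 3.0

    def test_single_record_sd_undefined(self):
        s = summarize_ages([self.rec(4.2)], "sp")
        assert s.median_mya == s.mean_mya == 4.2
        assert s.sd_mya is None

    def test_empty_summary_explicit(self):
        s = summarize_ages([], "sp")
        assert s.n_pairs == 0
        assert s.median_mya is None

    def test_round_trip_age_recovery(self):
        """For planted ages 1-17 Mya, E[K] = 2 mu T: recovery within 3 SE
        over replicate pairs per age."""
        for T in (1.0, 5.0, 10.0, 17.0):
            n, L = 40, 2000
            contigs = simulate_ltr_pairs([T] * n, ltr_len=L, seed=int(10 * T))
            ks = []
            for _, seq in contigs:
                dated, _ = date_records(detect_ltr_pairs(seq))
                ks.extend(r.K for r in dated)
            expected = 2 * DEFAULT_MU * T * 1e6
            se = math.sqrt(expected / (n * L))
            assert np.mean(ks) == pytest.approx(expected, abs=3 * se + 0.0005)

    def test_dedup_on_off_consistency(self, rng):
        """Without duplicated contigs the dedup flag barely moves the median
        (the published workflow's consistency check)."""
        ages = np.random.default_rng(5).uniform(1, 15, 60)
        contigs = simulate_ltr_pairs(ages, seed=55)
        def med(cs):
            recs = []
            for cid, seq in cs:
                recs.extend(detect_ltr_pairs(seq, contig_id=cid))
            dated, _ = date_records(recs)
            return summarize_ages(dated, "sp").median_mya
        m_on = med(dedup_contigs(contigs))
        m_off = med(contigs)
        assert abs(m_on - m_off) / m_off <= 0.15


def test_align_ltr_pair_rebuilds_full_alignment(rng):
    a = rand_seq(rng, 300)
    b = a[:150] + a[160:]  # 10 nt deletion
    ga, gb = align_ltr_pair(a, b)
    assert len(ga) == len(gb)
    assert ga.replace("-", "") == a
    assert gb.replace("-", "") == b
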