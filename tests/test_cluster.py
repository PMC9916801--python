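"""Similarity-hit detection and graph clustering, including the brute-force
all-pairs + union-find oracle equivalence."""

import itertools

import edlib
import numpy as np
import pytest

from skimrepeats.cluster import (SimilarityHit, align_identity, cluster_graph,
                                 comparative_cluster, find_hits, verify_pair)
from skimrepeats.io_utils import revcomp
from skimrepeats.simulate import GenomeSpec, build_genome, sample_reads

from conftest import make_family


def rand_seq(rng, n=100):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_str(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestFindHits:
    def test_identical_reads_single_hit(self, rng):
        r = rand_seq(rng)
        hits = find_hits([r, r])
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 100.0 and h.overlap_fraction == 1.0

    def test_reverse_complement_hit(self, rng):
        r = rand_seq(rng)
        hits = find_hits([r, revcomp(r)])
        assert len(hits) == 1
        assert hits[0].identity == 100.0
        assert hits[0].strand == "opposite"

    def test_half_overlap_below_threshold_rejected(self, rng):
        base = rand_seq(rng, 150)
        a, b = base[:100], base[50:150]  # 50 nt overlap < 55
        assert find_hits([a, b]) == []

    def test_eight_mismatches_pass_ninety_percent(self, rng):
        a = rand_seq(rng)
        b = mutate_str(a, range(5, 101, 12))  # 8 positions
        hits = find_hits([a, b])
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(92.0)

    def test_eleven_mismatches_fail(self, rng):
        a = rand_seq(rng)
        b = mutate_str(a, range(3, 91, 8))  # 11 positions
        assert find_hits([a, b]) == []

    def test_fewer_than_two_reads(self, rng):
        assert find_hits([]) == []
        assert find_hits([rand_seq(rng)]) == []

    def test_no_self_hits_and_symmetric_storage(self, rng):
        reads = [rand_seq(rng) for _ in range(5)]
        reads += [mutate_str(r, [3]) for r in reads]
        for h in find_hits(reads):
            assert h.read_a < h.read_b

    def test_identity_invariant_under_reverse_complement(self, rng):
        for _ in range(10):
            a = rand_seq(rng)
            b = mutate_str(a, rng.choice(100, size=5, replace=False))
            h1 = find_hits([a, b])[0]
            h2 = find_hits([a, revcomp(b)])[0]
            assert h1.identity == pytest.approx(h2.identity)
            assert h1.overlap_fraction == pytest.approx(h2.overlap_fraction)


def brute_force_components(reads, min_identity=90.0, min_overlap=0.55):
    """Independent oracle: all-pairs overlap alignment at every diagonal +
    union-find."""
    n = len(reads)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for i, j in itertools.combinations(range(n), 2):
        if _best_pair_hit(reads[i], reads[j], min_identity, min_overlap):
            union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values() if len(c) > 1}


def _best_pair_hit(a, b, min_identity, min_overlap):
    """Exhaustive scan: every strand and diagonal, gap-free column counts."""
    for target in (b, revcomp(b)):
        for d in range(-(len(a) - 1), len(target)):
            lo_a, hi_a = max(0, d), min(len(a), len(target) + d)
            span = hi_a - lo_a
            if 100 * span < 100 * min_overlap * min(len(a), len(target)) - 1e-6:
                continue
            matches = sum(
                1 for x, y in zip(a[lo_a:hi_a], target[lo_a - d:hi_a - d])
                if x == y)
            if 100.0 * matches / span >= min_identity:
                return True
    return False


class TestClusterGraph:
    def h(self, a, b):
        return SimilarityHit(a, b, 95.0, 1.0, "same", 0)

    def test_triangle_single_cluster(self):
        clusters, singles = cluster_graph(
            [self.h(0, 1), self.h(1, 2), self.h(0, 2)], 3)
        assert len(clusters) == 1 and clusters[0].size == 3
        assert singles == []

    def test_chain_matches_components_without_refinement(self):
        clusters, _ = cluster_graph([self.h(0, 1), self.h(1, 2)], 3,
                                    refine=False)
        assert [c.size for c in clusters] == [3]

    def test_size_class_threshold_arithmetic(self):
        # 80 members < 100 = 0.01% of 1e6 reads -> small
        hits = [self.h(i, i + 1) for i in range(79)]
        clusters, _ = cluster_graph(hits, 1_000_000, size_threshold=0.0001,
                                    refine=False)
        assert clusters[0].size == 80
        assert clusters[0].size_class == "small"

    def test_read_conservation(self, rng):
        reads = [rand_seq(rng) for _ in range(30)]
        reads += [mutate_str(reads[0], [i]) for i in range(10)]
        hits = find_hits(reads)
        clusters, singles = cluster_graph(hits, len(reads))
        assert sum(c.size for c in clusters) + len(singles) == len(reads)

    def test_cluster_ids_ordered_by_size(self, rng):
        base1, base2 = rand_seq(rng, 300), rand_seq(rng, 200)
        reads = [base1[s:s + 100] for s in range(0, 200, 10)]
        reads += [base2[s:s + 100] for s in range(0, 100, 10)]
        clusters, _ = cluster_graph(find_hits(reads), len(reads))
        sizes = [c.size for c in clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert [c.cluster_id for c in clusters] == list(range(1, len(sizes) + 1))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_refinement_off(self, seed):
        """Cluster memberships equal brute-force all-pairs + union-find."""
        rng = np.random.default_rng(1000 + seed)
        # a few diverged families plus noise reads
        n_fams = int(rng.integers(2, 5))
        reads = []
        for _ in range(n_fams):
            cons = rand_seq(rng, int(rng.integers(150, 400)))
            for _ in range(int(rng.integers(5, 25))):
                s = int(rng.integers(0, len(cons) - 100 + 1))
                r = cons[s:s + 100]
                pos = rng.choice(100, size=int(rng.integers(0, 6)),
                                 replace=False)
                r = mutate_str(r, pos)
                reads.append(r if rng.random() < 0.5 else revcomp(r))
        for _ in range(int(rng.integers(3, 10))):
            reads.append(rand_seq(rng))
        clusters, _ = cluster_graph(find_hits(reads), len(reads),
                                    refine=False)
        got = {frozenset(c.member_reads) for c in clusters}
        expected = brute_force_components(reads)
        assert got == expected


class TestComparative:
    def test_identical_species_equal_counts(self, rng):
        cons = rand_seq(rng, 200)
        recs = [(f"r{i}", cons[s:s + 100])
                for i, s in enumerate(range(0, 100, 10))]
        res = comparative_cluster({
            "a": [(f"a_{rid}", seq) for rid, seq in recs],
            "b": [(f"b_{rid}", seq) for rid, seq in recs]})
        for c in res.clusters:
            assert c.species_counts["a"] == c.species_counts["b"]

    def test_species_unique_cluster_flagged(self, rng):
        cons_a = rand_seq(rng, 200)
        cons_b = rand_seq(rng, 200)
        res = comparative_cluster({
            "a": [(f"a{i}", cons_a[s:s + 100])
                  for i, s in enumerate(range(0, 100, 12))],
            "b": [(f"b{i}", cons_b[s:s + 100])
                  for i, s in enumerate(range(0, 100, 12))]})
        uniq = res.unique_clusters()
        assert len(uniq) == 2
        assert res.shared_clusters() == []

    def test_colliding_ids_rejected(self, rng):
        r = rand_seq(rng)
        with pytest.raises(ValueError):
            comparative_cluster({"a": [("x", r)], "b": [("x", r)]})

    def test_coclustering_recovery_at_high_depth(self):
        """>= 90% of reads from families with divergence <= 0.05 land in the
        family's dominant cluster when reads tile the consensus densely.

        A read counts as "from" a family when >= 75% of it lies inside a
        family copy (an edge-straddling mate carrying < 55 nt of repeat can
        never satisfy the 55% overlap rule, whatever the clustering does).
        """
        import bisect

        spec = GenomeSpec("t", 500_000, [
            make_family("Low", ("ClassI", "LINE"), 500, 200, 0.01),
            make_family("High", ("ClassII", "TIR", "hAT"), 500, 200, 0.05),
        ], seed=3)
        genome = build_genome(spec)
        pairs = sample_reads(genome, n_pairs=600, degraded_tail_fraction=0,
                             seed=5)
        spans = sorted((s, e, f) for f, lst in genome.block_spans.items()
                       for s, e in lst)
        starts = [s for s, _, _ in spans]

        def family_of(mid, min_inside=75):
            i = bisect.bisect_right(starts, mid) - 1
            if i < 0:
                return None
            s, e, f = spans[i]
            inside = min(e, mid + 50) - max(s, mid - 50)
            return f if s <= mid < e and inside >= min_inside else None

        units, fams = [], []
        for p in pairs:
            units.append((f"{p.rid}/1", p.seq1[:100]))
            units.append((f"{p.rid}/2", p.seq2[:100]))
            fams.extend([family_of(p.origin1), family_of(p.origin2)])
        res = comparative_cluster({"sp": units})
        for fam in ("Low", "High"):
            members = [i for i, f in enumerate(fams) if f == fam]
            best = max(sum(1 for m in c.member_reads if fams[m] == fam)
                       for c in res.clusters)
            assert best / len(members) >= 0.9, fam
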