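"""All-vs-all read-similarity graph construction and clustering.

Candidate read pairs are found by shared canonical 9-mers (a provably
complete prefilter for the gap-free hit rule), then verified on the implied
diagonal.  A hit requires >= 90% identity over >= 55% of the read length,
considering both strands.  Clusters are connected components of the hit
graph, optionally refined by modularity-based community splitting with a
conductance gate so that well-connected components are not fragmented.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx

from .io_utils import revcomp


@dataclass
class SimilarityHit:
    read_a: int
    read_b: int
    identity: float  # % of aligned columns that match
    overlap_fraction: float  # aligned span / read length
    strand: str  # "same" | "opposite"
    offset: int  # start of read_a relative to read_b (strand-adjusted)

    def __post_init__(self):
        if self.read_a == self.read_b:
            raise ValueError("self-hit")


@dataclass
class ReadCluster:
    cluster_id: int  # ordinal by decreasing size, 1-based
    member_reads: list[int]
    species_counts: dict[str, int] = field(default_factory=dict)
    contigs: list[str] = field(default_factory=list)
    annotation: Optional[tuple[str, ...]] = None
    size_class: str = "small"  # "major" | "small"

    @property
    def size(self) -> int:
        return len(self.member_reads)


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned columns) from an edlib extended CIGAR."""
    matches = cols = num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            cols += num
            if ch == "=":
                matches += num
            num = 0
    return matches, cols


def align_identity(a: str, b: str) -> tuple[float, int]:
    """Global identity (%) between two sequences and aligned column count."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches, cols = _cigar_stats(res["cigar"])
    return 100.0 * matches / cols, cols


def verify_pair(seq_a: str, seq_b: str, offset: int,
                min_identity: float, min_overlap: float,
                band: int = 0) -> Optional[tuple[float, float]]:
    """Check one candidate (strand-resolved) pair at the given diagonal.

    With band=0 (the default) the overlap is compared gap-free on the
    diagonal, matching the substitution-only read model; band>0 switches to
    edlib alignment of the overlap window, for indel-bearing data.  Returns
    (identity, overlap_fraction) if the pair passes, else None.
    """
    la, lb = len(seq_a), len(seq_b)
    lo_a, hi_a = max(0, offset), min(la, lb + offset)
    span = hi_a - lo_a
    read_len = min(la, lb)
    if span < min_overlap * read_len - 1e-9:  # tolerate float boundary
        return None
    sub_a = seq_a[lo_a:hi_a]
    sub_b = seq_b[lo_a - offset : hi_a - offset]
    if band == 0:
        matches = sum(1 for x, y in zip(sub_a, sub_b) if x == y)
        identity, cols = 100.0 * matches / span, span
    else:
        identity, cols = align_identity(sub_a, sub_b)
    overlap_fraction = min(1.0, cols / read_len)
    if identity >= min_identity and overlap_fraction >= min_overlap - 1e-9:
        return identity, overlap_fraction
    return None


def find_hits(reads: Sequence[str], min_identity: float = 90.0,
              min_overlap: float = 0.55, k: int = 8,
              min_shared_kmers: int = 1, band: int = 0) -> list[SimilarityHit]:
    """Similarity hits between all read pairs passing the 90%/55% rule.

    Candidate (pair, strand, diagonal) triples come from shared canonical
    k-mers.  With the defaults the prefilter is *complete* for gap-free
    hits: at >= 90% identity over c columns there are m <= floor(0.1c)
    mismatches, so some exact run has length >= ceil((c-m)/(m+1)), whose
    minimum over c >= 55 is 8 -- the hit's own diagonal always carries a
    shared 8-mer.
    """
    n = len(reads)
    if n < 2:
        return []
    # canonical k-mer postings: kmer -> [(read, pos-in-forward, is_forward)]
    postings: dict[str, list[tuple[int, int, bool]]] = defaultdict(list)
    for i, seq in enumerate(reads):
        L = len(seq)
        for p in range(L - k + 1):
            km = seq[p : p + k]
            rc = revcomp(km)
            if km <= rc:
                postings[km].append((i, p, True))
            else:
                postings[rc].append((i, p, False))
    # votes per (pair, strand, diagonal)
    votes: Counter[tuple[int, int, bool, int]] = Counter()
    for entries in postings.values():
        if len(entries) < 2:
            continue
        for x in range(len(entries) - 1):
            i, pi, oi = entries[x]
            for y in range(x + 1, len(entries)):
                j, pj, oj = entries[y]
                if i == j:
                    continue
                a, pa, oa, b, pb, ob = (i, pi, oi, j, pj, oj) if i < j else (
                    j, pj, oj, i, pi, oi)
                same = oa == ob
                if same:
                    d = pa - pb
                else:
                    # position of the k-mer on revcomp(read_b)
                    d = pa - (len(reads[b]) - k - pb)
                votes[(a, b, same, d)] += 1
    # verify every candidate diagonal; keep the best hit per pair
    hits: dict[tuple[int, int], SimilarityHit] = {}
    for (a, b, same, d), c in sorted(votes.items()):
        if c < min_shared_kmers:
            continue
        seq_b = reads[b] if same else revcomp(reads[b])
        res = verify_pair(reads[a], seq_b, d, min_identity, min_overlap, band)
        if res is None:
            continue
        identity, ovl = res
        prev = hits.get((a, b))
        if prev is None or identity > prev.identity:
            hits[(a, b)] = SimilarityHit(a, b, identity, ovl,
                                         "same" if same else "opposite", d)
    return [hits[key] for key in sorted(hits)]


def _split_component(sub: nx.Graph, conductance_threshold: float,
                     seed: int) -> list[set]:
    """Louvain communities, re-merged while any pairwise conductance between
    community pair exceeds the threshold (prevents fragmenting one family)."""
    comms = [set(c) for c in nx.community.louvain_communities(sub, seed=seed)]
    if len(comms) <= 1:
        return [set(sub.nodes)]
    while len(comms) > 1:
        # volume (sum of degrees) per community and cut weights between pairs
        vol = [sum(d for _, d in sub.degree(c)) for c in comms]
        node2comm = {}
        for ci, c in enumerate(comms):
            for v in c:
                node2comm[v] = ci
        cut: Counter[tuple[int, int]] = Counter()
        for u, v in sub.edges():
            cu, cv = node2comm[u], node2comm[v]
            if cu != cv:
                cut[(min(cu, cv), max(cu, cv))] += 1
        if not cut:
            break
        (ci, cj), w = max(cut.items(),
                          key=lambda kv: kv[1] / max(1, min(vol[kv[0][0]], vol[kv[0][1]])))
        cond = w / max(1, min(vol[ci], vol[cj]))
        if cond <= conductance_threshold:
            break
        comms[ci] |= comms[cj]
        del comms[cj]
    return comms


def cluster_graph(hits: Sequence[SimilarityHit], n_reads: int,
                  size_threshold: float = 0.0001,
                  species: Optional[Sequence[str]] = None,
                  refine: bool = True,
                  conductance_threshold: float = 0.01,
                  seed: int = 0) -> tuple[list[ReadCluster], list[int]]:
    """Cluster the hit graph.

    Returns (clusters ordered by decreasing size, unclustered read indices).
    Clusters with >= size_threshold * n_reads members are flagged "major";
    reads with no hits at all form the single/low-copy bucket.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_reads))
    for h in hits:
        g.add_edge(h.read_a, h.read_b)
    groups: list[set] = []
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        if refine and len(comp) > 3:
            groups.extend(_split_component(g.subgraph(comp).copy(),
                                           conductance_threshold, seed))
        else:
            groups.append(set(comp))
    singles = sorted(v for v in g.nodes if g.degree(v) == 0)
    # also treat size-1 refinement leftovers as single-copy
    singles += sorted(x for grp in groups for x in grp if len(grp) == 1)
    groups = [grp for grp in groups if len(grp) > 1]
    groups.sort(key=lambda c: (-len(c), min(c)))
    min_major = size_threshold * n_reads
    clusters = []
    for idx, grp in enumerate(groups, start=1):
        members = sorted(grp)
        counts: dict[str, int] = {}
        if species is not None:
            for m in members:
                counts[species[m]] = counts.get(species[m], 0) + 1
        clusters.append(ReadCluster(
            cluster_id=idx, member_reads=members, species_counts=counts,
            size_class="major" if len(grp) >= min_major else "small"))
    return clusters, sorted(singles)


@dataclass
class ComparativeResult:
    reads: list[str]
    species: list[str]
    read_ids: list[str]
    hits: list[SimilarityHit]
    clusters: list[ReadCluster]
    singles: list[int]

    def shared_clusters(self) -> list[ReadCluster]:
        return [c for c in self.clusters
                if sum(1 for v in c.species_counts.values() if v > 0) > 1]

    def unique_clusters(self) -> list[ReadCluster]:
        return [c for c in self.clusters
                if sum(1 for v in c.species_counts.values() if v > 0) == 1]


def comparative_cluster(reads_by_species: dict[str, list[tuple[str, str]]],
                        min_identity: float = 90.0, min_overlap: float = 0.55,
                        size_threshold: float = 0.0001, refine: bool = True,
                        conductance_threshold: float = 0.01,
                        seed: int = 0) -> ComparativeResult:
    """Pooled clustering of species-tagged reads.

    reads_by_species maps species -> [(read_id, sequence)].  The caller is
    responsible for GS-proportional sampling when comparing genomes of
    different size.  Read ids must be unique across species.
    """
    if len(reads_by_species) < 1:
        raise ValueError("no species given")
    reads: list[str] = []
    species: list[str] = []
    read_ids: list[str] = []
    seen = set()
    for sp, recs in reads_by_species.items():
        for rid, seq in recs:
            if rid in seen:
                raise ValueError(f"read id {rid!r} collides across species")
            seen.add(rid)
            reads.append(seq)
            species.append(sp)
            read_ids.append(rid)
    hits = find_hits(reads, min_identity=min_identity, min_overlap=min_overlap)
    clusters, singles = cluster_graph(
        hits, len(reads), size_threshold=size_threshold, species=species,
        refine=refine, conductance_threshold=conductance_threshold, seed=seed)
    return ComparativeResult(reads, species, read_ids, hits, clusters, singles)
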