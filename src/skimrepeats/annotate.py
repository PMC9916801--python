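"""Cluster annotation against a miniature repeat reference library.

Library entries carry a taxonomy path (e.g. ClassI / LTR / Ty1-Copia / Ivana)
and are either protein-domain entries, searched by six-frame translated
alignment of the cluster contigs, or nucleotide entries (satellite monomers,
rDNA units), searched directly.  A cluster's label is the taxonomy path with
the greatest summed hit score, provided the hit-bearing contigs cover enough
of the cluster's reads; otherwise a tandem-periodicity detector may call
Satellite, and failing that the cluster stays Unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .assemble import Contig
from .cluster import ReadCluster, _cigar_stats
from .io_utils import revcomp
from .simulate import (GenomeSpec, RepeatFamilySpec, _decode, domain_region,
                       family_consensus)

UNCLASSIFIED: tuple[str, ...] = ("Unclassified",)
SATELLITE_PATH: tuple[str, ...] = ("Satellite",)


@dataclass
class LibraryEntry:
    taxonomy_path: tuple[str, ...]
    sequence: str  # aa for protein-domain entries, nt otherwise
    kind: str  # "protein-domain" | "nucleotide"


@dataclass
class RepeatLibrary:
    entries: list[LibraryEntry]

    def __len__(self) -> int:
        return len(self.entries)


def translate_frames(seq: str) -> list[str]:
    """Six-frame translation with stops masked to X (alignable)."""
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) >= 3:
                frames.append(str(Seq(sub).translate()).replace("*", "X"))
    return frames


def make_library(families: Sequence[RepeatFamilySpec], master_seed: int,
                 domain_len: int = 900) -> RepeatLibrary:
    """Miniature reference library built from the simulated family consensi:
    a translated internal domain for dispersed TEs, the monomer itself for
    tandem families."""
    entries = []
    for fam in families:
        cons = _decode(family_consensus(fam, master_seed))
        if fam.is_tandem:
            entries.append(LibraryEntry(fam.taxonomy_path, cons, "nucleotide"))
        else:
            s, e = domain_region(fam, domain_len)
            aa = str(Seq(cons[s:e]).translate()).replace("*", "X")
            entries.append(LibraryEntry(fam.taxonomy_path, aa, "protein-domain"))
    return RepeatLibrary(entries)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _nucleotide_hit(entry_seq: str, contig: str, min_identity: float = 0.85,
                    min_matches: int = 80) -> tuple[float, int]:
    """Best match between a (tandem) nucleotide entry and the contig.

    The entry is extended head-to-tail so that any monomer phase in the
    contig can align; both strands are tried.  Returns (score = matched
    bases, span); (0, 0) below the identity or length floor.
    """
    n_copies = max(2, len(contig) // len(entry_seq) + 2)
    target = entry_seq * n_copies  # always >= contig + 2 monomers
    best_score, best_span = 0.0, 0
    for query in (contig, revcomp(contig)):
        res = edlib.align(query, target, mode="HW", task="path")
        matches, cols = _cigar_stats(res["cigar"])
        if (cols and matches / cols >= min_identity
                and matches >= min(min_matches, 0.8 * len(contig))
                and matches > best_score):
            best_score, best_span = float(matches), cols
    return best_score, best_span


def detect_tandem_period(seq: str, min_period: int = 10, max_period: int = 500,
                         min_identity: float = 0.8) -> Optional[int]:
    """Smallest period p with self-identity >= min_identity at shift p and at
    least two full copies in the sequence (autocorrelation periodicity)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    for p in range(min_period, min(max_period, n // 2) + 1):
        frac = float((arr[:-p] == arr[p:]).mean())
        if frac >= min_identity:
            return p
    return None


def annotate_cluster(cluster: ReadCluster, contigs: Sequence[Contig],
                     library: RepeatLibrary, min_hit_fraction: float = 0.1,
                     min_protein_score: float = 60.0) -> tuple[str, ...]:
    """Label one cluster; also sets cluster.annotation."""
    n_cluster_reads = cluster.size
    scores: dict[tuple[str, ...], float] = {}
    spans: dict[tuple[str, ...], int] = {}
    covered_reads: dict[tuple[str, ...], int] = {}
    if library.entries and contigs:
        aligner = _protein_aligner()
        frames_per_contig = [translate_frames(c.sequence) for c in contigs]
        for entry in library.entries:
            path = entry.taxonomy_path
            for contig, frames in zip(contigs, frames_per_contig):
                best = 0.0
                span = 0
                if entry.kind == "protein-domain":
                    for fr in frames:
                        if len(fr) < 10:
                            continue
                        sc = aligner.score(fr, entry.sequence)
                        if sc >= min_protein_score and sc > best:
                            best = float(sc)
                            span = len(entry.sequence)
                else:
                    best, span = _nucleotide_hit(entry.sequence, contig.sequence)
                if best > 0:
                    scores[path] = scores.get(path, 0.0) + best
                    spans[path] = spans.get(path, 0) + span
                    covered_reads[path] = covered_reads.get(path, 0) + contig.n_reads
    # deterministic tie-break: score, then total hit span, then path
    candidates = [
        p for p in scores
        if n_cluster_reads == 0
        or covered_reads.get(p, 0) / n_cluster_reads >= min_hit_fraction
    ]
    if candidates:
        top = max((scores[p], spans[p]) for p in candidates)
        label = min(p for p in candidates if (scores[p], spans[p]) == top)
        cluster.annotation = label
        return label
    for contig in contigs:
        if detect_tandem_period(contig.sequence) is not None:
            cluster.annotation = SATELLITE_PATH
            return SATELLITE_PATH
    cluster.annotation = UNCLASSIFIED
    return UNCLASSIFIED


def annotate_clusters(clusters: Sequence[ReadCluster],
                      contigs_by_cluster: Sequence[Sequence[Contig]],
                      library: RepeatLibrary,
                      min_hit_fraction: float = 0.1) -> None:
    for cluster, contigs in zip(clusters, contigs_by_cluster):
        annotate_cluster(cluster, contigs, library, min_hit_fraction)
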