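"""Quality trimming and organelle-read removal ahead of clustering.

Trimming mirrors the classic Trimmomatic rule set applied in the order
LEADING, TRAILING, SLIDINGWINDOW, AVGQUAL, MINLEN, followed by a fixed CROP
to 100 nt.  A pair survives only if both mates survive.  Organelle (plastid)
pairs are removed by k-mer containment against a chloroplast reference
rather than by full alignment; the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_utils import revcomp, string_to_quals
from .simulate import ReadPair


@dataclass
class TrimSettings:
    avgqual: int = 20
    minlen: int = 100
    leading: int = 20
    trailing: int = 20
    window: tuple[int, int] = (4, 20)
    crop: int = 100


def trim_one(seq: str, quals: Sequence[int], s: TrimSettings = TrimSettings()
             ) -> Optional[tuple[str, list[int]]]:
    """Apply the trimming rules to a single read; None if discarded."""
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    q = list(quals)
    # LEADING: drop 5' bases while below threshold
    start = 0
    while start < len(q) and q[start] < s.leading:
        start += 1
    # TRAILING
    end = len(q)
    while end > start and q[end - 1] < s.trailing:
        end -= 1
    seq, q = seq[start:end], q[start:end]
    # SLIDINGWINDOW w:thr — cut at the start of the first failing window
    w, thr = s.window
    if len(q) >= w:
        qa = np.asarray(q, dtype=float)
        means = np.convolve(qa, np.ones(w) / w, mode="valid")
        bad = np.nonzero(means < thr)[0]
        if bad.size:
            cut = int(bad[0])
            seq, q = seq[:cut], q[:cut]
    # MINLEN before cropping
    if len(seq) < s.minlen:
        return None
    # CROP, then re-apply TRAILING and AVGQUAL to the final read so that
    # trimming is idempotent (a crop can expose a low-quality 3' base)
    seq, q = seq[: s.crop], q[: s.crop]
    end = len(q)
    while end > 0 and q[end - 1] < s.trailing:
        end -= 1
    seq, q = seq[:end], q[:end]
    if len(seq) < s.minlen:
        return None
    if float(np.mean(q)) < s.avgqual:
        return None
    return seq, q


def trim_reads(pairs: Iterable[ReadPair], settings: TrimSettings = TrimSettings()
               ) -> list[ReadPair]:
    """Trim both mates of every pair; keep pairs where both mates survive."""
    out = []
    for p in pairs:
        t1 = trim_one(p.seq1, p.qual1, settings)
        if t1 is None:
            continue
        t2 = trim_one(p.seq2, p.qual2, settings)
        if t2 is None:
            continue
        out.append(ReadPair(p.rid, t1[0], t1[1], t2[0], t2[1], p.from_plastid,
                            p.origin1, p.origin2))
    return out


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_organelle_index(reference: str, k: int = 21) -> set[str]:
    """k-mers of the organelle reference, both strands."""
    kmers = _kmer_set(reference, k)
    kmers |= _kmer_set(revcomp(reference), k)
    return kmers


def kmer_containment(seq: str, index: set[str], k: int) -> float:
    n = len(seq) - k + 1
    if n <= 0:
        raise ValueError(f"k={k} exceeds read length {len(seq)}")
    hits = sum(1 for i in range(n) if seq[i : i + k] in index)
    return hits / n


def filter_organelle(pairs: Sequence[ReadPair], organelle_ref: str,
                     k: int = 21, containment_threshold: float = 0.8,
                     remove_pair: bool = True) -> tuple[list[ReadPair], int]:
    """Remove pairs where either mate looks organelle-derived.

    Returns (nuclear pairs, number of removed pairs).  By default a pair is
    removed when either mate's k-mer containment reaches the threshold; with
    remove_pair off, both mates must match (stricter, keeps chimeric pairs).
    """
    if not organelle_ref:
        raise ValueError("organelle reference is empty")
    index = build_organelle_index(organelle_ref, k)
    kept: list[ReadPair] = []
    removed = 0
    for p in pairs:
        c1 = kmer_containment(p.seq1, index, k) >= containment_threshold
        c2 = kmer_containment(p.seq2, index, k) >= containment_threshold
        is_org = (c1 or c2) if remove_pair else (c1 and c2)
        if is_org:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


def pairs_from_fastq(r1: Iterable[tuple[str, str, str]],
                     r2: Iterable[tuple[str, str, str]]) -> list[ReadPair]:
    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2, strict=True):
        base1 = id1.split("/")[0].split()[0]
        base2 = id2.split("/")[0].split()[0]
        if base1 != base2:
            raise ValueError(f"unpaired records: {id1!r} vs {id2!r}")
        out.append(ReadPair(base1, s1, string_to_quals(q1), s2, string_to_quals(q2)))
    return out


def prep_summary(n_input: int, n_trimmed: int, n_organelle: int) -> dict:
    return {
        "input_pairs": n_input,
        "failed_trimming": n_input - n_trimmed,
        "organelle_removed": n_organelle,
        "surviving_pairs": n_trimmed - n_organelle,
    }
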