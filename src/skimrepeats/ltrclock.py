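"""LTR-pair detection and insertion-time dating.

The two long terminal repeats of an LTR retroelement are identical at
insertion and diverge thereafter, so the Kimura two-parameter distance K
between them dates the insertion as T = K / (2 mu) with mu the substitution
rate per site per year.  Pairs of similar direct repeats are harvested from
contigs by seeded diagonal matching; near-duplicate contigs can first be
removed by greedy identity clustering (both paths are supported since the
published workflow ran both and found them consistent).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .cluster import _cigar_stats
from .simulate import DEFAULT_MU

import edlib

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class LTRPairRecord:
    contig_id: str
    ltr5_span: tuple[int, int]  # half-open, 0-based, ltr5 before ltr3
    ltr3_span: tuple[int, int]
    aligned_pair: tuple[str, str]  # gapped alignment of the two LTRs
    identity: float
    P: float = float("nan")  # transition fraction
    Q: float = float("nan")  # transversion fraction
    K: float = float("nan")  # Kimura 2P distance, subst/site
    T_mya: float = float("nan")
    annotation: Optional[tuple[str, ...]] = None


class SaturationError(ValueError):
    """K2P log argument non-positive: the pair is too diverged to date."""


def kimura2p(aligned_pair: tuple[str, str]) -> tuple[float, float, float]:
    """(P, Q, K) from a gapped alignment; gap/ambiguous columns excluded.

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).
    """
    a, b = aligned_pair
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    sites = ts = tv = 0
    for ca, cb in zip(a, b):
        if ca not in "ACGT" or cb not in "ACGT":
            continue
        sites += 1
        if ca == cb:
            continue
        if (ca in PURINES) == (cb in PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("empty alignment")
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}): K2P undefined")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, K


def insertion_time(K: float, mu: float = DEFAULT_MU) -> float:
    """Insertion age in Mya: T = K / (2 mu), converted from years."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * mu) / 1e6


_LTR_ALIGNER: Optional[PairwiseAligner] = None


def _ltr_aligner() -> PairwiseAligner:
    global _LTR_ALIGNER
    if _LTR_ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -1
        a.open_gap_score = -10
        a.extend_gap_score = -0.5
        _LTR_ALIGNER = a
    return _LTR_ALIGNER


def align_ltr_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Global alignment of the two LTR sequences (affine gaps)."""
    aln = _ltr_aligner().align(seq5, seq3)[0]
    a, b = [], []
    coords = aln.coordinates
    for k in range(coords.shape[1] - 1):
        s5a, s5b = coords[0, k], coords[0, k + 1]
        s3a, s3b = coords[1, k], coords[1, k + 1]
        seg5 = seq5[s5a:s5b]
        seg3 = seq3[s3a:s3b]
        if len(seg5) < len(seg3):
            seg5 += "-" * (len(seg3) - len(seg5))
        elif len(seg3) < len(seg5):
            seg3 += "-" * (len(seg5) - len(seg3))
        a.append(seg5)
        b.append(seg3)
    return "".join(a), "".join(b)


def _refine_span(contig: str, s: int, e: int, d: int, window: int = 10,
                 min_window_identity: float = 0.6) -> tuple[int, int]:
    """Extend a seed-anchored repeat span outward along its diagonal.

    Seeds only mark exact matches, which truncates the diverged ends of old
    LTRs (and would bias the distance down); windows are extended while the
    two copies stay locally similar, i.e. until the flanking or internal
    background (~25% identity) is reached.
    """
    n = len(contig)
    while s - window >= 0:
        a = contig[s - window : s]
        b = contig[s - window + d : s + d]
        if sum(x == y for x, y in zip(a, b)) / window < min_window_identity:
            break
        s -= window
    while e + window + d <= n:
        a = contig[e : e + window]
        b = contig[e + d : e + d + window]
        if sum(x == y for x, y in zip(a, b)) / window < min_window_identity:
            break
        e += window
    return s, e


def detect_ltr_pairs(contig: str, contig_id: str = "contig",
                     min_ltr: int = 100, max_ltr: int = 2000,
                     min_identity: float = 80.0,
                     min_spacing: int = 1000, max_spacing: int = 15000,
                     seed_k: int = 13, min_seeds: int = 3
                     ) -> list[LTRPairRecord]:
    """Maximal pairs of similar direct repeats within one contig.

    Exact seed_k-mer matches between distant positions vote for diagonals;
    a diagonal with enough seeds defines a candidate repeat pair, refined by
    global alignment of the spanned windows.  Overlapping candidates resolve
    to the highest-identity, longest pair.
    """
    n = len(contig)
    if n < 2 * min_ltr + min_spacing:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for p in range(n - seed_k + 1):
        index[contig[p : p + seed_k]].append(p)
    # diagonal (= distance between copy starts) -> seed positions
    diags: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 50:
            continue  # skip hyper-repetitive (satellite-like) seeds
        for x in range(len(positions) - 1):
            for y in range(x + 1, len(positions)):
                d = positions[y] - positions[x]
                if min_ltr + min_spacing <= d <= max_ltr + max_spacing:
                    diags[d].append(positions[x])
    candidates: list[LTRPairRecord] = []
    merged: dict[int, list[int]] = {}
    # merge nearby diagonals (indel tolerance of +-2)
    for d in sorted(diags):
        home = next((dd for dd in merged if abs(dd - d) <= 2), None)
        if home is None:
            merged[d] = list(diags[d])
        else:
            merged[home].extend(diags[d])
    for d, seeds in merged.items():
        if len(seeds) < min_seeds:
            continue
        s = min(seeds)
        e = max(seeds) + seed_k
        s, e = _refine_span(contig, s, e, d)
        length = e - s
        if not (min_ltr <= length <= max_ltr):
            continue
        spacing = d - length
        if not (min_spacing <= spacing <= max_spacing):
            continue
        if e + d > n:
            continue
        seq5 = contig[s:e]
        seq3 = contig[s + d : e + d]
        aligned = align_ltr_pair(seq5, seq3)
        matches = sum(1 for x, y in zip(*aligned) if x == y and x != "-")
        identity = 100.0 * matches / len(aligned[0])
        if identity < min_identity:
            continue
        candidates.append(LTRPairRecord(
            contig_id=contig_id, ltr5_span=(s, e), ltr3_span=(s + d, e + d),
            aligned_pair=aligned, identity=identity))
    # resolve overlaps: highest identity, then longest
    candidates.sort(key=lambda r: (-r.identity,
                                   r.ltr5_span[0] - r.ltr5_span[1]))
    chosen: list[LTRPairRecord] = []
    for cand in candidates:
        span = (cand.ltr5_span[0], cand.ltr3_span[1])
        if any(not (span[1] <= c.ltr5_span[0] or span[0] >= c.ltr3_span[1])
               for c in chosen):
            continue
        chosen.append(cand)
    chosen.sort(key=lambda r: r.ltr5_span)
    return chosen


def date_records(records: Sequence[LTRPairRecord], mu: float = DEFAULT_MU
                 ) -> tuple[list[LTRPairRecord], list[str]]:
    """Fill P, Q, K, T_mya in place; saturated pairs are excluded and their
    reasons returned."""
    dated, excluded = [], []
    for rec in records:
        try:
            rec.P, rec.Q, rec.K = kimura2p(rec.aligned_pair)
        except SaturationError as err:
            excluded.append(f"{rec.contig_id}:{rec.ltr5_span}: {err}")
            continue
        rec.T_mya = insertion_time(rec.K, mu)
        dated.append(rec)
    return dated, excluded


def dedup_contigs(contigs: Sequence[tuple[str, str]],
                  identity_threshold: float = 0.9) -> list[tuple[str, str]]:
    """Greedy longest-first duplicate removal: a contig is dropped when its
    global identity to an already-retained representative reaches the
    threshold (CD-HIT-style cleaning)."""
    ordered = sorted(contigs, key=lambda c: (-len(c[1]), c[0]))
    kept: list[tuple[str, str]] = []
    for cid, seq in ordered:
        dup = False
        for _, rep in kept:
            res = edlib.align(seq, rep, mode="NW", task="path")
            matches, cols = _cigar_stats(res["cigar"])
            if cols and matches / cols >= identity_threshold:
                dup = True
                break
        if not dup:
            kept.append((cid, seq))
    return kept


@dataclass
class InsertionTimeSummary:
    species: str
    n_pairs: int
    median_mya: Optional[float] = None
    mean_mya: Optional[float] = None
    sd_mya: Optional[float] = None  # n-1 denominator; None when n < 2
    max_mya: Optional[float] = None
    subset: str = "all"
    dedup: bool = True


def summarize_ages(records: Sequence[LTRPairRecord], species: str = "",
                   subset: str = "all", dedup: bool = True
                   ) -> InsertionTimeSummary:
    """Median/mean/SD/max insertion age over dated records of one subset."""
    if subset == "all":
        recs = list(records)
    else:
        recs = [r for r in records
                if r.annotation is not None and subset in r.annotation]
    ages = np.array([r.T_mya for r in recs if not math.isnan(r.T_mya)])
    summary = InsertionTimeSummary(species, int(ages.size), subset=subset,
                                   dedup=dedup)
    if ages.size:
        summary.median_mya = float(np.median(ages))
        summary.mean_mya = float(np.mean(ages))
        summary.max_mya = float(np.max(ages))
        if ages.size > 1:
            summary.sd_mya = float(np.std(ages, ddof=1))
    return summary


def age_histogram(records: Sequence[LTRPairRecord], bin_mya: float = 1.0
                  ) -> pd.DataFrame:
    ages = [r.T_mya for r in records if not math.isnan(r.T_mya)]
    if not ages:
        return pd.DataFrame(columns=["bin_start_mya", "count"])
    edges = np.arange(0, math.ceil(max(ages) / bin_mya) * bin_mya + bin_mya,
                      bin_mya)
    counts, _ = np.histogram(ages, bins=edges)
    return pd.DataFrame({"bin_start_mya": edges[:-1], "count": counts})


def records_table(records: Sequence[LTRPairRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"contig_id": r.contig_id,
         "ltr5_start": r.ltr5_span[0], "ltr5_end": r.ltr5_span[1],
         "ltr3_start": r.ltr3_span[0], "ltr3_end": r.ltr3_span[1],
         "identity": r.identity, "P": r.P, "Q": r.Q, "K": r.K,
         "T_mya": r.T_mya,
         "annotation": "/".join(r.annotation) if r.annotation else ""}
        for r in records])


def plot_age_histogram(records: Sequence[LTRPairRecord], path: str,
                       species: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = age_histogram(records)
    fig, ax = plt.subplots(figsize=(4, 3))
    if not hist.empty:
        ax.bar(hist["bin_start_mya"] + 0.5, hist["count"], width=0.9)
    ax.set_xlabel("insertion time (Mya)")
    ax.set_ylabel("count")
    ax.set_title(species)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
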