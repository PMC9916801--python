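"""Within-cluster, within-species sequence-heterogeneity profiles.

For each selected cluster and species, the distribution of pairwise read
identities (from the stored similarity-hit table, so no re-alignment) is
summarized as a 1%-bin histogram over [90, 100], a median at 0.1%
resolution, and the fraction of pairs at >= 94% identity.  High-identity
profiles indicate recent amplification; skew toward lower identity indicates
ancient, diverged copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import ReadCluster, SimilarityHit

CONSERVED_THRESHOLD = 94.0
HIST_BINS = [(lo, lo + 1) for lo in range(90, 100)]


@dataclass
class HeterogeneityProfile:
    cluster_id: int
    species: str
    n_pairs: int
    histogram: dict[tuple[int, int], int] = field(default_factory=dict)
    median_identity: Optional[float] = None
    conserved_fraction: Optional[float] = None

    def check(self) -> None:
        assert sum(self.histogram.values()) == self.n_pairs
        if self.n_pairs > 0:
            assert 90.0 <= self.median_identity <= 100.0


def select_top_clusters(clusters: Sequence[ReadCluster], n_types: int = 8,
                        per_type: int = 2,
                        satellite_per_species: bool = True
                        ) -> list[ReadCluster]:
    """The per_type largest clusters from each of the n_types most abundant
    repeat types (by combined read count across species).

    For Satellite the selection is the per_type largest clusters per species
    instead (clusters dominated by one species's reads qualify per species).
    Ties in type abundance break by summed read count then label order.
    """
    by_type: dict[tuple[str, ...], list[ReadCluster]] = {}
    for c in clusters:
        if c.annotation is None:
            continue
        by_type.setdefault(c.annotation, []).append(c)
    ranked = sorted(by_type,
                    key=lambda p: (-sum(c.size for c in by_type[p]), p))
    selected: list[ReadCluster] = []
    for path in ranked[:n_types]:
        members = sorted(by_type[path], key=lambda c: (-c.size, c.cluster_id))
        if path == ("Satellite",) and satellite_per_species:
            species = sorted({sp for c in members for sp in c.species_counts})
            chosen: list[ReadCluster] = []
            for sp in species:
                by_sp = sorted(members,
                               key=lambda c: (-c.species_counts.get(sp, 0),
                                              c.cluster_id))
                for c in by_sp[:per_type]:
                    if c not in chosen:
                        chosen.append(c)
            selected.extend(chosen)
        else:
            selected.extend(members[:per_type])
    return selected


def heterogeneity_profile(cluster: ReadCluster, species: str,
                          hits: Sequence[SimilarityHit],
                          read_species: Optional[Sequence[str]] = None,
                          member_filter: Optional[set[int]] = None
                          ) -> HeterogeneityProfile:
    """Profile of pairwise identities between same-species reads of a cluster.

    Reciprocal hits are stored once in the hit table, so each unordered pair
    is counted once.  member_filter optionally restricts to a subset of reads
    (e.g. forward mates only).
    """
    members = set(cluster.member_reads)
    if member_filter is not None:
        members &= member_filter
    idents = []
    for h in hits:
        if h.read_a not in members or h.read_b not in members:
            continue
        if read_species is not None and (
                read_species[h.read_a] != species
                or read_species[h.read_b] != species):
            continue
        idents.append(h.identity)
    hist: Counter[tuple[int, int]] = Counter({b: 0 for b in HIST_BINS})
    for ident in idents:
        lo = min(99, max(90, int(ident) if ident < 100 else 99))
        hist[(lo, lo + 1)] += 1
    prof = HeterogeneityProfile(cluster.cluster_id, species, len(idents),
                                dict(hist))
    if idents:
        prof.median_identity = round(float(np.median(idents)), 1)
        prof.conserved_fraction = float(
            np.mean([i >= CONSERVED_THRESHOLD for i in idents]))
    prof.check()
    return prof


def profiles_table(profiles: Sequence[HeterogeneityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"cluster_id": p.cluster_id, "species": p.species,
               "n_pairs": p.n_pairs, "median_identity": p.median_identity,
               "conserved_fraction": p.conserved_fraction}
        for (lo, hi), n in sorted(p.histogram.items()):
            row[f"bin_{lo}_{hi}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def plot_profile(profile: HeterogeneityProfile, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    bins = sorted(profile.histogram)
    ax.bar([b[0] + 0.5 for b in bins], [profile.histogram[b] for b in bins],
           width=0.9)
    if profile.median_identity is not None:
        ax.axvline(profile.median_identity, ls="--", color="k")
    ax.set_xlabel("pairwise identity (%)")
    ax.set_ylabel("count")
    ax.set_title(f"CL{profile.cluster_id} {profile.species}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
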