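"""Genome composition tables and the comparative origin-forced regression.

Genomic proportion (GP) of a repeat cluster is its share of the analyzed
reads, interpreted as the fraction of the genome the repeat occupies; the
absolute amount is GP times the species' 1C genome size.  The two-species
comparison regresses per-cluster read counts of the larger genome on the
smaller, forcing the line through the origin, and compares the slope with
the genome-size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ReadCluster

SMALL_LABEL = "Small unclassified clusters (GP < 0.01%)"


def gs_ratio(gs_a: float, gs_b: float) -> float:
    """Genome-size ratio gs_a / gs_b (e.g. 147.29/73.19 = 2.01)."""
    if gs_a <= 0 or gs_b <= 0:
        raise ValueError("genome sizes must be positive")
    return gs_a / gs_b


def genomic_proportion(cluster_read_count: int, total_reads: int,
                       gs_bp: float) -> tuple[float, float]:
    """(gp_percent, absolute amount in bp) of one cluster."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if cluster_read_count > total_reads:
        raise ValueError("cluster read count exceeds total reads")
    gp = 100.0 * cluster_read_count / total_reads
    return gp, gp / 100.0 * gs_bp


def composition_table(clusters: Sequence[ReadCluster], total_reads: int,
                      gs_bp: float, species: Optional[str] = None
                      ) -> pd.DataFrame:
    """Aggregate annotated clusters into a composition table.

    Rows cover every annotation path and each of its ancestor prefixes
    (superfamily rows are exact sums of their lineage rows), the pooled
    small clusters, Total repeats, and Single copy (= 100 - Total).
    Cluster read counts may be per-species (pass `species`) or total.
    """
    def count(c: ReadCluster) -> int:
        return c.species_counts.get(species, 0) if species else c.size

    path_reads: dict[tuple[str, ...], int] = {}
    path_nclusters: dict[tuple[str, ...], int] = {}
    small_reads = 0
    for c in clusters:
        n = count(c)
        if c.size_class == "small":
            small_reads += n
            continue
        path = c.annotation or ("Unclassified",)
        path_reads[path] = path_reads.get(path, 0) + n
        path_nclusters[path] = path_nclusters.get(path, 0) + 1
    rows = []
    # ancestor prefixes, deepest-first aggregation
    all_paths: set[tuple[str, ...]] = set()
    for path in path_reads:
        for depth in range(1, len(path) + 1):
            all_paths.add(path[:depth])
    for prefix in sorted(all_paths):
        reads = sum(v for p, v in path_reads.items() if p[: len(prefix)] == prefix)
        ncl = sum(v for p, v in path_nclusters.items() if p[: len(prefix)] == prefix)
        gp, gp_abs = genomic_proportion(reads, total_reads, gs_bp)
        rows.append(("/".join(prefix), len(prefix), ncl, reads, gp, gp_abs))
    total_repeat_reads = sum(path_reads.values()) + small_reads
    gp, gp_abs = genomic_proportion(small_reads, total_reads, gs_bp)
    rows.append((SMALL_LABEL, 1, sum(1 for c in clusters if c.size_class == "small"),
                 small_reads, gp, gp_abs))
    gp, gp_abs = genomic_proportion(total_repeat_reads, total_reads, gs_bp)
    rows.append(("Total repeats", 0, len(clusters), total_repeat_reads, gp, gp_abs))
    single_reads = total_reads - total_repeat_reads
    gp, gp_abs = genomic_proportion(single_reads, total_reads, gs_bp)
    rows.append(("Single copy", 0, 0, single_reads, gp, gp_abs))
    df = pd.DataFrame(rows, columns=["repeat_type", "depth", "n_clusters",
                                     "n_reads", "gp_percent", "gp_abs_bp"])
    df["gp_gbp"] = df["gp_abs_bp"] / 1e9
    return df


@dataclass
class RegressionResult:
    subset: str
    slope: float
    r_squared: float
    p_value: float
    n_points: int
    expected_ratio: Optional[float] = None


def origin_regression(points: Sequence[tuple[float, float]], subset: str = "All",
                      expected_ratio: Optional[float] = None) -> RegressionResult:
    """Least-squares line through the origin: y = slope * x.

    slope = Sxy/Sx^2; R^2 is the uncentered 1 - RSS/Sy^2 (the convention for
    a no-intercept fit); p-value from the slope's t statistic with n-1 df.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all-zero x values")
    slope = float(x @ y) / sxx
    rss = float(((y - slope * x) ** 2).sum())
    syy = float(y @ y)
    r2 = 1.0 - rss / syy if syy > 0 else float("nan")
    n = len(x)
    df = n - 1
    sigma2 = rss / df if df > 0 else float("nan")
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0
    else:
        p = float(2 * stats.t.sf(abs(slope) / se, df))
    return RegressionResult(subset, slope, r2, p, n, expected_ratio)


#: cluster subsets mirrored from the comparative analysis
SUBSETS = ("Ty1/Copia", "Ty3/Gypsy", "All", "All classified")


def cluster_points(clusters: Sequence[ReadCluster], species_x: str,
                   species_y: str, subset: str = "All"
                   ) -> list[tuple[float, float]]:
    """Per-cluster (reads in species_x, reads in species_y) for shared
    clusters, filtered to a taxonomy subset."""
    pts = []
    for c in clusters:
        x = c.species_counts.get(species_x, 0)
        y = c.species_counts.get(species_y, 0)
        if x == 0 or y == 0:
            continue
        path = c.annotation or ("Unclassified",)
        if subset == "All":
            pass
        elif subset == "All classified":
            if path == ("Unclassified",):
                continue
        elif subset not in path:
            continue
        pts.append((float(x), float(y)))
    return pts


def regression_table(clusters: Sequence[ReadCluster], species_x: str,
                     species_y: str, expected_ratio: float,
                     subsets: Sequence[str] = SUBSETS) -> pd.DataFrame:
    rows = []
    for subset in subsets:
        pts = cluster_points(clusters, species_x, species_y, subset)
        if len(pts) < 2:
            continue
        r = origin_regression(pts, subset, expected_ratio)
        rows.append((subset, r.slope, r.r_squared, r.p_value, r.n_points,
                     expected_ratio))
    return pd.DataFrame(rows, columns=["subset", "slope", "r_squared",
                                       "p_value", "n_clusters", "expected_ratio"])


def single_copy_difference_bp(single_pct_a: float, gs_a: float,
                              single_pct_b: float, gs_b: float) -> float:
    """Absolute difference in single-copy DNA between two genomes (bp)."""
    return single_pct_a / 100.0 * gs_a - single_pct_b / 100.0 * gs_b
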