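"""Canonical desk-scale study conditions for the synthetic analyses.

The full-scale study compares a tetraploid baseline genome with a sister
genome doubled by whole-genome multiplication (WGM).  At desk scale that is
represented by a 20 Mb baseline and its 40 Mb WGM derivative carrying the
same repeat families (two satellites, seven LTR lineages across Ty1/Copia
and Ty3/Gypsy, a LINE, two TIR DNA transposons, rDNA, and two dozen
unannotatable "dark matter" families), sampled at 0.5% analyzed coverage
with 150 nt paired-end reads trimmed to 100 nt.  The giga-base scale of the
real genomes enters only through the 1C metadata used when converting
genomic proportions to absolute amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotate import RepeatLibrary, make_library
from .assemble import Contig, build_contigs
from .cluster import ComparativeResult, ReadCluster, comparative_cluster
from .readprep import TrimSettings, filter_organelle, trim_reads
from .simulate import (GenomeSpec, ReadPair, RepeatFamilySpec, SimulatedGenome,
                       apply_wgm, build_genome, make_plastid, sample_reads,
                       simulate_ltr_pairs)

BASELINE_GS = 20_000_000  # bp; WGM derivative is 2x
ANALYZED_COVERAGE = 0.005  # 0.5% of the genome in analyzed 100 nt reads
PLASTID_FRACTION = 0.02
N_DARK_FAMILIES = 24


def classified_families() -> list[RepeatFamilySpec]:
    """Library-represented families (percentages refer to the baseline).

    Consensus lengths are scaled to the 0.5%-coverage sampling depth so that
    each family's reads tile its consensus at ~8x or more and form connected
    similarity graphs, mirroring how the full-scale analysis relies on
    millions of reads for graph connectivity.
    """
    F = RepeatFamilySpec
    return [
        F("SatA", ("Satellite",), 170, 29412, 0.01, is_tandem=True),        # 25%
        F("SatB", ("Satellite",), 340, 4706, 0.02, is_tandem=True),         # 8%
        F("Athila", ("ClassI", "LTR", "Ty3/Gypsy", "Athila"), 1000, 1600,
          0.02, ltr_length=150, planted_age_mya=2.0),                       # 8%
        F("Ivana", ("ClassI", "LTR", "Ty1/Copia", "Ivana"), 1000, 1000,
          0.03, ltr_length=150, planted_age_mya=5.0),                       # 5%
        F("Tork", ("ClassI", "LTR", "Ty1/Copia", "Tork"), 900, 1000,
          0.04, ltr_length=150, planted_age_mya=7.0),                       # 4.5%
        F("LINE", ("ClassI", "LINE"), 600, 1333, 0.05),                     # 4%
        F("hAT", ("ClassII", "TIR", "hAT"), 500, 800, 0.04),                # 2%
        F("CACTA", ("ClassII", "TIR", "EnSpm-CACTA"), 450, 889, 0.05),      # 2%
        F("Ale", ("ClassI", "LTR", "Ty1/Copia", "Ale"), 800, 375,
          0.03, ltr_length=130, planted_age_mya=4.0),                       # 1.5%
        F("Tekay", ("ClassI", "LTR", "Ty3/Gypsy", "Tekay"), 800, 250,
          0.04, ltr_length=130, planted_age_mya=9.0),                       # 1%
        F("rDNA", ("rDNA",), 1500, 133, 0.01, is_tandem=True),              # 1%
        F("SIRE", ("ClassI", "LTR", "Ty1/Copia", "SIRE"), 700, 143,
          0.03, ltr_length=120, planted_age_mya=3.0),                       # 0.5%
        F("Reina", ("ClassI", "LTR", "Ty3/Gypsy", "Reina"), 700, 143,
          0.04, ltr_length=120, planted_age_mya=6.0),                       # 0.5%
    ]


def dark_families(n: int = N_DARK_FAMILIES) -> list[RepeatFamilySpec]:
    """Old, degraded repeat families absent from the reference library;
    together they emulate the unannotatable 'dark matter' fraction."""
    fams = []
    for i in range(n):
        div = 0.03 + 0.03 * (i % 4) / 3  # 0.03 .. 0.06
        fams.append(RepeatFamilySpec(
            f"Dark{i:02d}", ("Unknown",), 400, 350, div))  # ~0.7% each
    return fams


def default_families() -> list[RepeatFamilySpec]:
    return classified_families() + dark_families()


def baseline_spec(seed: int = 42) -> GenomeSpec:
    return GenomeSpec("baseline", BASELINE_GS, default_families(), seed=seed)


def wgm_spec(seed: int = 42,
             bursts: Optional[list[tuple[str, int, float]]] = None
             ) -> GenomeSpec:
    return GenomeSpec("wgm", BASELINE_GS, default_families(), wgm_factor=2,
                      amplification_bursts=bursts or [], seed=seed)


def make_study_genomes(seed: int = 42
                       ) -> tuple[SimulatedGenome, SimulatedGenome,
                                  RepeatLibrary, str]:
    """(baseline genome, WGM genome, annotation library, plastid reference).

    The WGM genome is the doubled baseline (same seed), modelling a sister
    species whose genome-size difference is explained by the WGM alone.
    """
    base = build_genome(baseline_spec(seed))
    wgm = apply_wgm(build_genome(GenomeSpec(
        "wgm", BASELINE_GS, default_families(), wgm_factor=2, seed=seed)))
    library = make_library(classified_families(), seed)
    plastid = make_plastid(seed=seed)
    return base, wgm, library, plastid


def n_pairs_for_coverage(gs_bp: int, coverage: float = ANALYZED_COVERAGE,
                         analyzed_len: int = 100) -> int:
    """Raw read pairs so that the analyzed reads (both mates, trimmed to
    analyzed_len) cover `coverage` of the genome."""
    return round(coverage * gs_bp / (2 * analyzed_len))


def prepped_reads(genome: SimulatedGenome, plastid: str, seed: int,
                  coverage: float = ANALYZED_COVERAGE,
                  plastid_fraction: float = PLASTID_FRACTION,
                  prefix: str = "read") -> list[ReadPair]:
    """Simulate, quality-trim, and organelle-filter one species' reads."""
    pairs = sample_reads(
        genome, n_pairs=n_pairs_for_coverage(len(genome), coverage),
        plastid_ref=plastid, plastid_fraction=plastid_fraction,
        seed=seed, prefix=prefix)
    trimmed = trim_reads(pairs, TrimSettings())
    nuclear, _ = filter_organelle(trimmed, plastid)
    return nuclear


def pairs_to_reads(pairs: list[ReadPair]) -> list[tuple[str, str]]:
    """Both mates of every pair as separate (id, sequence) clustering units."""
    out = []
    for p in pairs:
        out.append((f"{p.rid}/1", p.seq1))
        out.append((f"{p.rid}/2", p.seq2))
    return out


@dataclass
class AnalysisResult:
    """Clustering + assembly + annotation over one read set."""

    result: ComparativeResult
    contigs: dict[int, list[Contig]] = field(default_factory=dict)

    @property
    def clusters(self) -> list[ReadCluster]:
        return self.result.clusters

    @property
    def total_reads(self) -> int:
        return len(self.result.reads)


def run_analysis(reads_by_species: dict[str, list[tuple[str, str]]],
                 library: Optional[RepeatLibrary] = None,
                 min_identity: float = 90.0, min_overlap: float = 0.55,
                 size_threshold: float = 0.0001, refine: bool = True,
                 cap_reads: int = 2000, seed: int = 0) -> AnalysisResult:
    """Cluster (pooled across species), assemble contigs, annotate."""
    res = comparative_cluster(
        reads_by_species, min_identity=min_identity, min_overlap=min_overlap,
        size_threshold=size_threshold, refine=refine, seed=seed)
    out = AnalysisResult(res)
    from .annotate import annotate_cluster

    for c in res.clusters:
        contigs = build_contigs(res.reads, c.member_reads, res.hits, cap_reads)
        c.contigs = [ct.sequence for ct in contigs]
        out.contigs[c.cluster_id] = contigs
        if library is not None:
            annotate_cluster(c, contigs, library)
    return out


def read_truth_families(genome: SimulatedGenome, pairs: list[ReadPair]
                        ) -> list[Optional[str]]:
    """Per clustering unit (two per pair, mates in order), the true source
    family of the fragment (None = single-copy or plastid)."""
    out = []
    for p in pairs:
        for origin in (p.origin1, p.origin2):
            out.append(genome.family_at(origin) if origin is not None else None)
    return out


def heterogeneity_families() -> list[RepeatFamilySpec]:
    """Four equally abundant families whose copy divergences span the range
    from recently amplified to strongly diverged."""
    fams = []
    for i, div in enumerate([0.01, 0.03, 0.05, 0.08]):
        fams.append(RepeatFamilySpec(
            f"Het{i}", ("Unknown",), 400, 4250, div))  # 17% each of 10 Mb
    return fams


def heterogeneity_genome(seed: int = 42) -> SimulatedGenome:
    return build_genome(GenomeSpec(
        "het", 10_000_000, heterogeneity_families(), seed=seed))


# ---------------------------------------------------------------------------
# recovery experiments (shared by the test suite and the acceptance script)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2**31)


def comparative_slope_experiment(base: SimulatedGenome, wgm: SimulatedGenome,
                                 library: RepeatLibrary, plastid: str,
                                 n_reps: int = 12, seed: int = 42) -> dict:
    """Replicated comparative analyses of the WGM pair under GS-proportional
    0.5% sampling; returns per-replicate origin-forced slopes.

    A single replicate's slope carries sampling noise of ~0.15 (about 630
    repeat read-units in the smaller sample), so the recovery estimate is
    the mean over replicates.
    """
    from .quantify import cluster_points, origin_regression

    slopes_all, slopes_classified, shared = [], [], []
    for rep in range(n_reps):
        pr_b = prepped_reads(base, plastid, seed=_sub_seed(seed, 2 * rep),
                             prefix=f"b{rep}")
        pr_w = prepped_reads(wgm, plastid, seed=_sub_seed(seed, 2 * rep + 1),
                             prefix=f"w{rep}")
        res = run_analysis(
            {"baseline": pairs_to_reads(pr_b), "wgm": pairs_to_reads(pr_w)},
            library=library, seed=0)
        pts_all = cluster_points(res.clusters, "baseline", "wgm", "All")
        pts_cls = cluster_points(res.clusters, "baseline", "wgm",
                                 "All classified")
        slopes_all.append(origin_regression(pts_all, "All", 2.0).slope)
        if len(pts_cls) >= 2:
            slopes_classified.append(
                origin_regression(pts_cls, "All classified", 2.0).slope)
        shared.append(len(pts_all))
    return {"slopes_all": slopes_all, "slopes_classified": slopes_classified,
            "shared_clusters": shared}


def proportion_recovery_experiment(wgm: SimulatedGenome,
                                   library: RepeatLibrary, plastid: str,
                                   n_reps: int = 4, seed: int = 42) -> dict:
    """Individual analysis of the WGM species at 0.5% coverage; returns per
    classified taxonomy the realized truth GP and the mean recovered GP."""
    from collections import defaultdict

    from .quantify import composition_table

    truth: dict[str, float] = defaultdict(float)
    for t in wgm.truth.families.values():
        if t.taxonomy_path != ("Unknown",):
            truth["/".join(t.taxonomy_path)] += t.proportion_pct
    recovered: dict[str, list[float]] = defaultdict(list)
    for rep in range(n_reps):
        pr = prepped_reads(wgm, plastid, seed=_sub_seed(seed, 100 + rep),
                           prefix=f"i{rep}")
        res = run_analysis({"wgm": pairs_to_reads(pr)}, library=library,
                           seed=0)
        df = composition_table(res.clusters, res.total_reads, len(wgm))
        gp = df.set_index("repeat_type")["gp_percent"]
        for path in truth:
            recovered[path].append(float(gp.get(path, 0.0)))
    return {path: {"truth_pct": truth[path],
                   "recovered_pct": sum(recovered[path]) / len(recovered[path])}
            for path in truth}


def heterogeneity_experiment(seed: int = 42) -> dict:
    """Single-species analysis of four equally abundant families with
    increasing copy divergence; returns the per-family profile summary."""
    from collections import Counter, defaultdict

    from .cluster import ReadCluster
    from .heterogeneity import heterogeneity_profile

    genome = heterogeneity_genome(seed)
    plastid = make_plastid(seed=seed)
    pr = prepped_reads(genome, plastid, seed=_sub_seed(seed, 200), prefix="h")
    fams = read_truth_families(genome, pr)
    res = run_analysis({"sp": pairs_to_reads(pr)}, seed=0)
    members_by_fam = defaultdict(list)
    for c in res.clusters:
        dom = Counter(fams[m] for m in c.member_reads).most_common(1)[0][0]
        if dom is not None:
            members_by_fam[dom].extend(c.member_reads)
    out = {}
    for fam_spec in heterogeneity_families():
        members = sorted(members_by_fam.get(fam_spec.name, []))
        pseudo = ReadCluster(cluster_id=1, member_reads=members,
                             species_counts={"sp": len(members)})
        prof = heterogeneity_profile(pseudo, "sp", res.result.hits,
                                     res.result.species)
        out[fam_spec.name] = {"divergence": fam_spec.divergence,
                              "n_pairs": prof.n_pairs,
                              "median_identity": prof.median_identity,
                              "conserved_fraction": prof.conserved_fraction}
    return out


def ltr_age_experiment(seed: int = 42, n: int = 100,
                       age_range: tuple[float, float] = (1.0, 17.0)) -> dict:
    """Detect and date n planted LTR elements with ages uniform on
    age_range; returns planted vs estimated age summaries."""
    import numpy as np

    from .ltrclock import (date_records, dedup_contigs, detect_ltr_pairs,
                           summarize_ages)

    rng = np.random.default_rng(_sub_seed(seed, 300))
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    contigs = simulate_ltr_pairs(ages, seed=_sub_seed(seed, 301))
    kept = dedup_contigs(contigs)
    records = []
    for cid, seq in kept:
        records.extend(detect_ltr_pairs(seq, contig_id=cid))
    dated, excluded = date_records(records)
    summary = summarize_ages(dated, species="synthetic")
    planted_median = float(np.median(ages))
    return {"n_planted": n, "n_dated": len(dated),
            "planted_median_mya": planted_median,
            "estimated_median_mya": summary.median_mya,
            "estimated_mean_mya": summary.mean_mya,
            "estimated_sd_mya": summary.sd_mya,
            "estimated_max_mya": summary.max_mya,
            "n_excluded_saturated": len(excluded)}
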