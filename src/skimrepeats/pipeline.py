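"""File-based pipeline orchestration: simulate -> prep -> cluster ->
quantify -> heterogeneity -> ltrdate.

Each stage reads its inputs from the output directory of the previous stage
and writes plain-text artifacts (FASTA/FASTQ/TSV/JSON, optional PNG), so any
stage can be rerun in isolation.  A manifest with SHA-256 checksums of every
output makes end-to-end determinism checkable: the same config and seed give
identical manifests.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .annotate import (LibraryEntry, RepeatLibrary, annotate_cluster,
                       detect_tandem_period, make_library)
from .assemble import build_contigs
from .cluster import ReadCluster, comparative_cluster
from .heterogeneity import (heterogeneity_profile, plot_profile,
                            profiles_table, select_top_clusters)
from .io_utils import (ensure_dir, read_fasta, read_fastq, sha256_file,
                       quals_to_string, write_fasta, write_fastq)
from .ltrclock import (date_records, dedup_contigs, detect_ltr_pairs,
                       plot_age_histogram, records_table, summarize_ages)
from .quantify import composition_table, gs_ratio, regression_table
from .readprep import (TrimSettings, filter_organelle, pairs_from_fastq,
                       prep_summary, trim_reads)
from .simulate import (DEFAULT_MU, GenomeSpec, RepeatFamilySpec, apply_wgm,
                       build_genome, make_plastid, sample_reads, write_genome,
                       write_reads)

log = logging.getLogger("skimrepeats")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpeciesConfig:
    name: str
    gs_bp: float  # 1C used for absolute amounts (may be the real Gbp scale)
    simulate: Optional[dict] = None  # GenomeSpec-like fields
    r1: Optional[str] = None
    r2: Optional[str] = None
    coverage: float = 0.005
    plastid_fraction: float = 0.02


@dataclass
class RunConfig:
    outdir: str
    seed: int = 42
    species: list[SpeciesConfig] = field(default_factory=list)
    # thresholds, all spec defaults
    trim: dict = field(default_factory=dict)
    organelle_k: int = 21
    organelle_threshold: float = 0.8
    min_identity: float = 90.0
    min_overlap: float = 0.55
    size_threshold: float = 0.0001
    refine: bool = True
    conductance_threshold: float = 0.01
    cap_reads: int = 2000
    min_hit_fraction: float = 0.1
    merge_similar_clusters: bool = False  # optional >=95% contig-identity merge
    het_n_types: int = 8
    het_per_type: int = 2
    ltr: dict = field(default_factory=dict)
    dedup: bool = True
    dedup_identity: float = 0.9
    mu: float = DEFAULT_MU
    plots: bool = False

    def validate(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError(f"min_identity={self.min_identity} outside (0, 100]")
        if not 0 < self.min_overlap <= 1:
            raise ValueError(f"min_overlap={self.min_overlap} outside (0, 1]")
        if not 0 <= self.size_threshold <= 1:
            raise ValueError("size_threshold outside [0, 1]")
        if not 0 < self.organelle_threshold <= 1:
            raise ValueError("organelle_threshold outside (0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if len(self.species) < 1:
            raise ValueError("at least one species required")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for s in self.species:
            if s.simulate is None and not (s.r1 and s.r2):
                raise ValueError(f"{s.name}: needs either simulate or r1/r2")


def load_config(path: str, outdir: Optional[str] = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    species = [SpeciesConfig(**sp) for sp in raw.pop("species", [])]
    cfg_outdir = raw.pop("outdir", "skimrepeats_out")
    cfg = RunConfig(outdir=outdir or cfg_outdir, species=species, **raw)
    cfg.validate()
    return cfg


def _family_from_dict(d: dict) -> RepeatFamilySpec:
    return RepeatFamilySpec(
        name=d["name"], taxonomy_path=tuple(d["taxonomy_path"]),
        consensus_length=int(d["consensus_length"]),
        copy_number=int(d["copy_number"]), divergence=float(d["divergence"]),
        is_tandem=bool(d.get("is_tandem", False)),
        ltr_length=d.get("ltr_length"),
        planted_age_mya=d.get("planted_age_mya"))


def _families_from_config(value: Any) -> list[RepeatFamilySpec]:
    if value == "study-default":
        from .scenarios import default_families

        return default_families()
    return [_family_from_dict(d) for d in value]


# ---------------------------------------------------------------------------
# library serialization (taxonomy kept in the FASTA header)


def write_library(library: RepeatLibrary, path: str) -> None:
    # ";" separates taxonomy levels: labels like Ty1/Copia contain "/"
    write_fasta(path, ((f"{';'.join(e.taxonomy_path)}|{e.kind}", e.sequence)
                       for e in library.entries))


def read_library(path: str) -> RepeatLibrary:
    entries = []
    for name, seq in read_fasta(path):
        tax, kind = name.rsplit("|", 1)
        entries.append(LibraryEntry(tuple(tax.split(";")), seq, kind))
    return RepeatLibrary(entries)


# ---------------------------------------------------------------------------
# stages


def _stage_seed(cfg: RunConfig, stage: str, index: int = 0) -> int:
    table = {"simulate": 1, "reads": 2, "cluster": 3}
    return (cfg.seed * 1000 + table.get(stage, 9) * 100 + index) % (2**31)


def stage_simulate(cfg: RunConfig) -> list[str]:
    outputs = []
    sim_dir = ensure_dir(os.path.join(cfg.outdir, "simulate"))
    plastid = make_plastid(seed=cfg.seed)
    plastid_path = os.path.join(sim_dir, "plastid.fasta")
    write_fasta(plastid_path, [("plastid_synthetic", plastid)])
    outputs.append(plastid_path)
    library_entries = []
    # one master seed for every species: families with the same name are
    # homologous (shared consensus), as in sister species
    sim_seed = _stage_seed(cfg, "simulate")
    for i, sp in enumerate(cfg.species):
        if sp.simulate is None:
            continue
        sim = dict(sp.simulate)
        families = _families_from_config(sim.pop("families"))
        spec = GenomeSpec(species_name=sp.name, families=families,
                          seed=sim_seed, mu=cfg.mu, **sim)
        genome = build_genome(spec)
        if spec.wgm_factor > 1 or spec.amplification_bursts:
            genome = apply_wgm(genome)
        fasta = os.path.join(sim_dir, f"{sp.name}.genome.fasta")
        truth = os.path.join(sim_dir, f"{sp.name}.truth.json")
        write_genome(genome, fasta, truth)
        n_pairs = round(sp.coverage * len(genome) / 200)
        pairs = sample_reads(genome, n_pairs=n_pairs, plastid_ref=plastid,
                             plastid_fraction=sp.plastid_fraction,
                             seed=_stage_seed(cfg, "reads", i),
                             prefix=f"{sp.name}")
        r1 = os.path.join(sim_dir, f"{sp.name}_R1.fastq.gz")
        r2 = os.path.join(sim_dir, f"{sp.name}_R2.fastq.gz")
        write_reads(pairs, r1, r2)
        outputs += [fasta, truth, r1, r2]
        for fam in families:
            if fam.taxonomy_path != ("Unknown",):
                library_entries.append(fam)
    if library_entries:
        library = make_library(
            [f for i, f in enumerate(library_entries)
             if f.name not in {g.name for g in library_entries[:i]}],
            sim_seed)
        lib_path = os.path.join(sim_dir, "library.fasta")
        write_library(library, lib_path)
        outputs.append(lib_path)
    return outputs


def stage_prep(cfg: RunConfig) -> list[str]:
    outputs = []
    sim_dir = os.path.join(cfg.outdir, "simulate")
    prep_dir = ensure_dir(os.path.join(cfg.outdir, "prep"))
    plastid_path = os.path.join(sim_dir, "plastid.fasta")
    plastid = next(read_fasta(plastid_path))[1] if os.path.exists(plastid_path) else None
    settings = TrimSettings(**cfg.trim)
    summary_rows = []
    for sp in cfg.species:
        r1 = sp.r1 or os.path.join(sim_dir, f"{sp.name}_R1.fastq.gz")
        r2 = sp.r2 or os.path.join(sim_dir, f"{sp.name}_R2.fastq.gz")
        pairs = pairs_from_fastq(read_fastq(r1), read_fastq(r2))
        n_input = len(pairs)
        trimmed = trim_reads(pairs, settings)
        if plastid is not None:
            nuclear, removed = filter_organelle(
                trimmed, plastid, k=cfg.organelle_k,
                containment_threshold=cfg.organelle_threshold)
        else:
            nuclear, removed = trimmed, 0
        out1 = os.path.join(prep_dir, f"{sp.name}_R1.fastq.gz")
        out2 = os.path.join(prep_dir, f"{sp.name}_R2.fastq.gz")
        write_fastq(out1, ((p.rid, p.seq1, quals_to_string(p.qual1))
                           for p in nuclear))
        write_fastq(out2, ((p.rid, p.seq2, quals_to_string(p.qual2))
                           for p in nuclear))
        outputs += [out1, out2]
        row = prep_summary(n_input, len(trimmed), removed)
        row["species"] = sp.name
        summary_rows.append(row)
        log.info("prep %s: %s", sp.name, row)
    summary = os.path.join(prep_dir, "prep_summary.tsv")
    _write_tsv(summary, summary_rows)
    outputs.append(summary)
    return outputs


def _write_tsv(path: str, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_units(cfg: RunConfig) -> dict[str, list[tuple[str, str]]]:
    prep_dir = os.path.join(cfg.outdir, "prep")
    units: dict[str, list[tuple[str, str]]] = {}
    for sp in cfg.species:
        recs = []
        for mate in (1, 2):
            path = os.path.join(prep_dir, f"{sp.name}_R{mate}.fastq.gz")
            for rid, seq, _ in read_fastq(path):
                recs.append((f"{rid}/{mate}", seq))
        units[sp.name] = sorted(recs)
    return units


def _merge_similar(clusters: list[ReadCluster], contigs_by_cluster: dict,
                   identity_threshold: float = 0.95) -> list[ReadCluster]:
    """Optional merge of clusters whose longest contigs align at >=95%
    identity (automatic stand-in for manual cluster revision); default off."""
    from .cluster import align_identity

    merged: list[ReadCluster] = []
    for c in sorted(clusters, key=lambda c: -c.size):
        target = None
        best = max(contigs_by_cluster.get(c.cluster_id, []), key=len,
                   default=None)
        if best is not None:
            for m in merged:
                mbest = max(contigs_by_cluster.get(m.cluster_id, []), key=len,
                            default=None)
                if mbest is None:
                    continue
                ident, _ = align_identity(best.sequence, mbest.sequence)
                if ident >= 100 * identity_threshold:
                    target = m
                    break
        if target is None:
            merged.append(c)
        else:
            target.member_reads = sorted(target.member_reads + c.member_reads)
            for sp, n in c.species_counts.items():
                target.species_counts[sp] = target.species_counts.get(sp, 0) + n
    for i, c in enumerate(sorted(merged, key=lambda c: (-c.size, c.cluster_id)),
                          start=1):
        c.cluster_id = i
    return sorted(merged, key=lambda c: c.cluster_id)


def stage_cluster(cfg: RunConfig) -> list[str]:
    outputs = []
    cl_dir = ensure_dir(os.path.join(cfg.outdir, "cluster"))
    units = _load_units(cfg)
    res = comparative_cluster(
        units, min_identity=cfg.min_identity, min_overlap=cfg.min_overlap,
        size_threshold=cfg.size_threshold, refine=cfg.refine,
        conductance_threshold=cfg.conductance_threshold,
        seed=_stage_seed(cfg, "cluster"))
    lib_path = os.path.join(cfg.outdir, "simulate", "library.fasta")
    library = read_library(lib_path) if os.path.exists(lib_path) else RepeatLibrary([])
    contigs_by_cluster = {}
    for c in res.clusters:
        contigs = build_contigs(res.reads, c.member_reads, res.hits,
                                cfg.cap_reads)
        contigs_by_cluster[c.cluster_id] = contigs
        c.contigs = [ct.sequence for ct in contigs]
        annotate_cluster(c, contigs, library, cfg.min_hit_fraction)
    if cfg.merge_similar_clusters:
        res.clusters[:] = _merge_similar(res.clusters, contigs_by_cluster)
    # cluster table
    rows = []
    for c in res.clusters:
        row = {"cluster_id": c.cluster_id, "size": c.size,
               "annotation": ";".join(c.annotation or ("Unclassified",)),
               "size_class": c.size_class}
        for sp in units:
            row[f"reads_{sp}"] = c.species_counts.get(sp, 0)
        rows.append(row)
    cluster_tsv = os.path.join(cl_dir, "clusters.tsv")
    _write_tsv(cluster_tsv, rows)
    # membership, hits, contigs
    member_tsv = os.path.join(cl_dir, "members.tsv")
    _write_tsv(member_tsv, [
        {"unit_index": m, "unit_id": res.read_ids[m],
         "species": res.species[m], "cluster_id": c.cluster_id}
        for c in res.clusters for m in c.member_reads])
    hits_tsv = os.path.join(cl_dir, "hits.tsv")
    _write_tsv(hits_tsv, [
        {"read_a": h.read_a, "read_b": h.read_b,
         "identity": round(h.identity, 4),
         "overlap_fraction": round(h.overlap_fraction, 4),
         "strand": h.strand, "offset": h.offset} for h in res.hits])
    contig_fasta = os.path.join(cl_dir, "contigs.fasta")
    write_fasta(contig_fasta, (
        (f"CL{c.cluster_id}_contig{i}", ct.sequence)
        for c in res.clusters
        for i, ct in enumerate(contigs_by_cluster.get(c.cluster_id, []))))
    units_tsv = os.path.join(cl_dir, "units.tsv")
    _write_tsv(units_tsv, [
        {"unit_index": i, "unit_id": res.read_ids[i], "species": res.species[i]}
        for i in range(len(res.reads))])
    outputs += [cluster_tsv, member_tsv, hits_tsv, contig_fasta, units_tsv]
    log.info("cluster: %d clusters, %d single/low-copy reads",
             len(res.clusters), len(res.singles))
    return outputs


def _read_clusters(cfg: RunConfig):
    import pandas as pd

    cl_dir = os.path.join(cfg.outdir, "cluster")
    cdf = pd.read_csv(os.path.join(cl_dir, "clusters.tsv"), sep="\t")
    mdf = pd.read_csv(os.path.join(cl_dir, "members.tsv"), sep="\t")
    udf = pd.read_csv(os.path.join(cl_dir, "units.tsv"), sep="\t")
    clusters = []
    members = mdf.groupby("cluster_id")["unit_index"].apply(list)
    for _, row in cdf.iterrows():
        c = ReadCluster(
            cluster_id=int(row.cluster_id),
            member_reads=sorted(members.get(row.cluster_id, [])),
            species_counts={sp.name: int(row[f"reads_{sp.name}"])
                            for sp in cfg.species},
            annotation=tuple(str(row.annotation).split(";")),
            size_class=row.size_class)
        clusters.append(c)
    return clusters, udf


def stage_quantify(cfg: RunConfig) -> list[str]:
    outputs = []
    qdir = ensure_dir(os.path.join(cfg.outdir, "quantify"))
    clusters, udf = _read_clusters(cfg)
    totals = udf.groupby("species")["unit_index"].count().to_dict()
    for sp in cfg.species:
        df = composition_table(clusters, int(totals.get(sp.name, 0)),
                               sp.gs_bp, species=sp.name)
        path = os.path.join(qdir, f"composition_{sp.name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    if len(cfg.species) >= 2:
        ordered = sorted(cfg.species, key=lambda s: s.gs_bp)
        small, large = ordered[0], ordered[-1]
        expected = gs_ratio(large.gs_bp, small.gs_bp)
        reg = regression_table(clusters, small.name, large.name, expected)
        reg_path = os.path.join(qdir, "regression.tsv")
        reg.to_csv(reg_path, sep="\t", index=False)
        scatter = os.path.join(qdir, "scatter.tsv")
        _write_tsv(scatter, [
            {"cluster_id": c.cluster_id,
             f"reads_{small.name}": c.species_counts.get(small.name, 0),
             f"reads_{large.name}": c.species_counts.get(large.name, 0),
             "annotation": ";".join(c.annotation or ("Unclassified",))}
            for c in clusters])
        outputs += [reg_path, scatter]
        if cfg.plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            xs = [c.species_counts.get(small.name, 0) for c in clusters]
            ys = [c.species_counts.get(large.name, 0) for c in clusters]
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(xs, ys, s=12)
            lim = max(max(xs, default=1), 1)
            ax.plot([0, lim], [0, expected * lim], "k--",
                    label=f"GS ratio {expected:.2f}")
            ax.set_xlabel(f"reads {small.name}")
            ax.set_ylabel(f"reads {large.name}")
            ax.legend()
            fig.tight_layout()
            png = os.path.join(qdir, "scatter.png")
            fig.savefig(png, dpi=100)
            plt.close(fig)
            outputs.append(png)
    return outputs


def stage_heterogeneity(cfg: RunConfig) -> list[str]:
    import pandas as pd

    outputs = []
    hdir = ensure_dir(os.path.join(cfg.outdir, "heterogeneity"))
    clusters, udf = _read_clusters(cfg)
    hits_df = pd.read_csv(os.path.join(cfg.outdir, "cluster", "hits.tsv"),
                          sep="\t")
    from .cluster import SimilarityHit

    hits = [SimilarityHit(int(r.read_a), int(r.read_b), float(r.identity),
                          float(r.overlap_fraction), r.strand, int(r.offset))
            for r in hits_df.itertuples()]
    species_of = udf.set_index("unit_index")["species"].to_dict()
    species_list = [species_of[i] for i in range(len(species_of))]
    selected = select_top_clusters(clusters, cfg.het_n_types, cfg.het_per_type)
    profiles = []
    for c in selected:
        for sp in cfg.species:
            prof = heterogeneity_profile(c, sp.name, hits, species_list)
            profiles.append(prof)
            if cfg.plots and prof.n_pairs > 0:
                png = os.path.join(hdir, f"CL{c.cluster_id}_{sp.name}.png")
                plot_profile(prof, png)
                outputs.append(png)
    table = os.path.join(hdir, "profiles.tsv")
    profiles_table(profiles).to_csv(table, sep="\t", index=False)
    outputs.append(table)
    return outputs


def stage_ltrdate(cfg: RunConfig) -> list[str]:
    outputs = []
    ldir = ensure_dir(os.path.join(cfg.outdir, "ltrdate"))
    contigs = [(name, seq) for name, seq in
               read_fasta(os.path.join(cfg.outdir, "cluster", "contigs.fasta"))]
    # skip tandem-periodic contigs: satellite self-similarity is not an LTR
    contigs = [(n, s) for n, s in contigs if detect_tandem_period(s) is None]
    if cfg.dedup:
        contigs = dedup_contigs(contigs, cfg.dedup_identity)
    import pandas as pd

    cdf = pd.read_csv(os.path.join(cfg.outdir, "cluster", "clusters.tsv"),
                      sep="\t")
    ann_of = {int(r.cluster_id): tuple(str(r.annotation).split(";"))
              for r in cdf.itertuples()}
    records = []
    ltr_params = dict(cfg.ltr)
    for name, seq in contigs:
        recs = detect_ltr_pairs(seq, contig_id=name, **ltr_params)
        cl = int(name.split("_")[0][2:]) if name.startswith("CL") else None
        for r in recs:
            r.annotation = ann_of.get(cl)
        records.extend(recs)
    dated, excluded = date_records(records, cfg.mu)
    rec_path = os.path.join(ldir, "ltr_pairs.tsv")
    records_table(dated).to_csv(rec_path, sep="\t", index=False)
    outputs.append(rec_path)
    rows = []
    for subset in ("all", "Ty1/Copia", "Ty3/Gypsy"):
        s = summarize_ages(dated, species="pooled", subset=subset,
                           dedup=cfg.dedup)
        rows.append(vars(s))
    summary = os.path.join(ldir, "age_summary.tsv")
    _write_tsv(summary, rows)
    outputs.append(summary)
    if excluded:
        excl = os.path.join(ldir, "excluded.txt")
        with open(excl, "w") as fh:
            fh.write("\n".join(excluded) + "\n")
        outputs.append(excl)
    if cfg.plots and dated:
        png = os.path.join(ldir, "age_histogram.png")
        plot_age_histogram(dated, png, "pooled")
        outputs.append(png)
    return outputs


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "cluster": stage_cluster,
    "quantify": stage_quantify,
    "heterogeneity": stage_heterogeneity,
    "ltrdate": stage_ltrdate,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in order; return (and write) the output manifest."""
    cfg.validate()
    ensure_dir(cfg.outdir)
    logging.basicConfig(level=logging.INFO)
    log.info("skimrepeats %s seed=%d thresholds: identity=%.1f overlap=%.2f "
             "size=%.4g mu=%.3g", __version__, cfg.seed, cfg.min_identity,
             cfg.min_overlap, cfg.size_threshold, cfg.mu)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    for name, fn in STAGES.items():
        if name == "simulate" and not any(s.simulate for s in cfg.species):
            continue
        try:
            files = fn(cfg)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest["stages"][name] = {
            os.path.relpath(f, cfg.outdir): sha256_file(f) for f in files}
    path = os.path.join(cfg.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
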