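# Methods

`skimrepeats` reimplements, as a self-contained and testable pipeline, the
repeat-landscape analysis used to characterize giant plant genomes from
genome-skimming data: graph-based clustering of low-coverage reads,
quantification of repeats as genomic proportions, a two-species comparison
against the genome-size ratio, intra-family heterogeneity profiling, and
LTR insertion-time dating. This note records the models, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the workflow left choices open.

## The analysis model

**Genomic proportion.** At coverage far below 1x, shotgun reads sample the
genome almost uniformly, so the fraction of analyzed reads that join a
repeat cluster estimates the fraction of the genome occupied by that
repeat (its genomic proportion, GP). Absolute amounts are GP x 1C, using
each species' own genome size; coverage bookkeeping uses single-read
accounting at the analyzed read length (n_reads x 100 nt / 1C).

**Similarity graph.** Two reads are connected when they align at >= 90%
identity over >= 55% of the read length, on either strand. Candidate pairs
are found by shared canonical k-mers with k = 8 and verified on the implied
diagonal. The seed size is not a tunable: for a gap-free hit with c aligned
columns and m <= floor(0.1 c) mismatches, some exact run has length
>= ceil((c - m)/(m + 1)), whose minimum over c >= 55 is 8 — so the
prefilter provably never misses a qualifying hit. Verification is gap-free
by default (the substitution-only read model makes gaps spurious); a
`band` parameter switches to banded edlib alignment for indel-bearing
inputs. Clusters are connected components, optionally refined by Louvain
community splitting with a conductance gate (default 0.01): a proposed
split survives only if the cut joining the parts has conductance at or
below the gate, which separates chimeric components bridged by isolated
spurious edges from densely tiled families. Reads with no hits at all form
the single/low-copy bucket; clusters below 0.01% of the analyzed reads are
pooled as small unclassified clusters.

**Assembly and annotation.** Per-cluster contigs come from a greedy
overlap-layout-consensus over the verified hits (strand and diagonal are
already known, so no re-alignment is needed; the consensus is the column
majority). Contigs are searched against a miniature reference library:
protein-domain entries by six-frame translated local alignment (BLOSUM62,
stops masked to X), tandem entries (satellite monomers, rDNA units) by
alignment against a head-to-tail extension of the monomer so any phase and
rotation can match. A cluster takes the taxonomy path with the greatest
summed hit score, provided hit-bearing contigs cover >= 10% of its reads;
ties break by score, then total hit span, then lexicographic path. With no
library hit, a tandem-periodicity detector (self-identity >= 0.8 at some
shift of 10-500 nt, two full copies required) may still call Satellite;
otherwise the cluster is Unclassified.

**Two-species comparison.** The species are sampled GS-proportionally and
clustered together. For shared clusters, the read count of the larger
genome is regressed on the smaller through the origin: slope = Sxy/Sx^2,
uncentered R^2 = 1 - RSS/Sy^2 (the no-intercept convention), p-value from
the slope's t statistic on n-1 df. If the larger genome arose by a
whole-genome multiplication that amplified everything uniformly, the slope
equals the genome-size ratio; subsets (Ty1/Copia, Ty3/Gypsy, all, all
classified) are fitted separately.

**Heterogeneity.** For selected clusters (the two largest of each of the
eight most abundant repeat types; satellites per species), the stored
pairwise identities of same-species read pairs are summarized as a 1%-bin
histogram over [90, 100], a median at 0.1% resolution, and the fraction of
pairs at >= 94% identity. Identities below the 90%/55% rule are absent by
construction, so the profiles describe the visible (clusterable) part of a
family; recently amplified families pile up near 100%, anciently diverged
ones skew toward the 90% edge. Reciprocal pairs are counted once.

**LTR dating.** The two long terminal repeats of an element are identical
at insertion and diverge neutrally afterwards. Pairs of similar direct
repeats are harvested from contigs by exact-seed diagonal voting (k = 13,
>= 3 seeds; hyper-repetitive seeds and tandem-periodic contigs are
skipped), the seed-anchored span is extended outward while 10-nt windows
on the diagonal stay >= 60% identical (otherwise the diverged LTR ends
would be truncated and the distance biased low), candidates are kept at
100-2000 nt length, 1-15 kb spacing and >= 80% identity, and overlaps
resolve to the highest-identity, longest pair. The two LTRs are globally
aligned (match 2, mismatch -1, gap open -10, extend -0.5); gap and
ambiguous columns are excluded; the Kimura two-parameter distance is
K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P and Q the transition and
transversion fractions, and the insertion age is T = K / (2 mu) with
mu = 4.79e-9 substitutions per site per year (a fern-calibrated rate).
Saturated pairs (non-positive log argument) are excluded with a logged
reason. A CD-HIT-style greedy longest-first deduplication (drop at >= 90%
global identity to a retained representative) can precede dating; both
paths are supported because they should agree on clean data, and a test
asserts they do.

## The synthetic-data generator

The generator plants known truth so every downstream stage can be scored.
Family consensi are uniform random DNA (frame-0 stop codons resampled so
translated search behaves); copies evolve from the consensus along a
Kimura two-parameter substitution process with a 2:1
transition:transversion ratio, using the exact closed-form site
probabilities — so the K2P estimator is exercised on both P and Q and
multiple hits are really corrected, not just simulated as flip counts.
Satellites and rDNA are emitted as head-to-tail arrays (~200 monomers per
array); LTR families as LTR-internal-LTR with each terminal repeat evolved
independently along a branch of mu x T years, giving the planted pair an
expected divergence of 2 mu T. A whole-genome multiplication concatenates
the genome wgm_factor times (truth proportions are invariant under uniform
doubling); amplification bursts then add extra low-divergence copies,
which raises a family's proportion and lowers its mean pairwise
divergence. Every pair of repeat blocks is separated by a unique-sequence
spacer: without spacers, reads spanning a repeat-repeat junction recur at
every copy of that junction type and create spurious cross-family edges
(an artifact of densely packed short blocks, discovered and eliminated
during development). The truth table records *realized* proportions and a
brute-force mean pairwise copy divergence measured on up to 30 realized
copies.

Reads are 150 nt pairs from uniform positions on both strands with a
350-500 bp insert, per-base substitution errors at 0.1%, constant Q35
qualities with a 2% fraction of degraded (Q10) 3' tails to exercise
trimming, and a configurable plastid-contamination fraction (default 2%)
drawn from a synthetic plastid reference. With a fixed seed all FASTA and
FASTQ output is byte-identical (gzip members carry no name or timestamp).

Indels are not simulated by default: the dating formula is
substitution-only, and the gap-free hit verification assumes it. An indel
robustness path exists via the `band` alignment parameter.

## Desk-scale study conditions

The canonical synthetic conditions mirror the real study's structure at
desk scale: a 20 Mb tetraploid-like baseline and its 40 Mb WGM double
(sister species sharing all family consensi), sampled at 0.5% analyzed
coverage (1,000 and 2,000 analyzed 100-nt reads), trimmed with
AVGQUAL:20 MINLEN:100 LEADING:20 TRAILING:20 SLIDINGWINDOW:4:20 and
cropped to 100 nt, plastid-filtered by 21-mer containment at 0.8. The real
genomes' giga-base scale enters only as 1C metadata when proportions are
converted to absolute amounts.

Two desk-scale constraints shaped the family table:

* **Tiling depth.** Graph clustering needs reads to tile each family's
  consensus densely enough to stay connected (the full-scale analysis gets
  this from millions of reads). Consensus lengths are therefore chosen so
  per-family depth is roughly 8x or more at 0.5% coverage (dispersed TEs
  400-1000 nt, satellites 170/340 nt monomers).
* **Regression attenuation.** The origin-forced slope Sxy/Sx^2 is
  attenuated by count noise in x (classical errors-in-variables); with
  ~750 repeat read-units in the smaller sample the attenuation is a few
  percent unless Sx^2 is concentrated in large clusters. The table is
  therefore satellite-heavy (25% + 8%), with total repeats 79.8% and
  single copy 20.2% — close to the published landscape of the larger
  species (77.3/22.7). Slope recovery is reported as the mean over 12
  read-sampling replicates because a single replicate's slope carries
  ~0.10 sampling noise at these read counts.

Thirteen classified families (two satellites; Athila, Tekay, Reina within
Ty3/Gypsy; Ivana, Tork, Ale, SIRE within Ty1/Copia; a LINE; hAT and
EnSpm-CACTA TIR transposons; rDNA) carry 1-8% each with copy divergences
0.01-0.05 and planted LTR ages 2-9 Mya; twenty-four library-absent "dark"
families at 0.7% each (divergence 0.03-0.06) emulate the unannotatable
dark-matter fraction. Heterogeneity ordering uses a separate 10 Mb genome
with four equal families at divergences 0.01/0.03/0.05/0.08; LTR-age
recovery uses 100 standalone elements (300 nt LTRs, 2 kb internal) with
ages uniform on 1-17 Mya.

What passing these tests shows — and does not. The generator emulates the
statistical structure the method relies on (uniform sampling, family-wise
divergence, tandem arrays, LTR pair divergence, WGM doubling), not real
genomes: there are no nested or truncated insertions, no solo LTRs, no GC
or coverage bias, no chromosome structure, and library entries derive from
the same consensi as the planted repeats (annotation is easier than
against a real, diverged reference database). Recovery under these
conditions validates the machinery, not the biology of any particular
genome.

## Numerical and procedural choices

* Trimming applies LEADING, TRAILING, SLIDINGWINDOW, MINLEN, CROP-to-100,
  then TRAILING and AVGQUAL again on the final cropped read. Re-checking
  after the crop makes trimming idempotent (a crop can expose a low-quality
  3' base or shift the mean); survivors are exactly 100 nt. A pair survives
  only if both mates survive, and an organelle match on either mate removes
  the pair.
* Cluster ids are ordinal by decreasing size with ties broken by smallest
  member index; annotation ties break deterministically (score, span,
  lexicographic path); consensus ties take the alphabetically first base;
  Louvain refinement is seeded.
* The comparative regression uses raw read counts (sampling is already
  GS-proportional), and absolute amounts always use each species' own 1C —
  the published table's printed absolute column mixes the two species'
  genome sizes and is not reproduced.
* K2P saturation (1 - 2P - Q <= 0 or 1 - 2Q <= 0) excludes a pair rather
  than producing a NaN age; empty summaries are explicit (n = 0, no silent
  zeros).
* Cluster merging at >= 95% contig identity (an automatic stand-in for
  manual cluster revision at a 5% similarity threshold) is available behind
  `merge_similar_clusters`, default off, because the manual step it mimics
  is not mechanically reproducible.
* The pipeline derives per-stage seeds from the run seed; identical
  configs and seeds give identical manifests (SHA-256 over every output).

## Known limitations

* At 0.5% coverage, dispersed families fragment into positional
  subclusters in single-species analyses (real pipelines show the same
  per-domain splitting); proportions are robust to this because fragments
  still annotate, but per-cluster statistics refer to fragments, not whole
  families.
* Contigs from low-coverage clusters rarely span a full LTR element, so
  in-pipeline dating from cluster contigs is sparse at desk scale; the
  age-recovery experiment therefore dates planted full-length elements
  directly, standing in for the contigs a deep individual analysis yields.
* The heterogeneity profile is truncated at the 90% hit threshold, so for
  strongly diverged families (divergence >= ~0.07) it describes only the
  conserved tail of the pairwise-identity distribution.
* The tandem detector reports the smallest adequate period; satellites
  whose monomers exceed 500 nt would need the bound raised.
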