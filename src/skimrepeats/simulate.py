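"""Synthetic two-species genome and read simulator.

Generates desk-scale genomes with planted repeat families (dispersed TEs,
tandem satellites/rDNA, LTR retroelements whose two terminal repeats diverge
as 2*mu*T for a planted age T), an optional whole-genome multiplication (WGM)
with post-WGM amplification bursts, and paired-end reads with per-base
qualities and plastid contamination.  A machine-readable truth table records
the *realized* composition so that downstream recovery can be scored.

Substitutions follow a Kimura two-parameter process with a configurable
transition:transversion ratio (default 2:1); indels are off by default since
the dating formula is substitution-only.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_utils import quals_to_string, revcomp, write_fasta, write_fastq

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (A<->G, C<->T) in 0..3 coding
_TS_PARTNER = np.array([2, 3, 0, 1])
_STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MU = 4.79e-9  # substitutions / site / year, fern-calibrated rate


# ---------------------------------------------------------------------------
# specs


@dataclass
class RepeatFamilySpec:
    """One planted repeat family.

    divergence is the expected number of substitutions per site separating
    each copy from the family consensus (branch length of the copy).
    """

    name: str
    taxonomy_path: tuple[str, ...]
    consensus_length: int
    copy_number: int
    divergence: float
    is_tandem: bool = False
    ltr_length: Optional[int] = None
    planted_age_mya: Optional[float] = None

    def __post_init__(self):
        self.taxonomy_path = tuple(self.taxonomy_path)
        if self.copy_number < 0:
            raise ValueError(f"{self.name}: copy_number must be >= 0")
        if not 0 <= self.divergence <= 0.25:
            raise ValueError(f"{self.name}: divergence must be in [0, 0.25]")
        if self.planted_age_mya is not None:
            if not self.ltr_length or self.ltr_length <= 0:
                raise ValueError(
                    f"{self.name}: planted_age_mya requires ltr_length > 0"
                )
        if self.ltr_length is not None and 2 * self.ltr_length >= self.consensus_length:
            raise ValueError(f"{self.name}: two LTRs exceed consensus_length")

    @property
    def total_bases(self) -> int:
        return self.consensus_length * self.copy_number


@dataclass
class GenomeSpec:
    species_name: str
    gs_bp: int
    families: list[RepeatFamilySpec]
    single_copy_fraction: Optional[float] = None
    wgm_factor: int = 1
    amplification_bursts: list[tuple[str, int, float]] = field(default_factory=list)
    mu: float = DEFAULT_MU
    ts_tv: float = 2.0
    seed: int = 42

    def __post_init__(self):
        if self.wgm_factor < 1:
            raise ValueError("wgm_factor must be >= 1")
        repeat_bases = sum(f.total_bases for f in self.families)
        if repeat_bases > self.gs_bp:
            raise ValueError(
                f"requested repeat content ({repeat_bases} bp) exceeds gs_bp "
                f"({self.gs_bp} bp)"
            )
        names = {f.name for f in self.families}
        for fam, _, _ in self.amplification_bursts:
            if fam not in names:
                raise ValueError(f"burst names unknown family {fam!r}")


@dataclass
class FamilyTruth:
    proportion_pct: float
    n_copies: int
    total_bases: int
    divergence: float  # planted branch length copy->consensus
    mean_pairwise_divergence: float  # measured on sampled realized copies
    ltr_ages_mya: list[float] = field(default_factory=list)
    taxonomy_path: tuple[str, ...] = ()


@dataclass
class TruthTable:
    species_name: str
    gs_bp: int
    families: dict[str, FamilyTruth]
    single_copy_pct: float
    plastid_fraction: float = 0.0

    def check(self) -> None:
        total = self.single_copy_pct + sum(
            t.proportion_pct for t in self.families.values()
        )
        if abs(total - 100.0) > 0.01:
            raise AssertionError(f"truth proportions sum to {total}, not 100")

    def to_json(self) -> str:
        d = {
            "species_name": self.species_name,
            "gs_bp": self.gs_bp,
            "single_copy_pct": self.single_copy_pct,
            "plastid_fraction": self.plastid_fraction,
            "families": {
                name: {
                    "proportion_pct": t.proportion_pct,
                    "n_copies": t.n_copies,
                    "total_bases": t.total_bases,
                    "divergence": t.divergence,
                    "mean_pairwise_divergence": t.mean_pairwise_divergence,
                    "ltr_ages_mya": t.ltr_ages_mya,
                    "taxonomy_path": list(t.taxonomy_path),
                }
                for name, t in self.families.items()
            },
        }
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimulatedGenome:
    """A realized genome: sequence plus bookkeeping for truth recomputation."""

    spec: GenomeSpec
    sequence: str
    truth: TruthTable
    # half-open spans of full LTR elements on the genome, per family
    element_spans: dict[str, list[tuple[int, int]]]
    # realized copies per family (strings), used for truth recomputation
    copies: dict[str, list[str]]
    # placed spans of every repeat block (copy or tandem array), per family
    block_spans: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def family_at(self, pos: int) -> Optional[str]:
        """Family owning genome position pos, or None for single-copy DNA."""
        if not hasattr(self, "_block_index") or self._block_index is None:
            spans = sorted((s, e, fam) for fam, lst in self.block_spans.items()
                           for s, e in lst)
            self._block_index = spans
            self._block_starts = [s for s, _, _ in spans]
        import bisect

        i = bisect.bisect_right(self._block_starts, pos) - 1
        if i >= 0:
            s, e, fam = self._block_index[i]
            if s <= pos < e:
                return fam
        return None


# ---------------------------------------------------------------------------
# K2P substitution machinery


def k2p_probabilities(branch: float, ts_tv: float = 2.0) -> tuple[float, float, float]:
    """Closed-form K2P site probabilities after `branch` expected subs/site.

    Returns (p_same, p_transition, p_each_transversion); the two transversion
    targets are equiprobable.  ts_tv is the ratio of transitions to *total*
    transversions.
    """
    if branch < 0:
        raise ValueError("branch length must be >= 0")
    # rates: alpha (ts), beta (each of 2 tv); alpha + 2 beta = 1 after scaling
    beta = 1.0 / (2.0 * ts_tv + 2.0)
    alpha = 2.0 * ts_tv * beta
    t = branch
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_same, p_ts, p_tv


def mutate(seq: np.ndarray, branch: float, rng: np.random.Generator,
           ts_tv: float = 2.0) -> np.ndarray:
    """Evolve a 0..3-coded sequence along a K2P branch (substitutions only)."""
    if branch == 0:
        return seq.copy()
    p_same, p_ts, p_tv = k2p_probabilities(branch, ts_tv)
    u = rng.random(seq.size)
    out = seq.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    out[ts_mask] = _TS_PARTNER[seq[ts_mask]]
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    # transversion targets: the two bases of the other purine/pyrimidine class
    tv_targets = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
    out[tv1] = tv_targets[seq[tv1], 0]
    out[tv2] = tv_targets[seq[tv2], 1]
    return out


def _decode(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _orf_clean(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Remove frame-0 stop codons by resampling (keeps translated search sane)."""
    arr = arr.copy()
    for i in range(0, len(arr) - 2, 3):
        while _decode(arr[i : i + 3]) in _STOP_CODONS:
            arr[i : i + 3] = rng.integers(0, 4, size=3, dtype=np.uint8)
    return arr


def family_consensus(spec: RepeatFamilySpec, master_seed: int) -> np.ndarray:
    """Deterministic consensus per (seed, family name); shared with the
    annotation-library builder so library entries match planted repeats."""
    name_key = int.from_bytes(hashlib.md5(spec.name.encode()).digest()[:4], "big")
    key = np.random.SeedSequence([master_seed, name_key % (2**31)])
    rng = np.random.default_rng(key)
    cons = random_sequence(spec.consensus_length, rng)
    return _orf_clean(cons, rng)


def domain_region(spec: RepeatFamilySpec, domain_len: int = 900) -> tuple[int, int]:
    """Span of the protein-domain segment inside the consensus (internal,
    i.e. between the LTRs when the family has them)."""
    lo = spec.ltr_length or 0
    hi = spec.consensus_length - lo
    length = min(domain_len, ((hi - lo) // 3) * 3)
    start = lo + ((hi - lo - length) // 2 // 3) * 3
    return start, start + length


# ---------------------------------------------------------------------------
# genome construction


def _realize_family(spec: RepeatFamilySpec, cons: np.ndarray, genome_spec: GenomeSpec,
                    rng: np.random.Generator, n_copies: Optional[int] = None,
                    divergence: Optional[float] = None,
                    age_mya: Optional[float] = None):
    """Return (blocks, copies, ltr_spans_within_block) for one family.

    blocks are (array, family_name, element_spans) where element_spans are
    LTR-element spans local to the block.
    """
    n = spec.copy_number if n_copies is None else n_copies
    d = spec.divergence if divergence is None else divergence
    age = spec.planted_age_mya if age_mya is None else age_mya
    ts_tv = genome_spec.ts_tv
    blocks: list[tuple[np.ndarray, str, list[tuple[int, int]]]] = []
    copies: list[np.ndarray] = []
    if n == 0:
        return blocks, copies
    if spec.is_tandem:
        # head-to-tail arrays of ~200 monomers
        per_array = 200
        i = 0
        while i < n:
            m = min(per_array, n - i)
            arr_copies = [mutate(cons, d, rng, ts_tv) for _ in range(m)]
            copies.extend(arr_copies)
            blocks.append((np.concatenate(arr_copies), spec.name, []))
            i += m
        return blocks, copies
    ltr = spec.ltr_length
    for _ in range(n):
        copy = mutate(cons, d, rng, ts_tv)
        spans: list[tuple[int, int]] = []
        if ltr and age is not None:
            branch = genome_spec.mu * age * 1e6
            copy[:ltr] = mutate(copy[:ltr], branch, rng, ts_tv)
            copy[-ltr:] = mutate(copy[-ltr:], branch, rng, ts_tv)
            spans.append((0, len(copy)))
        copies.append(copy)
        blocks.append((copy, spec.name, spans))
    return blocks, copies


def measure_pairwise_divergence(copies: Sequence[np.ndarray | str],
                                max_copies: int = 30,
                                rng: Optional[np.random.Generator] = None) -> float:
    """Mean raw mismatch fraction over all pairs of (<= max_copies sampled)
    equal-length realized copies; the brute-force truth oracle."""
    if len(copies) < 2:
        return 0.0
    arrs = [c if isinstance(c, np.ndarray) else _encode(c) for c in copies]
    if len(arrs) > max_copies:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(arrs), size=max_copies, replace=False)
        arrs = [arrs[i] for i in sorted(idx)]
    stack = np.stack(arrs)
    n = stack.shape[0]
    total, pairs = 0.0, 0
    for i in range(n - 1):
        diff = (stack[i + 1 :] != stack[i]).mean(axis=1)
        total += diff.sum()
        pairs += diff.size
    return total / pairs


def _build_truth(spec: GenomeSpec, copies: dict[str, list[np.ndarray]],
                 element_ages: dict[str, list[float]], genome_len: int) -> TruthTable:
    fams: dict[str, FamilyTruth] = {}
    fam_specs = {f.name: f for f in spec.families}
    repeat_bases = 0
    for name, fam_copies in copies.items():
        total = int(sum(len(c) for c in fam_copies))
        repeat_bases += total
        fams[name] = FamilyTruth(
            proportion_pct=100.0 * total / genome_len,
            n_copies=len(fam_copies),
            total_bases=total,
            divergence=fam_specs[name].divergence,
            mean_pairwise_divergence=measure_pairwise_divergence(fam_copies),
            ltr_ages_mya=element_ages.get(name, []),
            taxonomy_path=fam_specs[name].taxonomy_path,
        )
    truth = TruthTable(
        species_name=spec.species_name,
        gs_bp=genome_len,
        families=fams,
        single_copy_pct=100.0 * (genome_len - repeat_bases) / genome_len,
    )
    truth.check()
    return truth


def build_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Realize a genome from its spec (WGM applied separately by apply_wgm)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    blocks: list[tuple[np.ndarray, Optional[str], list[tuple[int, int]]]] = []
    copies: dict[str, list[np.ndarray]] = {}
    element_ages: dict[str, list[float]] = {}
    for fam in spec.families:
        cons = family_consensus(fam, spec.seed)
        fam_blocks, fam_copies = _realize_family(fam, cons, spec, rng)
        copies[fam.name] = fam_copies
        if fam.planted_age_mya is not None:
            element_ages[fam.name] = [fam.planted_age_mya] * fam.copy_number
        blocks.extend(fam_blocks)
    filler = spec.gs_bp - sum(len(b[0]) for b in blocks)
    if filler < 0:
        raise ValueError("requested repeat content exceeds gs_bp")
    # one unique spacer between consecutive repeat blocks: without them,
    # reads spanning a repeat-repeat junction recur at every copy of that
    # junction type and create spurious cross-family similarity edges
    n_repeat_blocks = len(blocks)
    order = rng.permutation(n_repeat_blocks)
    if filler > 0:
        n_segments = n_repeat_blocks + 1
        base, extra = divmod(filler, n_segments)
        seg_lens = [base + (1 if i < extra else 0) for i in range(n_segments)]
        interleaved = []
        for i, bi in enumerate(order):
            if seg_lens[i] > 0:
                interleaved.append((random_sequence(seg_lens[i], rng), None, []))
            interleaved.append(blocks[bi])
        if seg_lens[-1] > 0:
            interleaved.append((random_sequence(seg_lens[-1], rng), None, []))
        blocks = interleaved
        order = np.arange(len(blocks))
    sequence_parts: list[np.ndarray] = []
    element_spans: dict[str, list[tuple[int, int]]] = {}
    block_spans: dict[str, list[tuple[int, int]]] = {}
    pos = 0
    for i in order:
        arr, fam_name, spans = blocks[i]
        for s, e in spans:
            element_spans.setdefault(fam_name, []).append((pos + s, pos + e))
        if fam_name is not None:
            block_spans.setdefault(fam_name, []).append((pos, pos + len(arr)))
        sequence_parts.append(arr)
        pos += len(arr)
    genome_arr = np.concatenate(sequence_parts) if sequence_parts else np.empty(0, np.uint8)
    truth = _build_truth(spec, copies, element_ages, len(genome_arr))
    return SimulatedGenome(
        spec=spec,
        sequence=_decode(genome_arr),
        truth=truth,
        element_spans=element_spans,
        copies={k: [_decode(c) for c in v] for k, v in copies.items()},
        block_spans=block_spans,
    )


def apply_wgm(genome: SimulatedGenome, spec: Optional[GenomeSpec] = None) -> SimulatedGenome:
    """Duplicate the genome wgm_factor times, then apply amplification bursts
    (extra low-divergence copies modelling post-WGM repeat activation)."""
    spec = spec or genome.spec
    factor = spec.wgm_factor
    if factor == 1 and not spec.amplification_bursts:
        return genome
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    base_len = len(genome.sequence)
    sequence = genome.sequence * factor
    element_spans = {
        fam: [(s + k * base_len, e + k * base_len) for k in range(factor)
              for s, e in spans]
        for fam, spans in genome.element_spans.items()
    }
    block_spans = {
        fam: [(s + k * base_len, e + k * base_len) for k in range(factor)
              for s, e in spans]
        for fam, spans in genome.block_spans.items()
    }
    copies = {fam: list(v) * factor for fam, v in genome.copies.items()}
    element_ages = {
        fam: [t.ltr_ages_mya for t in [genome.truth.families[fam]]][0] * factor
        for fam in genome.truth.families
    }
    fam_specs = {f.name: f for f in spec.families}
    parts = [sequence]
    pos = len(sequence)
    for fam_name, extra, burst_div in spec.amplification_bursts:
        fam = fam_specs[fam_name]
        cons = family_consensus(fam, spec.seed)
        # burst copies are young: LTR pairs nearly identical (age ~ 0)
        blocks, burst_copies = _realize_family(
            fam, cons, spec, rng, n_copies=extra, divergence=burst_div,
            age_mya=0.0 if fam.planted_age_mya is not None else None)
        for arr, name, spans in blocks:
            for s, e in spans:
                element_spans.setdefault(name, []).append((pos + s, pos + e))
            block_spans.setdefault(name, []).append((pos, pos + len(arr)))
            parts.append(_decode(arr))
            pos += len(arr)
        copies.setdefault(fam_name, []).extend(_decode(c) for c in burst_copies)
        if fam.planted_age_mya is not None:
            element_ages.setdefault(fam_name, []).extend([0.0] * extra)
    sequence = "".join(parts)
    truth = _build_truth(
        spec, {k: [_encode(c) for c in v] for k, v in copies.items()},
        element_ages, len(sequence))
    return SimulatedGenome(spec=spec, sequence=sequence, truth=truth,
                           element_spans=element_spans, copies=copies,
                           block_spans=block_spans)


# ---------------------------------------------------------------------------
# read sampling


def reads_at_coverage(gs_bp: float, coverage: float, read_len: int = 100) -> int:
    """Single-read accounting: how many reads of read_len give `coverage`."""
    return round(coverage * gs_bp / read_len)


def coverage_percent(n_reads: float, gs_bp: float, read_len: int = 100) -> float:
    """Genome coverage (in %) of n_reads reads of read_len."""
    return 100.0 * n_reads * read_len / gs_bp


@dataclass
class ReadPair:
    rid: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    from_plastid: bool = False
    origin1: Optional[int] = None  # mate-1 midpoint on the genome (truth tag)
    origin2: Optional[int] = None  # mate-2 midpoint on the genome (truth tag)


def make_plastid(length: int = 150_000, seed: int = 42) -> str:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    return _decode(random_sequence(length, rng))


def sample_reads(genome: SimulatedGenome | str,
                 coverage_fraction: Optional[float] = None,
                 n_pairs: Optional[int] = None,
                 read_len: int = 150,
                 insert: tuple[int, int] = (350, 500),
                 error_rate: float = 0.001,
                 quality: int = 35,
                 degraded_tail_fraction: float = 0.02,
                 plastid_ref: Optional[str] = None,
                 plastid_fraction: float = 0.0,
                 seed: int = 42,
                 prefix: str = "read") -> list[ReadPair]:
    """Draw paired-end reads uniformly from both strands of the genome.

    n_pairs defaults to round(coverage_fraction * gs / (2 * read_len)).
    A plastid_fraction of pairs is drawn from plastid_ref instead.  Qualities
    are constant Phred `quality` except for a degraded_tail_fraction of reads
    whose 3' tail drops to Q10 (to exercise quality trimming).
    """
    seq = genome.sequence if isinstance(genome, SimulatedGenome) else genome
    if len(seq) == 0:
        raise ValueError("empty genome")
    if read_len > len(seq):
        raise ValueError("read_len exceeds genome length")
    if n_pairs is None:
        if coverage_fraction is None or coverage_fraction <= 0:
            raise ValueError("need coverage_fraction > 0 or n_pairs")
        n_pairs = round(coverage_fraction * len(seq) / (2 * read_len))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    if plastid_fraction and plastid_ref is None:
        raise ValueError("plastid_fraction > 0 requires plastid_ref")
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        from_plastid = bool(plastid_fraction and rng.random() < plastid_fraction)
        src = plastid_ref if from_plastid else seq
        frag_len = int(rng.integers(insert[0], insert[1] + 1))
        frag_len = min(frag_len, len(src))
        start = int(rng.integers(0, len(src) - frag_len + 1))
        frag = src[start : start + frag_len]
        flipped = rng.random() < 0.5
        if flipped:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag)[:read_len]
        if error_rate > 0:
            r1 = _apply_errors(r1, error_rate, rng)
            r2 = _apply_errors(r2, error_rate, rng)
        q1 = _qualities(len(r1), quality, degraded_tail_fraction, rng)
        q2 = _qualities(len(r2), quality, degraded_tail_fraction, rng)
        if from_plastid:
            o1 = o2 = None
        else:
            head_mid = start + min(read_len, frag_len) // 2
            tail_mid = start + frag_len - min(read_len, frag_len) // 2
            o1, o2 = (tail_mid, head_mid) if flipped else (head_mid, tail_mid)
        pairs.append(ReadPair(f"{prefix}_{i}", r1, q1, r2, q2, from_plastid,
                              o1, o2))
    return pairs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = _encode(seq)
    mask = rng.random(arr.size) < rate
    if mask.any():
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=mask.sum())) % 4
    return _decode(arr)


def _qualities(n: int, quality: int, degraded_tail_fraction: float,
               rng: np.random.Generator) -> list[int]:
    quals = [quality] * n
    if degraded_tail_fraction and rng.random() < degraded_tail_fraction:
        tail = int(rng.integers(40, 71))
        for j in range(max(0, n - tail), n):
            quals[j] = 10
    return quals


def write_reads(pairs: Sequence[ReadPair], r1_path: str, r2_path: str) -> None:
    write_fastq(r1_path, ((p.rid, p.seq1, quals_to_string(p.qual1)) for p in pairs))
    write_fastq(r2_path, ((p.rid, p.seq2, quals_to_string(p.qual2)) for p in pairs))


def write_genome(genome: SimulatedGenome, fasta_path: str, truth_path: str) -> None:
    write_fasta(fasta_path, [(genome.spec.species_name, genome.sequence)])
    with open(truth_path, "w") as fh:
        fh.write(genome.truth.to_json())


# ---------------------------------------------------------------------------
# standalone LTR-pair simulator for the dating exercise


def simulate_ltr_pairs(ages_mya: Sequence[float], ltr_len: int = 300,
                       internal_len: int = 2000, flank: int = 200,
                       mu: float = DEFAULT_MU, ts_tv: float = 2.0,
                       seed: int = 42) -> list[tuple[str, str]]:
    """One contig per planted age: flank + LTR + internal + LTR' + flank,
    with the two LTRs evolved independently along branches of mu*T years
    (total expected LTR-LTR divergence 2*mu*T)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    contigs = []
    for i, age in enumerate(ages_mya):
        ltr = random_sequence(ltr_len, rng)
        internal = random_sequence(internal_len, rng)
        branch = mu * age * 1e6
        ltr5 = mutate(ltr, branch, rng, ts_tv)
        ltr3 = mutate(ltr, branch, rng, ts_tv)
        parts = [random_sequence(flank, rng), ltr5, internal, ltr3,
                 random_sequence(flank, rng)]
        contigs.append((f"elem_{i}_age{age:.3f}", _decode(np.concatenate(parts))))
    return contigs
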