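"""Synthetic tetraploid genome, ground-truth variants, and caller emulation.

The generator builds a toy genome whose modal copy number is 4, plants true
variants of ten classes with class-specific size ranges, and emits the four
caller output dialects the pipeline consumes:

* a small-variant VCF with ploidy-4 genotypes,
* a split-read SV table (supporting reads, mapping scores),
* a read-pair SV table (confidence score, supporting read pairs,
  breakpoint distance for insertions), and
* a binned normalized-depth track plus a read-depth CNV table.

No sequence content is simulated — only coordinates, genotypes and support
metrics.  Every emitted call is linked to its truth record (or flagged as a
false positive) in a JSON-lines manifest, which downstream tests use as an
oracle.

Design notes
------------
* A bin's normalized depth is defined as ``CN / 2``, so the downstream
  multiply-by-two integer assignment recovers the true copy number exactly
  on noiseless data.
* Copy-number-bearing truth variants (long homozygous deletions, long
  deletions, duplications) are snapped to depth-bin boundaries so that the
  binned track represents them without partial-bin averaging.
* Breakpoint jitter is applied only to the read-pair and read-depth
  emulators; the split-read and small-variant callers are breakpoint-exact.
* One master seed; each emitter draws from its own deterministically
  spawned substream, so adding calls to one file never perturbs another.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
from intervaltree import IntervalTree

from .calls import Caller, VariantClass
from .intervals import Interval

NUCLEOTIDES = ("A", "C", "G", "T")
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class TruthClass(str, enum.Enum):
    """Fine-grained truth classes (the catalog's summary rows)."""

    SUBSTITUTION = "substitution"
    SHORT_DELETION = "short_deletion"
    SHORT_INSERTION = "short_insertion"
    LONG_DELETION = "long_deletion"
    LONG_INSERTION = "long_insertion"
    DUPLICATION = "duplication"
    INVERSION = "inversion"
    INTRA_TRANSLOCATION = "intra_translocation"
    INTER_TRANSLOCATION = "inter_translocation"
    HOMOZYGOUS_DELETION = "homozygous_deletion"


#: Coarse call class each truth class surfaces as in caller output.
TRUTH_TO_CALL_CLASS = {
    TruthClass.SUBSTITUTION: VariantClass.SUBSTITUTION,
    TruthClass.SHORT_DELETION: VariantClass.DELETION,
    TruthClass.SHORT_INSERTION: VariantClass.INSERTION,
    TruthClass.LONG_DELETION: VariantClass.DELETION,
    TruthClass.LONG_INSERTION: VariantClass.INSERTION,
    TruthClass.DUPLICATION: VariantClass.DUPLICATION,
    TruthClass.INVERSION: VariantClass.INVERSION,
    TruthClass.INTRA_TRANSLOCATION: VariantClass.INTRA_TRANSLOCATION,
    TruthClass.INTER_TRANSLOCATION: VariantClass.INTER_TRANSLOCATION,
    TruthClass.HOMOZYGOUS_DELETION: VariantClass.DELETION,
}

#: Which caller families can detect each truth class at all.  Mirrors the
#: real tool capabilities: only the read-pair caller reports
#: intra-chromosomal translocations, only split-read and read-pair callers
#: report translocations, the read-depth caller only sees copy-number
#: events, and the small-variant caller sees small events plus a tail of
#: longer indels.
DEFAULT_SENSITIVITY: dict[TruthClass, dict[Caller, float]] = {
    TruthClass.SUBSTITUTION: {Caller.SMALL_VARIANT: 0.97},
    TruthClass.SHORT_DELETION: {Caller.SMALL_VARIANT: 0.92, Caller.SPLIT_READ: 0.85,
                                Caller.READ_PAIR: 0.02},
    TruthClass.SHORT_INSERTION: {Caller.SMALL_VARIANT: 0.90, Caller.SPLIT_READ: 0.80},
    TruthClass.LONG_DELETION: {Caller.SMALL_VARIANT: 0.10, Caller.SPLIT_READ: 0.80,
                               Caller.READ_PAIR: 0.60, Caller.READ_DEPTH: 0.90},
    TruthClass.LONG_INSERTION: {Caller.SMALL_VARIANT: 0.08, Caller.SPLIT_READ: 0.75,
                                Caller.READ_PAIR: 0.25},
    TruthClass.DUPLICATION: {Caller.SPLIT_READ: 0.70, Caller.READ_DEPTH: 0.65},
    TruthClass.INVERSION: {Caller.SPLIT_READ: 0.85, Caller.READ_PAIR: 0.30},
    TruthClass.INTRA_TRANSLOCATION: {Caller.READ_PAIR: 0.80},
    TruthClass.INTER_TRANSLOCATION: {Caller.SPLIT_READ: 0.60, Caller.READ_PAIR: 0.60},
    TruthClass.HOMOZYGOUS_DELETION: {Caller.SMALL_VARIANT: 0.95, Caller.READ_DEPTH: 0.90,
                                     Caller.SPLIT_READ: 0.30},
}

#: Canonical caller per truth class, used by the noiseless configuration:
#: with these sensitivities at 1 and all others at 0, every truth variant is
#: recovered by exactly the callers whose merge group it belongs to, so the
#: merged catalog is set-equal to the truth.
CANONICAL_SENSITIVITY: dict[TruthClass, dict[Caller, float]] = {
    TruthClass.SUBSTITUTION: {Caller.SMALL_VARIANT: 1.0},
    TruthClass.SHORT_DELETION: {Caller.SMALL_VARIANT: 1.0, Caller.SPLIT_READ: 1.0},
    TruthClass.SHORT_INSERTION: {Caller.SMALL_VARIANT: 1.0, Caller.SPLIT_READ: 1.0},
    TruthClass.LONG_DELETION: {Caller.SPLIT_READ: 1.0, Caller.READ_PAIR: 1.0},
    TruthClass.LONG_INSERTION: {Caller.SPLIT_READ: 1.0, Caller.READ_PAIR: 1.0},
    TruthClass.DUPLICATION: {Caller.SPLIT_READ: 1.0, Caller.READ_DEPTH: 1.0},
    TruthClass.INVERSION: {Caller.SPLIT_READ: 1.0, Caller.READ_PAIR: 1.0},
    TruthClass.INTRA_TRANSLOCATION: {Caller.READ_PAIR: 1.0},
    TruthClass.INTER_TRANSLOCATION: {Caller.SPLIT_READ: 1.0, Caller.READ_PAIR: 1.0},
    TruthClass.HOMOZYGOUS_DELETION: {Caller.SMALL_VARIANT: 1.0, Caller.READ_DEPTH: 1.0},
}


class SimulationSizeError(ValueError):
    """Raised when a chromosome cannot host the requested variant count."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome and caller emulation.

    Defaults describe a desk-scale hypotetraploid genome: two chromosomes
    totalling 5 Mb, baseline copy number 4 over at least 65% of bases,
    100 bp depth bins, and per-class variant counts small enough that the
    whole bundle generates in seconds.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000})
    baseline_copy_number: int = 4
    variant_counts: dict[TruthClass, int] = field(default_factory=lambda: {
        TruthClass.SUBSTITUTION: 300,
        TruthClass.SHORT_DELETION: 120,
        TruthClass.SHORT_INSERTION: 100,
        TruthClass.LONG_DELETION: 40,
        TruthClass.LONG_INSERTION: 30,
        TruthClass.DUPLICATION: 25,
        TruthClass.INVERSION: 20,
        TruthClass.INTRA_TRANSLOCATION: 10,
        TruthClass.INTER_TRANSLOCATION: 8,
        TruthClass.HOMOZYGOUS_DELETION: 15,
    })
    # Inclusive size ranges in bp per class (substitutions are 1 bp).
    size_ranges: dict[TruthClass, tuple[int, int]] = field(default_factory=lambda: {
        TruthClass.SHORT_DELETION: (1, 49),
        TruthClass.SHORT_INSERTION: (1, 49),
        TruthClass.LONG_DELETION: (500, 10_000),
        TruthClass.LONG_INSERTION: (50, 500),
        TruthClass.DUPLICATION: (1_000, 20_000),
        TruthClass.INVERSION: (1_000, 25_000),
        TruthClass.INTRA_TRANSLOCATION: (5_000, 20_000),
        TruthClass.HOMOZYGOUS_DELETION: (1_000, 20_000),
    })
    sensitivity: dict[TruthClass, dict[Caller, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SENSITIVITY.items()})
    jitter_sd: float = 120.0
    # Fraction of true calls whose support metrics are drawn to fail QC,
    # per caller; calibrates how much each quality filter removes.
    qc_fail_rate: dict[Caller, float] = field(default_factory=lambda: {
        Caller.SPLIT_READ: 0.15, Caller.READ_PAIR: 0.15, Caller.READ_DEPTH: 0.15})
    false_positive_counts: dict[Caller, int] = field(default_factory=lambda: {
        Caller.SMALL_VARIANT: 10, Caller.SPLIT_READ: 15,
        Caller.READ_PAIR: 15, Caller.READ_DEPTH: 8})
    depth_noise_sd: float = 0.08
    bin_size: int = 100
    modal_fraction_min: float = 0.65
    telomere_bp: int = 20_000
    centromere_bp: int = 100_000
    # Fraction of homozygous deletions that are sub-bin-size events seen by
    # the small-variant caller (the rest are long CN-0 segments).
    homdel_short_fraction: float = 0.3
    # Genotype model for small variants: P(allele count = 1..4).  The
    # all-alt weight sets the homozygous fraction; because plain deletions
    # cap at 3 alt alleles (an all-alt deletion is a homozygous deletion),
    # 0.53 hom mass on the remaining classes puts the catalog-wide hom/het
    # ratio near the 0.635 seen in real tetraploid data.
    allele_count_probs: tuple[float, float, float, float] = (0.26, 0.12, 0.09, 0.53)
    # P(substitution is a transition); 0.677 gives Ts/Tv near 2.1.
    transition_prob: float = 0.677
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin size must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter must be >= 0")
        for tc, n in self.variant_counts.items():
            if n < 0:
                raise ValueError(f"negative count for {tc.value}")
        for chrom, length in self.chromosomes.items():
            if length < self.bin_size:
                raise ValueError(f"{chrom} shorter than one depth bin")

    def noiseless(self) -> "SimulationConfig":
        """A copy with jitter 0, depth noise 0, no false positives, no QC
        failures, and canonical sensitivities of 1 — under which the merged
        catalog must equal the truth set exactly."""
        import copy
        cfg = copy.deepcopy(self)
        cfg.jitter_sd = 0.0
        cfg.depth_noise_sd = 0.0
        cfg.qc_fail_rate = {c: 0.0 for c in Caller}
        cfg.false_positive_counts = {c: 0 for c in Caller}
        cfg.sensitivity = {k: dict(v) for k, v in CANONICAL_SENSITIVITY.items()}
        return cfg


@dataclass
class TruthVariant:
    truth_id: str
    tclass: TruthClass
    interval: Optional[Interval] = None
    breakpoints: Optional[tuple[tuple[str, int], tuple[str, int]]] = None
    insert_length: Optional[int] = None
    allele_count: Optional[int] = None      # alt alleles out of 4, small variants
    copy_number: Optional[int] = None       # CNV classes
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.allele_count is not None and not 1 <= self.allele_count <= 4:
            raise ValueError("allele count must be in 1..4")
        if self.tclass is TruthClass.HOMOZYGOUS_DELETION and self.copy_number != 0:
            raise ValueError("homozygous deletion must have copy number 0")


@dataclass
class TruthSet:
    config: SimulationConfig
    variants: list[TruthVariant]
    # Per-chromosome integer copy number per depth bin.
    cn_bins: dict[str, np.ndarray]
    gap_regions: list[Interval]

    def by_class(self, tclass: TruthClass) -> list[TruthVariant]:
        return [v for v in self.variants if v.tclass is tclass]

    def baseline_fraction(self) -> float:
        base = sum(int((a == self.config.baseline_copy_number).sum()) for a in self.cn_bins.values())
        total = sum(a.size for a in self.cn_bins.values())
        return base / total


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def _default_gaps(config: SimulationConfig) -> list[Interval]:
    """Telomeric intervals at both chromosome ends plus a centromeric
    interval in the middle, bin-aligned."""
    gaps: list[Interval] = []
    b = config.bin_size
    for chrom, length in config.chromosomes.items():
        tel = (config.telomere_bp // b) * b
        cen = (config.centromere_bp // b) * b
        if tel > 0:
            gaps.append(Interval(chrom, 0, tel))
            gaps.append(Interval(chrom, ((length - tel) // b) * b, length))
        if cen > 0:
            mid = ((length // 2) // b) * b
            gaps.append(Interval(chrom, mid - cen // 2, mid + cen // 2))
    return gaps


_PLACEMENT_BUFFER = 10  # bp between placed variants: rules out accidental adjacency


class _Placer:
    """Rejection-samples non-overlapping intervals across the genome,
    avoiding gap regions and everything placed before."""

    def __init__(self, config: SimulationConfig, gaps: list[Interval], rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.trees = {c: IntervalTree() for c in config.chromosomes}
        for g in gaps:
            self.trees[g.chrom].addi(g.start, g.end)
        self.chrom_names = list(config.chromosomes)
        lens = np.array([config.chromosomes[c] for c in self.chrom_names], dtype=float)
        self.chrom_probs = lens / lens.sum()

    def place(self, size: int, tclass: TruthClass, *, bin_aligned: bool = False,
              max_tries: int = 200) -> Interval:
        b = self.config.bin_size
        for _ in range(max_tries):
            chrom = self.chrom_names[self.rng.choice(len(self.chrom_names), p=self.chrom_probs)]
            clen = self.config.chromosomes[chrom]
            if bin_aligned:
                size_b = max(b, int(round(size / b)) * b)
                nbins = clen // b - size_b // b
                if nbins <= 1:
                    continue
                # start at bin 1 or later so VCF anchor bases exist upstream
                start = int(self.rng.integers(1, nbins)) * b
                iv = Interval(chrom, start, start + size_b)
            else:
                if clen <= size + 2:
                    continue
                start = int(self.rng.integers(1, clen - size))
                iv = Interval(chrom, start, start + size)
            if not self.trees[chrom].overlap(iv.start - _PLACEMENT_BUFFER,
                                             iv.end + _PLACEMENT_BUFFER):
                self.trees[chrom].addi(iv.start - _PLACEMENT_BUFFER, iv.end + _PLACEMENT_BUFFER)
                return iv
        raise SimulationSizeError(
            f"could not place a {size} bp {tclass.value} after {max_tries} tries; "
            "genome too small for the requested counts")


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Generate the ground-truth variant set and the per-bin copy-number map.

    Copy-number-bearing classes are placed first (bin-aligned) and written
    into the CN map; all placements are mutually non-overlapping with a
    small buffer, so no two truth loci of any class are adjacent or
    overlapping.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    gaps = _default_gaps(config)
    placer = _Placer(config, gaps, rng)
    b = config.bin_size
    cn_bins = {
        chrom: np.full(length // b, config.baseline_copy_number, dtype=np.int64)
        for chrom, length in config.chromosomes.items()
    }

    variants: list[TruthVariant] = []
    counter = 0

    def tid() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter:05d}"

    def write_cn(iv: Interval, cn: int) -> None:
        arr = cn_bins[iv.chrom]
        arr[iv.start // b: iv.end // b] = cn

    counts = config.variant_counts

    # CN-bearing classes first (bin aligned).
    n_hd = counts.get(TruthClass.HOMOZYGOUS_DELETION, 0)
    n_hd_short = int(round(n_hd * config.homdel_short_fraction))
    for i in range(n_hd):
        if i < n_hd_short:
            size = _draw_size(rng, 1, 49)
            iv = placer.place(size, TruthClass.HOMOZYGOUS_DELETION)
            variants.append(TruthVariant(tid(), TruthClass.HOMOZYGOUS_DELETION,
                                         interval=iv, allele_count=4, copy_number=0))
        else:
            lo, hi = config.size_ranges[TruthClass.HOMOZYGOUS_DELETION]
            iv = placer.place(_draw_size(rng, lo, hi), TruthClass.HOMOZYGOUS_DELETION,
                              bin_aligned=True)
            write_cn(iv, 0)
            variants.append(TruthVariant(tid(), TruthClass.HOMOZYGOUS_DELETION,
                                         interval=iv, copy_number=0))

    for i in range(counts.get(TruthClass.LONG_DELETION, 0)):
        lo, hi = config.size_ranges[TruthClass.LONG_DELETION]
        iv = placer.place(_draw_size(rng, lo, hi), TruthClass.LONG_DELETION, bin_aligned=True)
        # Allelic losses on the tetraploid background: CN 1 segments are
        # deletion sites under the diploid-relative rule, CN 3 are single-
        # copy losses the depth caller reports but the catalog does not
        # count as deletion sites.
        cn = int(rng.choice([1, 3], p=[0.5, 0.5]))
        write_cn(iv, cn)
        variants.append(TruthVariant(tid(), TruthClass.LONG_DELETION,
                                     interval=iv, copy_number=cn,
                                     allele_count=4 - cn))

    for i in range(counts.get(TruthClass.DUPLICATION, 0)):
        lo, hi = config.size_ranges[TruthClass.DUPLICATION]
        iv = placer.place(_draw_size(rng, lo, hi), TruthClass.DUPLICATION, bin_aligned=True)
        cn = int(rng.choice([5, 6], p=[0.7, 0.3]))
        write_cn(iv, cn)
        variants.append(TruthVariant(tid(), TruthClass.DUPLICATION,
                                     interval=iv, copy_number=cn))

    # Balanced / small classes.
    for tclass in (TruthClass.INVERSION, TruthClass.LONG_INSERTION,
                   TruthClass.SHORT_DELETION, TruthClass.SHORT_INSERTION):
        for _ in range(counts.get(tclass, 0)):
            lo, hi = config.size_ranges[tclass]
            size = _draw_size(rng, lo, hi)
            if tclass in (TruthClass.SHORT_INSERTION, TruthClass.LONG_INSERTION):
                iv = placer.place(1, tclass)
                ac = int(rng.choice([1, 2, 3, 4], p=config.allele_count_probs))
                variants.append(TruthVariant(tid(), tclass, interval=iv,
                                             insert_length=size, allele_count=ac))
            elif tclass is TruthClass.SHORT_DELETION:
                # an all-alternate deletion genotype would be a homozygous
                # deletion, which is its own truth class: cap at 3 alt alleles
                iv = placer.place(size, tclass)
                p = np.asarray(config.allele_count_probs[:3], dtype=float)
                ac = int(rng.choice([1, 2, 3], p=p / p.sum()))
                variants.append(TruthVariant(tid(), tclass, interval=iv, allele_count=ac))
            else:
                iv = placer.place(size, tclass)
                ac = int(rng.choice([1, 2, 3, 4], p=config.allele_count_probs))
                variants.append(TruthVariant(tid(), tclass, interval=iv, allele_count=ac))

    for _ in range(counts.get(TruthClass.SUBSTITUTION, 0)):
        iv = placer.place(1, TruthClass.SUBSTITUTION)
        ref = str(rng.choice(NUCLEOTIDES))
        if rng.random() < config.transition_prob:
            alt = TRANSITION[ref]
        else:
            others = [x for x in NUCLEOTIDES if x != ref and x != TRANSITION[ref]]
            alt = str(rng.choice(others))
        ac = int(rng.choice([1, 2, 3, 4], p=config.allele_count_probs))
        variants.append(TruthVariant(tid(), TruthClass.SUBSTITUTION, interval=iv,
                                     allele_count=ac, ref=ref, alt=alt))

    for _ in range(counts.get(TruthClass.INTRA_TRANSLOCATION, 0)):
        lo, hi = config.size_ranges[TruthClass.INTRA_TRANSLOCATION]
        iv = placer.place(_draw_size(rng, lo, hi), TruthClass.INTRA_TRANSLOCATION)
        variants.append(TruthVariant(tid(), TruthClass.INTRA_TRANSLOCATION, interval=iv))

    chrom_names = list(config.chromosomes)
    for _ in range(counts.get(TruthClass.INTER_TRANSLOCATION, 0)):
        if len(chrom_names) < 2:
            raise SimulationSizeError(
                "inter-chromosomal translocations need at least two chromosomes")
        c1, c2 = [chrom_names[i] for i in
                  rng.choice(len(chrom_names), size=2, replace=False)]
        p1 = placer.place(1, TruthClass.INTER_TRANSLOCATION)
        # second breakpoint forced onto the other chromosome
        while True:
            q = placer.place(1, TruthClass.INTER_TRANSLOCATION)
            if q.chrom != p1.chrom:
                break
        bp = tuple(sorted([(p1.chrom, p1.start), (q.chrom, q.start)]))
        variants.append(TruthVariant(tid(), TruthClass.INTER_TRANSLOCATION, breakpoints=bp))

    truth = TruthSet(config, variants, cn_bins, gaps)
    if truth.baseline_fraction() < config.modal_fraction_min:
        raise SimulationSizeError(
            f"baseline CN covers {truth.baseline_fraction():.2f} of the genome, "
            f"below the configured modal fraction {config.modal_fraction_min}")
    return truth


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------

@dataclass
class CallsetBundle:
    """Paths of one emitted synthetic bundle plus its truth manifest."""

    small_variant_vcf: Path
    split_read_tsv: Path
    read_pair_tsv: Path
    depth_bedgraph: Path
    cnv_tsv: Path
    gap_bed: Path
    manifest: Path


def _passes_split_read(reads: int, summed: float) -> bool:
    return reads >= 2 and summed >= 100 and (summed / reads) > 10


def _draw_split_read_metrics(rng: np.random.Generator, fail: bool) -> tuple[int, float]:
    for _ in range(1000):
        reads = 2 + int(rng.poisson(8))
        mean = float(rng.uniform(5, 60))
        if fail and rng.random() < 0.5:
            reads = int(rng.integers(0, 2))
            mean = float(rng.uniform(5, 60))
        summed = round(mean * max(reads, 1), 1)
        if _passes_split_read(reads, summed) == (not fail):
            return reads, summed
    raise RuntimeError("metric sampling failed to converge")


def _draw_read_pair_metrics(rng: np.random.Generator, fail: bool) -> tuple[float, int]:
    for _ in range(1000):
        conf = float(np.round(rng.uniform(40, 99), 1))
        pairs = int(rng.integers(1, 30))
        if (conf >= 80 and pairs >= 4) == (not fail):
            return conf, pairs
    raise RuntimeError("metric sampling failed to converge")


def _draw_cnv_metrics(rng: np.random.Generator, fail: bool) -> tuple[float, float, float]:
    for _ in range(1000):
        p1 = float(10 ** rng.uniform(-8, -0.5))
        p2 = float(10 ** rng.uniform(-8, -0.5))
        q0 = float(np.round(rng.uniform(0, 0.9), 3))
        if (p1 < 0.01 and p2 < 0.01 and q0 < 0.5) == (not fail):
            return p1, p2, q0
    raise RuntimeError("metric sampling failed to converge")


def _jitter(rng: np.random.Generator, pos: int, sd: float, lo: int, hi: int) -> int:
    if sd == 0:
        return pos
    return int(np.clip(pos + int(round(rng.normal(0, sd))), lo, hi))


def emit_caller_callsets(truth: TruthSet, out_dir: str | Path) -> CallsetBundle:
    """Write the four caller files, the gap BED, and the truth manifest.

    Each truth variant is emitted by each capable caller with probability
    equal to that caller's configured sensitivity for the class.  Support
    metrics are rejection-sampled so that a configurable fraction of true
    calls fails the downstream QC filter; false positives are placed
    uniformly outside gap regions with metrics from the same distributions.
    """
    config = truth.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([config.seed, 23])
    rng_sens, rng_sv, rng_sr, rng_rp, rng_rd, rng_fp = (
        np.random.default_rng(s) for s in ss.spawn(6))

    manifest_rows: list[dict] = []
    sens = config.sensitivity

    def detected(v: TruthVariant, caller: Caller) -> bool:
        p = sens.get(v.tclass, {}).get(caller, 0.0)
        return p > 0 and rng_sens.random() < p

    # --- small-variant VCF -------------------------------------------------
    vcf_path = out / "small_variant.vcf"
    header = pysam.VariantHeader()
    for chrom, length in config.chromosomes.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype (ploidy 4)")
    header.add_sample("SAMPLE")
    sv_records = []
    sv_classes = {TruthClass.SUBSTITUTION, TruthClass.SHORT_DELETION,
                  TruthClass.SHORT_INSERTION, TruthClass.LONG_DELETION,
                  TruthClass.LONG_INSERTION, TruthClass.HOMOZYGOUS_DELETION}
    for v in truth.variants:
        if v.tclass not in sv_classes or v.allele_count is None:
            continue
        if not detected(v, Caller.SMALL_VARIANT):
            continue
        sv_records.append((v, v.allele_count))
    # false positives for the small-variant caller: substitutions only
    for i in range(config.false_positive_counts.get(Caller.SMALL_VARIANT, 0)):
        iv = _random_nongap_interval(rng_fp, config, truth.gap_regions, 1)
        ref = str(rng_fp.choice(NUCLEOTIDES))
        alt = TRANSITION[ref]
        ac = int(rng_fp.choice([1, 2, 3, 4], p=config.allele_count_probs))
        fp = TruthVariant(f"FP-sv-{i:04d}", TruthClass.SUBSTITUTION, interval=iv,
                          allele_count=ac, ref=ref, alt=alt)
        sv_records.append((fp, ac))

    order = {c: i for i, c in enumerate(config.chromosomes)}
    sv_records.sort(key=lambda t: (order[t[0].interval.chrom], t[0].interval.start,
                                   t[0].truth_id))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for idx, (v, ac) in enumerate(sv_records):
            call_id = f"sv-{idx:05d}"
            iv = v.interval
            if v.tclass is TruthClass.SUBSTITUTION:
                rec = vf.new_record(contig=iv.chrom, start=iv.start, stop=iv.end,
                                    alleles=(v.ref, v.alt), id=call_id)
            elif v.tclass in (TruthClass.SHORT_INSERTION, TruthClass.LONG_INSERTION):
                rec = vf.new_record(contig=iv.chrom, start=iv.start - 1, stop=iv.start,
                                    alleles=("A", "A" + "N" * v.insert_length), id=call_id)
            else:  # deletions incl. short homozygous deletions
                rec = vf.new_record(contig=iv.chrom, start=iv.start - 1, stop=iv.end,
                                    alleles=("A" + "N" * len(iv), "A"), id=call_id)
            gt = tuple([1] * ac + [0] * (4 - ac))
            rec.samples["SAMPLE"]["GT"] = gt
            rec.samples["SAMPLE"].phased = False
            vf.write(rec)
            manifest_rows.append({
                "caller": Caller.SMALL_VARIANT.value, "call_id": call_id,
                "truth_id": None if v.truth_id.startswith("FP") else v.truth_id,
                "false_positive": v.truth_id.startswith("FP"),
                "qc_fail": False, "class": v.tclass.value})

    # --- split-read table --------------------------------------------------
    sr_path = out / "split_read.tsv"
    sr_classes = {TruthClass.SHORT_DELETION, TruthClass.SHORT_INSERTION,
                  TruthClass.LONG_DELETION, TruthClass.LONG_INSERTION,
                  TruthClass.DUPLICATION, TruthClass.INVERSION,
                  TruthClass.INTER_TRANSLOCATION, TruthClass.HOMOZYGOUS_DELETION}
    sr_rows = []
    fail_rate = config.qc_fail_rate.get(Caller.SPLIT_READ, 0.0)
    for v in truth.variants:
        if v.tclass not in sr_classes or not detected(v, Caller.SPLIT_READ):
            continue
        fail = rng_sr.random() < fail_rate
        reads, summed = _draw_split_read_metrics(rng_sr, fail)
        sr_rows.append((v, False, fail, reads, summed))
    for i in range(config.false_positive_counts.get(Caller.SPLIT_READ, 0)):
        lo, hi = config.size_ranges[TruthClass.LONG_DELETION]
        size = _draw_size(rng_fp, lo, hi)
        iv = _random_nongap_interval(rng_fp, config, truth.gap_regions, size)
        fail = rng_fp.random() < fail_rate
        reads, summed = _draw_split_read_metrics(rng_fp, fail)
        fp = TruthVariant(f"FP-sr-{i:04d}", TruthClass.LONG_DELETION, interval=iv)
        sr_rows.append((fp, True, fail, reads, summed))

    def sr_sort_key(row):
        v = row[0]
        if v.interval is not None:
            return (order[v.interval.chrom], v.interval.start, v.truth_id)
        (c1, p1), _ = v.breakpoints
        return (order[c1], p1, v.truth_id)

    sr_rows.sort(key=sr_sort_key)
    with open(sr_path, "w") as fh:
        fh.write("call_id\tchrom\tstart\tend\tsvclass\tlength\tnum_reads\tsum_mapq"
                 "\tchrom2\tpos2\n")
        for idx, (v, is_fp, fail, reads, summed) in enumerate(sr_rows):
            call_id = f"sr-{idx:05d}"
            cclass = TRUTH_TO_CALL_CLASS[v.tclass]
            if v.tclass is TruthClass.INTER_TRANSLOCATION:
                (c1, p1), (c2, p2) = v.breakpoints
                fh.write(f"{call_id}\t{c1}\t{p1}\t{p1 + 1}\t{cclass.value}\t\t"
                         f"{reads}\t{summed}\t{c2}\t{p2}\n")
            else:
                iv = v.interval
                length = v.insert_length if v.insert_length is not None else len(iv)
                end = iv.start + 1 if cclass is VariantClass.INSERTION else iv.end
                fh.write(f"{call_id}\t{iv.chrom}\t{iv.start}\t{end}\t{cclass.value}\t"
                         f"{length}\t{reads}\t{summed}\t\t\n")
            manifest_rows.append({
                "caller": Caller.SPLIT_READ.value, "call_id": call_id,
                "truth_id": None if is_fp else v.truth_id, "false_positive": is_fp,
                "qc_fail": fail, "class": v.tclass.value})

    # --- read-pair table ---------------------------------------------------
    rp_path = out / "read_pair.tsv"
    rp_classes = {TruthClass.SHORT_DELETION, TruthClass.LONG_DELETION,
                  TruthClass.LONG_INSERTION, TruthClass.INVERSION,
                  TruthClass.INTRA_TRANSLOCATION, TruthClass.INTER_TRANSLOCATION}
    rp_rows = []
    fail_rate = config.qc_fail_rate.get(Caller.READ_PAIR, 0.0)
    for v in truth.variants:
        if v.tclass not in rp_classes or not detected(v, Caller.READ_PAIR):
            continue
        fail = rng_rp.random() < fail_rate
        conf, pairs = _draw_read_pair_metrics(rng_rp, fail)
        rp_rows.append((v, False, fail, conf, pairs))
    for i in range(config.false_positive_counts.get(Caller.READ_PAIR, 0)):
        lo, hi = config.size_ranges[TruthClass.LONG_DELETION]
        size = _draw_size(rng_fp, lo, hi)
        iv = _random_nongap_interval(rng_fp, config, truth.gap_regions, size)
        fail = rng_fp.random() < fail_rate
        conf, pairs = _draw_read_pair_metrics(rng_fp, fail)
        fp = TruthVariant(f"FP-rp-{i:04d}", TruthClass.LONG_DELETION, interval=iv)
        rp_rows.append((fp, True, fail, conf, pairs))

    rp_rows.sort(key=sr_sort_key)
    with open(rp_path, "w") as fh:
        fh.write("call_id\tchrom1\tpos1\tchrom2\tpos2\tsvclass\tsize\tconfidence"
                 "\tnum_pairs\tbp_distance\n")
        for idx, (v, is_fp, fail, conf, pairs) in enumerate(rp_rows):
            call_id = f"rp-{idx:05d}"
            cclass = TRUTH_TO_CALL_CLASS[v.tclass]
            sd = config.jitter_sd
            if v.tclass is TruthClass.INTER_TRANSLOCATION:
                (c1, p1), (c2, p2) = v.breakpoints
                j1 = _jitter(rng_rp, p1, sd, 0, config.chromosomes[c1] - 1)
                j2 = _jitter(rng_rp, p2, sd, 0, config.chromosomes[c2] - 1)
                fh.write(f"{call_id}\t{c1}\t{j1}\t{c2}\t{j2}\t{cclass.value}\t\t"
                         f"{conf}\t{pairs}\t\n")
            elif cclass is VariantClass.INSERTION:
                iv = v.interval
                pos = _jitter(rng_rp, iv.start, sd, 0, config.chromosomes[iv.chrom] - 2)
                # breakpoint distance: within the insert size for plausible
                # calls (the QC rule removes calls whose distance exceeds it)
                bd = int(rng_rp.integers(0, max(v.insert_length, 1) + 1))
                fh.write(f"{call_id}\t{iv.chrom}\t{pos}\t{iv.chrom}\t{pos + 1}\t"
                         f"{cclass.value}\t{v.insert_length}\t{conf}\t{pairs}\t{bd}\n")
            else:
                iv = v.interval
                s = _jitter(rng_rp, iv.start, sd, 0, config.chromosomes[iv.chrom] - 2)
                e = _jitter(rng_rp, iv.end, sd, s + 1, config.chromosomes[iv.chrom])
                fh.write(f"{call_id}\t{iv.chrom}\t{s}\t{iv.chrom}\t{e}\t{cclass.value}\t"
                         f"{e - s}\t{conf}\t{pairs}\t\n")
            manifest_rows.append({
                "caller": Caller.READ_PAIR.value, "call_id": call_id,
                "truth_id": None if is_fp else v.truth_id, "false_positive": is_fp,
                "qc_fail": fail, "class": v.tclass.value})

    # --- read-depth: depth track + CNV table --------------------------------
    depth_path = out / "depth.bedgraph"
    b = config.bin_size
    with open(depth_path, "w") as fh:
        for chrom in config.chromosomes:
            arr = truth.cn_bins[chrom]
            depth = arr / 2.0
            if config.depth_noise_sd > 0:
                depth = depth + rng_rd.normal(0, config.depth_noise_sd, size=arr.size)
                depth = np.clip(depth, 0.0, None)
            for i, d in enumerate(depth):
                fh.write(f"{chrom}\t{i * b}\t{(i + 1) * b}\t{d:.4f}\n")

    cnv_path = out / "cnv_calls.tsv"
    rd_classes = {TruthClass.HOMOZYGOUS_DELETION, TruthClass.LONG_DELETION,
                  TruthClass.DUPLICATION}
    rd_rows = []
    fail_rate = config.qc_fail_rate.get(Caller.READ_DEPTH, 0.0)
    for v in truth.variants:
        if v.tclass not in rd_classes or not detected(v, Caller.READ_DEPTH):
            continue
        if v.tclass is TruthClass.HOMOZYGOUS_DELETION and len(v.interval) < b:
            continue  # sub-bin events are invisible to a binned depth caller
        fail = rng_rd.random() < fail_rate
        p1, p2, q0 = _draw_cnv_metrics(rng_rd, fail)
        rd_rows.append((v, False, fail, p1, p2, q0))
    for i in range(config.false_positive_counts.get(Caller.READ_DEPTH, 0)):
        lo, hi = config.size_ranges[TruthClass.LONG_DELETION]
        size = _draw_size(rng_fp, lo, hi)
        iv = _random_nongap_interval(rng_fp, config, truth.gap_regions, size,
                                     bin_size=b)
        fail = rng_fp.random() < fail_rate
        p1, p2, q0 = _draw_cnv_metrics(rng_fp, fail)
        fp = TruthVariant(f"FP-rd-{i:04d}", TruthClass.LONG_DELETION, interval=iv,
                          copy_number=int(rng_fp.choice([1, 2, 3, 5, 6])))
        rd_rows.append((fp, True, fail, p1, p2, q0))

    rd_rows.sort(key=sr_sort_key)
    with open(cnv_path, "w") as fh:
        fh.write("call_id\tchrom\tstart\tend\tcopy_number\tpval1\tpval2\tq0\n")
        for idx, (v, is_fp, fail, p1, p2, q0) in enumerate(rd_rows):
            call_id = f"rd-{idx:05d}"
            iv = v.interval
            sd = config.jitter_sd
            # depth-caller jitter is bin-quantized
            js = max(0, iv.start + int(round(rng_rd.normal(0, sd) / b)) * b) if sd else iv.start
            je = iv.end + int(round(rng_rd.normal(0, sd) / b)) * b if sd else iv.end
            je = min(max(je, js + b), config.chromosomes[iv.chrom])
            fh.write(f"{call_id}\t{iv.chrom}\t{js}\t{je}\t{v.copy_number}\t"
                     f"{p1:.3e}\t{p2:.3e}\t{q0}\n")
            manifest_rows.append({
                "caller": Caller.READ_DEPTH.value, "call_id": call_id,
                "truth_id": None if is_fp else v.truth_id, "false_positive": is_fp,
                "qc_fail": fail, "class": v.tclass.value})

    gap_path = out / "gaps.bed"
    with open(gap_path, "w") as fh:
        for g in sorted(truth.gap_regions, key=lambda g: (order[g.chrom], g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\n")

    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        for row in manifest_rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")

    return CallsetBundle(vcf_path, sr_path, rp_path, depth_path, cnv_path,
                         gap_path, manifest_path)


def _random_nongap_interval(rng: np.random.Generator, config: SimulationConfig,
                            gaps: list[Interval], size: int,
                            bin_size: int | None = None) -> Interval:
    chroms = list(config.chromosomes)
    lens = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    gap_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for g in gaps:
        gap_trees[g.chrom].addi(g.start, g.end)
    for _ in range(500):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        clen = config.chromosomes[chrom]
        if bin_size:
            size_b = max(bin_size, (size // bin_size) * bin_size)
            if clen // bin_size - size_b // bin_size <= 0:
                continue
            start = int(rng.integers(0, clen // bin_size - size_b // bin_size)) * bin_size
            iv = Interval(chrom, start, start + size_b)
        else:
            if clen <= size + 1:
                continue
            start = int(rng.integers(0, clen - size))
            iv = Interval(chrom, start, start + size)
        if not gap_trees[chrom].overlap(iv.start, iv.end):
            return iv
    raise SimulationSizeError("could not place a false-positive call outside gaps")
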