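"""Core call model shared by every pipeline stage.

A :class:`VariantCall` is one normalized record from one caller.  Callers
report very different things — a tetraploid genotype, split-read support, a
read-pair confidence score, an integer copy number — so most fields are
optional and a field that a caller does not report is ``None``, never a
default value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .intervals import Interval

PLOIDY = 4

#: Length below which an insertion or deletion is "short" (NCBI SV convention).
SHORT_LONG_CUTOFF = 50


class VariantClass(str, enum.Enum):
    """Coarse variant classes as reported by callers.

    The short/long indel split and the homozygous-deletion category are
    derived downstream from length and genotype/copy number, not encoded
    here.
    """

    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    INVERSION = "inversion"
    INTRA_TRANSLOCATION = "intra_translocation"
    INTER_TRANSLOCATION = "inter_translocation"


class Caller(str, enum.Enum):
    """The four caller families whose output dialects the pipeline consumes."""

    SMALL_VARIANT = "small_variant"  # haplotype-based small-variant caller, ploidy-4 GT
    SPLIT_READ = "split_read"        # split-read SV caller, precise breakpoints
    READ_PAIR = "read_pair"          # read-pair SV caller, imprecise breakpoints
    READ_DEPTH = "read_depth"        # binned read-depth CNV caller


#: Callers whose breakpoints come from base-level read evidence; they take
#: precedence in the hierarchical merge.
SPLIT_PRECISION_CALLERS = frozenset({Caller.SMALL_VARIANT, Caller.SPLIT_READ})


@dataclass
class VariantCall:
    caller: Caller
    vclass: VariantClass
    interval: Optional[Interval] = None
    # Translocations carry a breakpoint pair instead of an interval.
    breakpoints: Optional[tuple[tuple[str, int], tuple[str, int]]] = None
    length: Optional[int] = None          # event length in bp (insert length for insertions)
    call_id: str = ""
    # small-variant caller
    genotype: Optional[tuple[int, ...]] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    # split-read caller
    num_reads: Optional[int] = None
    sum_mapq: Optional[float] = None
    # read-pair caller
    confidence: Optional[float] = None
    num_pairs: Optional[int] = None
    bp_distance: Optional[int] = None     # breakpoint distance, insertions only
    # read-depth caller
    copy_number: Optional[int] = None
    pvalues: Optional[tuple[float, float]] = None
    q0: Optional[float] = None

    @property
    def mean_mapq(self) -> Optional[float]:
        if self.sum_mapq is None or not self.num_reads:
            return None
        return self.sum_mapq / self.num_reads

    @property
    def is_homozygous_alt(self) -> bool:
        """All four alleles identical and non-reference."""
        gt = self.genotype
        return gt is not None and len(set(gt)) == 1 and gt[0] != 0

    @property
    def chrom(self) -> Optional[str]:
        if self.interval is not None:
            return self.interval.chrom
        return None

    def with_interval(self, interval: Interval) -> "VariantCall":
        return replace(self, interval=interval)


@dataclass
class QCThresholds:
    """Per-caller quality-filter thresholds.

    Defaults are the published operating points: split-read calls need at
    least 2 supporting reads, a summed mapping score of at least 100 and a
    mean mapping score strictly above 10; read-pair calls need a confidence
    of at least 80 and at least 4 supporting pairs; read-depth CNV calls are
    removed when either t-test p-value reaches 0.01 or the zero-mapping-
    quality fraction reaches 0.5.
    """

    min_supporting_reads: int = 2
    min_summed_mapq: float = 100.0
    min_mean_mapq_exclusive: float = 10.0
    min_confidence: float = 80.0
    min_read_pairs: int = 4
    max_cnv_pvalue_exclusive: float = 0.01
    max_q0_exclusive: float = 0.5
    short_long_cutoff: int = SHORT_LONG_CUTOFF
    translocation_max_bp_distance: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "min_supporting_reads", "min_summed_mapq", "min_mean_mapq_exclusive",
            "min_confidence", "min_read_pairs", "max_cnv_pvalue_exclusive",
            "max_q0_exclusive", "short_long_cutoff", "translocation_max_bp_distance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MergedLocus:
    """One harmonized variant locus after cross-caller merging."""

    vclass: VariantClass
    interval: Optional[Interval] = None
    breakpoints: Optional[tuple[tuple[str, int], tuple[str, int]]] = None
    callers: frozenset[Caller] = field(default_factory=frozenset)
    source_ids: tuple[str, ...] = ()
    length: Optional[int] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.callers:
            raise ValueError("merged locus must have at least one contributing caller")


@dataclass
class DatabaseRecord:
    """One external-database entry in the minimal schema the matcher needs."""

    database: str
    interval: Interval
    vclass: VariantClass
    identifier: str = ""
    ref: Optional[str] = None
    alt: Optional[str] = None
    clinical_significance: Optional[str] = None
    has_assertion_criteria: Optional[bool] = None
    submitter: Optional[str] = None
    is_common: Optional[bool] = None
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.allele_frequency is not None and not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")


def sort_key(call: VariantCall) -> tuple:
    """Deterministic ordering for calls: by interval, then id."""
    if call.interval is not None:
        iv = call.interval
        return (iv.chrom, iv.start, iv.end, call.call_id)
    assert call.breakpoints is not None
    (c1, p1), (c2, p2) = sorted(call.breakpoints)
    return (c1, p1, c2, p2, call.call_id)
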