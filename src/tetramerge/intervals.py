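"""Interval algebra for variant-locus comparison.

All coordinates are 0-based, half-open ``[start, end)``.  The matching
primitives here implement the overlap rules used throughout the pipeline:
any-overlap, fractional reciprocal overlap (symmetric), fractional one-way
overlap (asymmetric), bookended adjacency, and breakpoint-distance matching
for translocations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a: Interval, b: Interval) -> int:
    """Number of bases shared by two intervals; 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def any_overlap(a: Interval, b: Interval) -> bool:
    """At least one shared base."""
    return overlap_bp(a, b) >= 1


def reciprocal_match(a: Interval, b: Interval, f: float = 0.25, *, strict: bool = False) -> bool:
    """Reciprocal fractional overlap: the shared span must cover fraction ``f``
    of *each* interval's own length.

    ``strict`` selects ``>`` instead of ``>=`` on both comparisons; the
    database-matching rules for population SVs (>25%) and pathogenic SVs
    (>90%) are strict, while the caller-comparison rule (minimum 25%) is
    inclusive.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return False
    ta, tb = f * len(a), f * len(b)
    if strict:
        return ov > ta and ov > tb
    return ov >= ta and ov >= tb


def oneway_match(a: Interval, b: Interval, f: float = 0.25, *, strict: bool = False) -> bool:
    """One-way fractional overlap: is fraction ``f`` of ``a`` covered by ``b``?

    Asymmetric by design — used for duplications and inversions, where the
    two callers' size estimates differ too much for a reciprocal criterion.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return False
    t = f * len(a)
    return ov > t if strict else ov >= t


def adjacent_or_overlapping(a: Interval, b: Interval) -> bool:
    """True when the intervals share a base or are bookended (zero gap).

    Under half-open coordinates "adjacent" means ``a.end == b.start`` or
    ``b.end == a.start``.
    """
    if a.chrom != b.chrom:
        return False
    return a.start <= b.end and b.start <= a.end


def breakpoint_distance_match(
    bp_a: tuple[tuple[str, int], tuple[str, int]],
    bp_b: tuple[tuple[str, int], tuple[str, int]],
    max_distance: int = 1000,
) -> bool:
    """Translocation matching: both breakpoints of one call are within
    ``max_distance`` (exclusive) of the corresponding breakpoints of the
    other, and the chromosome pair is the same.

    Breakpoint pairs are compared after sorting by chromosome so that
    (chr1, chr2) and (chr2, chr1) orderings are equivalent.
    """
    a1, a2 = sorted(bp_a)
    b1, b2 = sorted(bp_b)
    if a1[0] != b1[0] or a2[0] != b2[0]:
        return False
    return abs(a1[1] - b1[1]) < max_distance and abs(a2[1] - b2[1]) < max_distance


def union_interval(intervals: Sequence[Interval]) -> Interval:
    """Smallest interval covering all inputs (single chromosome)."""
    if not intervals:
        raise ValueError("empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"cannot union intervals across chromosomes: {chroms}")
    return Interval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def connected_components(n: int, edges: Iterable[tuple[int, int]]) -> list[list[int]]:
    """Union-find connected components over ``n`` items.

    Merge clusters throughout the pipeline are the transitive closure of a
    pairwise predicate; this is the single place that closure is computed so
    every merge is deterministic and order-free.  Components are returned
    sorted by smallest member.
    """
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]
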