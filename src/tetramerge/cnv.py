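"""Integer copy-number assignment from a binned normalized-depth track.

The depth caller reports a normalized read depth per fixed-size bin (100 bp
by default).  Integer copy numbers are assigned by doubling the normalized
depth and rounding into half-open unit bins with cut points at 0.5, 1.5,
2.5, ...: copy number ``k`` covers ``2d in [k - 0.5, k + 0.5)``, with CN 0
when ``2d < 0.5``.  The boundary is assigned upward; this is a convention
choice (the cut points alone do not fix a side) and is configurable.

Copy-number classes on the tetraploid background follow the catalog's
definitions: deletion sites are CN <= 1 (relative to a diploid genome),
homozygous deletions are CN = 0, duplication sites are CN >= 5 (one copy
above the tetraploid baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import Interval


@dataclass
class CNSegment:
    interval: Interval
    copy_number: int

    @property
    def is_deletion(self) -> bool:
        return self.copy_number <= 1

    @property
    def is_homozygous_deletion(self) -> bool:
        return self.copy_number == 0

    @property
    def is_duplication(self) -> bool:
        return self.copy_number >= 5


@dataclass
class CopyNumberProfile:
    """Binned depth track plus derived integer-CN segments.

    ``bins`` maps chromosome -> (starts array, normalized depth array);
    bins tile each chromosome in order without overlap.
    """

    bin_size: int
    depths: dict[str, np.ndarray]          # per-chromosome normalized depth per bin
    baseline_copy_number: int = 4
    boundary_upward: bool = True

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin size must be >= 1")
        for chrom, d in self.depths.items():
            if d.size == 0:
                raise ValueError(f"{chrom} has no bins")
            if np.any(d < 0):
                raise ValueError(f"negative depth on {chrom}")

    @property
    def n_bins(self) -> int:
        return sum(d.size for d in self.depths.values())

    def integer_cn(self) -> dict[str, np.ndarray]:
        return {c: assign_integer_cn(d, boundary_upward=self.boundary_upward)
                for c, d in self.depths.items()}

    def segments(self) -> list[CNSegment]:
        """Maximal runs of equal integer CN, per chromosome, in bin units."""
        segs: list[CNSegment] = []
        b = self.bin_size
        for chrom, cn in self.integer_cn().items():
            boundaries = np.flatnonzero(np.diff(cn)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [cn.size]))
            for s, e in zip(starts, ends):
                segs.append(CNSegment(Interval(chrom, int(s) * b, int(e) * b),
                                      int(cn[s])))
        return segs


def assign_integer_cn(depth: Union[float, np.ndarray], *,
                      boundary_upward: bool = True) -> Union[int, np.ndarray]:
    """Integer CN for a normalized depth value (scalar or array).

    ``CN = k`` iff ``2 * depth`` lies in ``[k - 0.5, k + 0.5)`` (upward
    half-open bins; flip ``boundary_upward`` for ``(k - 0.5, k + 0.5]``).
    Negative depth is an input error.
    """
    arr = np.asarray(depth, dtype=float)
    if np.any(arr < 0):
        raise ValueError("normalized depth must be >= 0")
    doubled = 2.0 * arr
    if boundary_upward:
        cn = np.floor(doubled + 0.5)
    else:
        cn = np.ceil(doubled - 0.5)
    cn = np.maximum(cn, 0.0).astype(np.int64)
    if np.isscalar(depth) or arr.ndim == 0:
        return int(cn)
    return cn


def classify_cn_segments(profile: CopyNumberProfile) -> dict[str, list[CNSegment]]:
    """Partition derived segments into the catalog's CN classes.

    Returns deletion sites (CN <= 1), homozygous deletions (CN = 0, a
    subset of deletions), and duplication sites (CN >= 5).
    """
    segs = profile.segments()
    return {
        "deletion": [s for s in segs if s.is_deletion],
        "homozygous_deletion": [s for s in segs if s.is_homozygous_deletion],
        "duplication": [s for s in segs if s.is_duplication],
    }


def modal_copy_number(profile: CopyNumberProfile) -> int:
    """The integer CN covering the largest total base count.

    Ties break toward the lower copy number for determinism.
    """
    counts: dict[int, int] = {}
    for cn in profile.integer_cn().values():
        vals, n = np.unique(cn, return_counts=True)
        for v, c in zip(vals, n):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    if not counts:
        raise ValueError("empty profile")
    best = max(sorted(counts), key=lambda k: (counts[k], -k))
    return best


def cn_genome_fraction_histogram(profile: CopyNumberProfile) -> dict[int, float]:
    """Fraction of covered genome at each integer CN; sums to 1."""
    counts: dict[int, int] = {}
    total = 0
    for cn in profile.integer_cn().values():
        vals, n = np.unique(cn, return_counts=True)
        total += cn.size
        for v, c in zip(vals, n):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    return {k: counts[k] / total for k in sorted(counts)}


def read_depth_bedgraph(path: str | Path, bin_size: int = 100,
                        baseline_copy_number: int = 4) -> CopyNumberProfile:
    """Load a 4-column bedGraph-like depth track into a profile.

    Bins must tile each chromosome contiguously at ``bin_size``.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str, "start": int, "end": int, "depth": float})
    depths: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not np.all(np.diff(starts) == bin_size) or not np.all(ends - starts == bin_size):
            raise ValueError(f"{chrom}: depth bins do not tile at bin size {bin_size}")
        depths[chrom] = grp["depth"].to_numpy()
    return CopyNumberProfile(bin_size=bin_size, depths=depths,
                             baseline_copy_number=baseline_copy_number)


def write_cn_segments_bed(segments: Iterable[CNSegment], path: str | Path) -> None:
    """CN segments as 5-column BED with the copy number in the score column."""
    with open(path, "w") as fh:
        for s in segments:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tCN{s.copy_number}\t{s.copy_number}\n")
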