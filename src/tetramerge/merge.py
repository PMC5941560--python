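"""Class-aware overlap rules and the hierarchical cross-caller merge.

Breakpoint precision differs sharply between caller families, so calls are
merged hierarchically: split-read-precision calls (small-variant and
split-read callers) form the backbone; read-pair calls that overlap the
backbone under the class's comparison rule are dropped and the remainder
merged in; read-depth calls are treated the same way last.  Insertions are
merged by direct overlap only, with no hierarchy.  Homozygous deletions
get a dedicated filter/swap/merge pipeline combining small-variant
homozygous-deletion calls with copy-number-zero segments.

Comparison rules per class:

* insertions/deletions — reciprocal overlap of at least 25% (inclusive);
* duplications/inversions — one-way: at least 25% of the call is covered;
* inter-chromosomal translocations — both breakpoints within 1000 bp;
* homozygous-deletion swap — reciprocal overlap strictly above 50%.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calls import (Caller, MergedLocus, QCThresholds, VariantCall,
                    VariantClass, sort_key)
from .intervals import (Interval, adjacent_or_overlapping, any_overlap,
                        breakpoint_distance_match, connected_components,
                        oneway_match, reciprocal_match, union_interval)
from .io_qc import ContractViolation

#: classes compared by inclusive 25% reciprocal overlap
RECIPROCAL_CLASSES = {VariantClass.DELETION}
#: classes compared by inclusive 25% one-way overlap
ONEWAY_CLASSES = {VariantClass.DUPLICATION, VariantClass.INVERSION,
                  VariantClass.INTRA_TRANSLOCATION}


def class_match(a: VariantCall, b: VariantCall, vclass: VariantClass,
                f: float = 0.25, max_bp_distance: int = 1000) -> bool:
    """Do two calls of one class overlap under that class's comparison rule?

    For the one-way classes the test is symmetric in practice: a match is
    declared when at least 25% of either call is covered by the other.
    """
    if vclass is VariantClass.INTER_TRANSLOCATION:
        return breakpoint_distance_match(a.breakpoints, b.breakpoints, max_bp_distance)
    if vclass is VariantClass.SUBSTITUTION:
        return a.interval == b.interval
    if vclass is VariantClass.INSERTION:
        return any_overlap(a.interval, b.interval)
    if vclass in ONEWAY_CLASSES:
        return (oneway_match(a.interval, b.interval, f)
                or oneway_match(b.interval, a.interval, f))
    return reciprocal_match(a.interval, b.interval, f)


def _dropped_by(call: VariantCall, loci: Sequence["_WorkLocus"], vclass: VariantClass,
                f: float = 0.25, max_bp_distance: int = 1000) -> bool:
    """Is a lower-tier call overlapped (class rule) by any higher-tier locus?

    For one-way classes the asymmetric rule is applied from the lower-tier
    call's side: it is dropped when at least 25% of *it* is covered."""
    for locus in loci:
        if vclass is VariantClass.INTER_TRANSLOCATION:
            if breakpoint_distance_match(call.breakpoints, locus.breakpoints,
                                         max_bp_distance):
                return True
        elif vclass in ONEWAY_CLASSES:
            if oneway_match(call.interval, locus.interval, f):
                return True
        else:
            if reciprocal_match(call.interval, locus.interval, f):
                return True
    return False


@dataclass
class _WorkLocus:
    interval: Optional[Interval]
    breakpoints: Optional[tuple] = None
    callers: frozenset = frozenset()
    source_ids: tuple = ()
    length: Optional[int] = None
    provenance: str = ""


def _cluster_loci(items: list[_WorkLocus], pred) -> list[_WorkLocus]:
    items = sorted(items, key=lambda w: (w.interval.chrom, w.interval.start,
                                         w.interval.end, w.source_ids))
    edges = [(i, j) for i in range(len(items)) for j in range(i + 1, len(items))
             if pred(items[i], items[j])]
    out = []
    for comp in connected_components(len(items), edges):
        members = [items[i] for i in comp]
        if len(members) == 1:
            out.append(members[0])
            continue
        iv = union_interval([m.interval for m in members])
        out.append(_WorkLocus(
            interval=iv,
            callers=frozenset().union(*[m.callers for m in members]),
            source_ids=tuple(x for m in members for x in m.source_ids),
            length=len(iv),
            provenance=";".join(p for m in members if (p := m.provenance))))
    return out


def _as_locus(call: VariantCall) -> _WorkLocus:
    return _WorkLocus(interval=call.interval, breakpoints=call.breakpoints,
                      callers=frozenset({call.caller}),
                      source_ids=tuple(call.call_id.split(",")),
                      length=call.length)


def _finalize(work: Iterable[_WorkLocus], vclass: VariantClass) -> list[MergedLocus]:
    out = [MergedLocus(vclass=vclass, interval=w.interval, breakpoints=w.breakpoints,
                       callers=w.callers, source_ids=w.source_ids, length=w.length,
                       provenance=w.provenance)
           for w in work]
    out.sort(key=lambda m: ((m.interval.chrom, m.interval.start, m.interval.end)
                            if m.interval is not None else m.breakpoints))
    return out


def hierarchical_merge(split_precision_calls: Sequence[VariantCall],
                       read_pair_calls: Sequence[VariantCall] = (),
                       read_depth_calls: Sequence[VariantCall] = (),
                       *, vclass: VariantClass | None = None,
                       overlap_fraction: float = 0.25) -> list[MergedLocus]:
    """Three-stage precedence merge for one interval-valued variant class.

    Stage 1 union-merges the split-read-precision calls (adjacent or
    overlapping clusters).  Stage 2 drops read-pair calls overlapping the
    stage-1 loci under the class comparison rule and union-merges the
    remainder in.  Stage 3 repeats for read-depth calls.  Output loci are
    pairwise non-adjacent and non-overlapping.
    """
    all_calls = list(split_precision_calls) + list(read_pair_calls) + list(read_depth_calls)
    if not all_calls:
        return []
    classes = {c.vclass for c in all_calls}
    if len(classes) != 1:
        raise ContractViolation(f"hierarchical_merge got mixed classes: {classes}")
    cls = vclass or classes.pop()
    if cls is VariantClass.INSERTION:
        raise ContractViolation("insertions are merged without hierarchy; "
                                "use merge_insertions")

    pred = lambda a, b: adjacent_or_overlapping(a.interval, b.interval)
    loci = _cluster_loci([_as_locus(c) for c in split_precision_calls], pred)
    for tier in (read_pair_calls, read_depth_calls):
        survivors = [_as_locus(c) for c in tier
                     if not _dropped_by(c, loci, cls, overlap_fraction)]
        loci = _cluster_loci(loci + survivors, pred)
    return _finalize(loci, cls)


def merge_insertions(*callsets: Sequence[VariantCall]) -> list[MergedLocus]:
    """Merge insertion calls across callers by direct overlap only.

    No adjacency rule and no tool hierarchy; the longest inserted length in
    each cluster is retained."""
    calls = sorted((c for cs in callsets for c in cs), key=sort_key)
    for c in calls:
        if c.vclass is not VariantClass.INSERTION:
            raise ContractViolation(f"merge_insertions got a {c.vclass.value}")
    edges = [(i, j) for i in range(len(calls)) for j in range(i + 1, len(calls))
             if any_overlap(calls[i].interval, calls[j].interval)]
    out = []
    for comp in connected_components(len(calls), edges):
        members = [calls[i] for i in comp]
        iv = union_interval([m.interval for m in members])
        out.append(MergedLocus(
            vclass=VariantClass.INSERTION, interval=iv,
            callers=frozenset(m.caller for m in members),
            source_ids=tuple(x for m in members for x in m.call_id.split(",")),
            length=max((m.length or 0) for m in members)))
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end))
    return out


def merge_translocations(*callsets: Sequence[VariantCall],
                         max_bp_distance: int = 1000) -> list[MergedLocus]:
    """Cross-caller merge of inter-chromosomal translocations by the
    breakpoint-distance rule (both breakpoints < 1000 bp apart, same
    chromosome pair).  The leftmost breakpoint pair represents a cluster."""
    calls = [c for cs in callsets for c in cs]
    for c in calls:
        if c.vclass is not VariantClass.INTER_TRANSLOCATION:
            raise ContractViolation("merge_translocations expects inter-chromosomal "
                                    "translocations")
    calls.sort(key=sort_key)
    edges = [(i, j) for i in range(len(calls)) for j in range(i + 1, len(calls))
             if breakpoint_distance_match(calls[i].breakpoints, calls[j].breakpoints,
                                          max_bp_distance)]
    out = []
    for comp in connected_components(len(calls), edges):
        members = [calls[i] for i in comp]
        rep = min(members, key=sort_key)
        out.append(MergedLocus(
            vclass=VariantClass.INTER_TRANSLOCATION, breakpoints=rep.breakpoints,
            callers=frozenset(m.caller for m in members),
            source_ids=tuple(x for m in members for x in m.call_id.split(","))))
    out.sort(key=lambda m: m.breakpoints)
    return out


def merge_homozygous_deletions(
        small_variant_homdels: Sequence[VariantCall],
        cn0_calls: Sequence[VariantCall],
        split_read_deletions: Sequence[VariantCall] = (),
        read_pair_deletions: Sequence[VariantCall] = (),
        all_small_variant_calls: Sequence[VariantCall] = (),
        *, swap_fraction: float = 0.5) -> list[MergedLocus]:
    """Filter, swap and merge homozygous-deletion calls.

    1. Copy-number-zero segments that overlap (any overlap) *any*
       small-variant-caller call are removed — a region cannot be at zero
       copies if the small-variant caller genotyped variants inside it.
    2. Surviving CN-0 segments with reciprocal overlap strictly above 50%
       with a split-read or read-pair deletion are replaced by that
       deletion's breakpoints (ties: highest reciprocal overlap, then the
       split-read candidate, then leftmost).
    3. The result is merged (adjacent-or-overlapping clusters) with the
       small-variant caller's homozygous-deletion calls.
    """
    sv_calls = list(all_small_variant_calls) or list(small_variant_homdels)
    work: list[_WorkLocus] = []
    for seg in sorted(cn0_calls, key=sort_key):
        if any(c.interval is not None and any_overlap(seg.interval, c.interval)
               for c in sv_calls):
            continue
        candidates = []
        for cand in list(split_read_deletions) + list(read_pair_deletions):
            if reciprocal_match(seg.interval, cand.interval, swap_fraction, strict=True):
                ov = min(seg.interval.end, cand.interval.end) - max(seg.interval.start,
                                                                    cand.interval.start)
                frac = min(ov / len(seg.interval), ov / len(cand.interval))
                candidates.append((frac, cand))
        if candidates:
            best = max(candidates,
                       key=lambda t: (t[0], t[1].caller is Caller.SPLIT_READ,
                                      -t[1].interval.start, t[1].call_id))[1]
            work.append(_WorkLocus(
                interval=best.interval, callers=frozenset({Caller.READ_DEPTH, best.caller}),
                source_ids=(seg.call_id, best.call_id), length=len(best.interval),
                provenance=f"CN0 {seg.call_id} replaced by {best.caller.value}:{best.call_id}"))
        else:
            work.append(_as_locus(seg))
    work.extend(_as_locus(c) for c in small_variant_homdels)
    pred = lambda a, b: adjacent_or_overlapping(a.interval, b.interval)
    return _finalize(_cluster_loci(work, pred), VariantClass.DELETION)


def passthrough_loci(calls: Sequence[VariantCall],
                     vclass: VariantClass) -> list[MergedLocus]:
    """Wrap single-caller calls as merged loci unchanged (substitutions and
    intra-chromosomal translocations are reported by one caller only)."""
    return _finalize([_as_locus(c) for c in sorted(calls, key=sort_key)], vclass)


# ---------------------------------------------------------------------------
# Contribution accounting
# ---------------------------------------------------------------------------

def summarize_contributions(class_name: str,
                            per_caller: dict[Caller, Sequence[VariantCall]],
                            merged: Sequence[MergedLocus],
                            vclass: VariantClass,
                            overlap_fraction: float = 0.25) -> pd.DataFrame:
    """Per-caller accounting for one class: call count, fraction of its
    calls overlapping any other caller's calls (under the class comparison
    rule), and fraction of merged loci it contributed to."""
    rows = []
    n_merged = len(merged)
    for caller, calls in per_caller.items():
        others = [c for other, cs in per_caller.items() if other != caller for c in cs]
        n = len(calls)
        if n and others:
            n_ov = sum(1 for c in calls
                       if any(class_match(c, o, vclass, overlap_fraction) for o in others))
            frac = n_ov / n
        else:
            frac = 0.0
        contributed = sum(1 for m in merged if caller in m.callers)
        rows.append({
            "class": class_name, "caller": caller.value, "n_calls": n,
            "overlap_fraction": frac, "merged_total": n_merged,
            "merged_with_caller": contributed,
            "fraction_of_merged": contributed / n_merged if n_merged else 0.0,
        })
    return pd.DataFrame(rows)


def size_histogram(loci: Sequence[MergedLocus], bins: Sequence[int] | None = None
                   ) -> pd.Series:
    """Locus-size histogram for one class (log-spaced bins by default)."""
    sizes = [m.length if m.length is not None else len(m.interval)
             for m in loci if m.interval is not None or m.length is not None]
    if not sizes:
        return pd.Series(dtype=int)
    if bins is None:
        bins = [0, 10, 50, 100, 500, 1000, 5000, 10_000, 50_000, 10 ** 9]
    cut = pd.cut(pd.Series(sizes), bins=list(bins), right=False)
    return cut.value_counts().sort_index()
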