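"""Caller-dialect parsing, per-caller quality filters, repeat masking,
length-class split, and within-caller merging.

Each caller family has its own output dialect (see :mod:`tetramerge.synth`
for the column contracts).  ``parse_callset`` normalizes all of them into
:class:`~tetramerge.calls.VariantCall` records with 0-based half-open
coordinates; the filters then implement the published per-caller QC rules
exactly, including their inclusive/exclusive boundaries:

* split-read: keep calls with >= 2 supporting reads, summed mapping score
  >= 100, and mean mapping score strictly > 10;
* read-pair: keep calls with confidence >= 80 and >= 4 supporting pairs,
  and drop insertion calls whose breakpoint distance exceeds the insertion
  size;
* read-depth: drop CNV calls when either t-test p-value is >= 0.01 or the
  fraction of zero-mapping-quality reads is >= 0.5.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .calls import Caller, MergedLocus, QCThresholds, VariantCall, VariantClass, sort_key
from .intervals import (Interval, adjacent_or_overlapping, any_overlap,
                        breakpoint_distance_match, connected_components,
                        union_interval)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A record that does not conform to its declared dialect."""

    def __init__(self, path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path, self.line = path, line


class ContractViolation(ValueError):
    """An operation was handed calls outside its contract (mixed callers or
    classes)."""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_callset(path: str | Path, caller: Caller) -> list[VariantCall]:
    """Parse one caller file into normalized calls.

    Coordinates come out 0-based half-open; ploidy-4 genotypes are kept as
    allele tuples.  Malformed records raise :class:`ParseError` naming the
    file and line.
    """
    if caller is Caller.SMALL_VARIANT:
        return _parse_small_variant_vcf(path)
    if caller is Caller.SPLIT_READ:
        return _parse_split_read(path)
    if caller is Caller.READ_PAIR:
        return _parse_read_pair(path)
    if caller is Caller.READ_DEPTH:
        return _parse_cnv_table(path)
    raise ValueError(f"unknown caller dialect: {caller}")


def _classify_vcf_alleles(ref: str, alt: str) -> tuple[VariantClass, Interval | None, int]:
    """Class, interval and length from a biallelic REF/ALT pair.

    Deletion interval is the REF span minus the anchor base; an insertion
    occupies the point interval after its anchor; a substitution locus is
    the single substituted base.
    """
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SUBSTITUTION, None, 1
    if len(ref) > len(alt):
        return VariantClass.DELETION, None, len(ref) - len(alt)
    return VariantClass.INSERTION, None, len(alt) - len(ref)


def _parse_small_variant_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0] if list(vf.header.samples) else None
        for i, rec in enumerate(vf):
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(path, i + 1, "expected biallelic records")
            ref, alt = rec.ref, rec.alts[0]
            vclass, _, length = _classify_vcf_alleles(ref, alt)
            if vclass is VariantClass.SUBSTITUTION:
                iv = Interval(rec.contig, rec.start, rec.start + 1)
            elif vclass is VariantClass.DELETION:
                iv = Interval(rec.contig, rec.start + 1, rec.start + len(ref))
            else:
                iv = Interval(rec.contig, rec.start + 1, rec.start + 2)
            gt: Optional[tuple[int, ...]] = None
            if sample is not None:
                raw = rec.samples[sample].get("GT")
                if raw is not None and raw != (None,):
                    gt = tuple(a if a is not None else 0 for a in raw)
            calls.append(VariantCall(
                caller=Caller.SMALL_VARIANT, vclass=vclass, interval=iv,
                length=length, call_id=rec.id or f"sv-{i:05d}",
                genotype=gt, ref=ref, alt=alt))
    return calls


def _req(df_row, col, path, line, cast):
    val = df_row[col]
    if pd.isna(val) or val == "":
        raise ParseError(path, line, f"missing required field '{col}'")
    try:
        return cast(val)
    except (TypeError, ValueError) as exc:
        raise ParseError(path, line, f"bad value for '{col}': {val!r}") from exc


def _parse_split_read(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        vclass = VariantClass(_req(row, "svclass", path, line, str))
        reads = _req(row, "num_reads", path, line, int)
        summed = _req(row, "sum_mapq", path, line, float)
        cid = row["call_id"]
        if vclass is VariantClass.INTER_TRANSLOCATION:
            c1 = _req(row, "chrom", path, line, str)
            p1 = _req(row, "start", path, line, int)
            c2 = _req(row, "chrom2", path, line, str)
            p2 = _req(row, "pos2", path, line, int)
            calls.append(VariantCall(
                caller=Caller.SPLIT_READ, vclass=vclass,
                breakpoints=tuple(sorted([(c1, p1), (c2, p2)])),
                call_id=cid, num_reads=reads, sum_mapq=summed))
        else:
            chrom = _req(row, "chrom", path, line, str)
            start = _req(row, "start", path, line, int)
            end = _req(row, "end", path, line, int)
            length = _req(row, "length", path, line, int)
            calls.append(VariantCall(
                caller=Caller.SPLIT_READ, vclass=vclass,
                interval=Interval(chrom, start, end), length=length,
                call_id=cid, num_reads=reads, sum_mapq=summed))
    return calls


def _parse_read_pair(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for i, row in df.iterrows():
        line = i + 2
        vclass = VariantClass(_req(row, "svclass", path, line, str))
        conf = _req(row, "confidence", path, line, float)
        pairs = _req(row, "num_pairs", path, line, int)
        cid = row["call_id"]
        c1 = _req(row, "chrom1", path, line, str)
        p1 = _req(row, "pos1", path, line, int)
        c2 = _req(row, "chrom2", path, line, str)
        p2 = _req(row, "pos2", path, line, int)
        if vclass is VariantClass.INTER_TRANSLOCATION:
            calls.append(VariantCall(
                caller=Caller.READ_PAIR, vclass=vclass,
                breakpoints=tuple(sorted([(c1, p1), (c2, p2)])),
                call_id=cid, confidence=conf, num_pairs=pairs))
            continue
        if c1 != c2:
            raise ParseError(path, line, f"{vclass.value} spans two chromosomes")
        size = _req(row, "size", path, line, int)
        bd = None
        if vclass is VariantClass.INSERTION:
            bd = _req(row, "bp_distance", path, line, int)
            iv = Interval(c1, p1, p1 + 1)
        else:
            iv = Interval(c1, p1, p2)
        calls.append(VariantCall(
            caller=Caller.READ_PAIR, vclass=vclass, interval=iv, length=size,
            call_id=cid, confidence=conf, num_pairs=pairs, bp_distance=bd))
    return calls


def _parse_cnv_table(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for i, row in df.iterrows():
        line = i + 2
        chrom = _req(row, "chrom", path, line, str)
        start = _req(row, "start", path, line, int)
        end = _req(row, "end", path, line, int)
        cn = _req(row, "copy_number", path, line, int)
        p1 = _req(row, "pval1", path, line, float)
        p2 = _req(row, "pval2", path, line, float)
        q0 = _req(row, "q0", path, line, float)
        vclass = VariantClass.DELETION if cn < 4 else VariantClass.DUPLICATION
        calls.append(VariantCall(
            caller=Caller.READ_DEPTH, vclass=vclass,
            interval=Interval(chrom, start, end), length=end - start,
            call_id=row["call_id"], copy_number=cn, pvalues=(p1, p2), q0=q0))
    return calls


def read_bed(path: str | Path) -> list[Interval]:
    """Plain 3+ column BED into intervals."""
    out = []
    with open(path) as fh:
        for i, raw in enumerate(fh):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, i + 1, "BED needs >= 3 columns")
            out.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

class FilterResult:
    """Retained calls plus per-call removal reasons for the run report."""

    def __init__(self, retained: list[VariantCall], removed: list[tuple[VariantCall, str]]):
        self.retained = retained
        self.removed = removed

    def __iter__(self):
        return iter(self.retained)


def filter_split_read_calls(calls: Iterable[VariantCall],
                            thresholds: QCThresholds | None = None) -> FilterResult:
    """Keep split-read calls with enough supporting reads and mapping score.

    Retained iff reads >= 2 AND summed score >= 100 AND mean score > 10
    (mean strictly greater, per the published rule)."""
    t = thresholds or QCThresholds()
    retained, removed = [], []
    for c in calls:
        if c.num_reads is None or c.sum_mapq is None:
            removed.append((c, "unscorable"))
            continue
        if c.num_reads < t.min_supporting_reads:
            removed.append((c, "supporting_reads"))
        elif c.sum_mapq < t.min_summed_mapq:
            removed.append((c, "summed_mapq"))
        elif not (c.mean_mapq is not None and c.mean_mapq > t.min_mean_mapq_exclusive):
            removed.append((c, "mean_mapq"))
        else:
            retained.append(c)
    return FilterResult(retained, removed)


def filter_read_pair_calls(calls: Iterable[VariantCall],
                           thresholds: QCThresholds | None = None) -> FilterResult:
    """Keep read-pair calls with confidence >= 80 and >= 4 supporting pairs;
    insertion calls whose breakpoint distance exceeds the insertion size are
    additionally removed."""
    t = thresholds or QCThresholds()
    retained, removed = [], []
    for c in calls:
        if c.confidence is None or c.num_pairs is None:
            removed.append((c, "unscorable"))
            continue
        if c.confidence < t.min_confidence:
            removed.append((c, "confidence"))
        elif c.num_pairs < t.min_read_pairs:
            removed.append((c, "read_pairs"))
        elif (c.vclass is VariantClass.INSERTION and c.bp_distance is not None
              and c.length is not None and c.bp_distance > c.length):
            removed.append((c, "breakpoint_distance"))
        else:
            retained.append(c)
    return FilterResult(retained, removed)


def filter_cnv_calls(calls: Iterable[VariantCall],
                     thresholds: QCThresholds | None = None) -> FilterResult:
    """Remove CNV calls when either t-test p-value is >= 0.01 or the
    zero-mapping-quality fraction is >= 0.5 (both bounds inclusive on the
    removal side)."""
    t = thresholds or QCThresholds()
    retained, removed = [], []
    for c in calls:
        if c.pvalues is None or c.q0 is None:
            removed.append((c, "unscorable"))
            continue
        if not (c.pvalues[0] < t.max_cnv_pvalue_exclusive
                and c.pvalues[1] < t.max_cnv_pvalue_exclusive):
            removed.append((c, "t_test_pvalue"))
        elif not c.q0 < t.max_q0_exclusive:
            removed.append((c, "q0_fraction"))
        else:
            retained.append(c)
    return FilterResult(retained, removed)


def mask_gap_regions(calls: Iterable[VariantCall],
                     gaps: Sequence[Interval]) -> FilterResult:
    """Remove calls overlapping centromeric/telomeric gap intervals by at
    least one base.  Inter-chromosomal translocations are exempt."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in gaps:
        trees[g.chrom].addi(g.start, g.end)
    retained, removed = [], []
    for c in calls:
        if c.vclass is VariantClass.INTER_TRANSLOCATION:
            retained.append(c)
            continue
        iv = c.interval
        if iv is not None and trees[iv.chrom].overlap(iv.start, iv.end):
            removed.append((c, "gap_overlap"))
        else:
            retained.append(c)
    return FilterResult(retained, removed)


def split_by_length(calls: Iterable[VariantCall],
                    cutoff: int | None = None) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition indel calls into (short, long) at the 50 bp cutoff.

    Length >= 50 is "long", matching the NCBI structural-variant convention
    for the smallest SV.
    """
    cut = QCThresholds().short_long_cutoff if cutoff is None else cutoff
    short, long_ = [], []
    for c in calls:
        if c.vclass not in (VariantClass.DELETION, VariantClass.INSERTION):
            raise ContractViolation(f"split_by_length expects indels, got {c.vclass.value}")
        if c.length is None:
            raise ContractViolation(f"call {c.call_id} has no length")
        (long_ if c.length >= cut else short).append(c)
    return short, long_


# ---------------------------------------------------------------------------
# Within-caller merging
# ---------------------------------------------------------------------------

def _cluster_calls(calls: list[VariantCall], predicate) -> list[list[VariantCall]]:
    calls = sorted(calls, key=sort_key)
    edges = [(i, j) for i in range(len(calls)) for j in range(i + 1, len(calls))
             if predicate(calls[i], calls[j])]
    return [[calls[i] for i in comp] for comp in connected_components(len(calls), edges)]


def _merge_cluster(cluster: list[VariantCall]) -> VariantCall:
    """Representative call for a merged cluster: union interval, longest
    insert length for insertions, provenance ids concatenated."""
    first = cluster[0]
    if len(cluster) == 1:
        return first
    ids = ",".join(c.call_id for c in cluster)
    if first.vclass is VariantClass.INSERTION:
        best = max(cluster, key=lambda c: (c.length or 0))
        return replace(best, call_id=ids)
    if first.interval is not None:
        iv = union_interval([c.interval for c in cluster])
        return replace(first, interval=iv, length=len(iv), call_id=ids)
    # translocations: keep the leftmost breakpoint pair as representative
    best = min(cluster, key=sort_key)
    return replace(best, call_id=ids)


def within_caller_merge(calls: Sequence[VariantCall],
                        thresholds: QCThresholds | None = None) -> list[VariantCall]:
    """Merge redundant calls from a single caller and single class.

    * split-read insertions: merged on direct overlap (an insertion occupies
      the point interval ``[pos, pos+1)``), keeping the longest insertion
      length;
    * split-read inter-chromosomal translocations: collapsed to one record
      per chromosome pair;
    * read-pair inter-chromosomal translocations: clustered when both
      breakpoints are less than 1000 bp apart;
    * everything else: merged when adjacent or overlapping.

    Clusters are transitive closures of the pairwise rule.
    """
    calls = list(calls)
    if not calls:
        return []
    callers = {c.caller for c in calls}
    classes = {c.vclass for c in calls}
    if len(callers) != 1 or len(classes) != 1:
        raise ContractViolation(
            f"within_caller_merge needs one caller and one class, got {callers}, {classes}")
    caller, vclass = callers.pop(), classes.pop()
    t = thresholds or QCThresholds()

    if vclass is VariantClass.INTER_TRANSLOCATION:
        if caller is Caller.SPLIT_READ:
            pred = lambda a, b: ({a.breakpoints[0][0], a.breakpoints[1][0]}
                                 == {b.breakpoints[0][0], b.breakpoints[1][0]})
        else:
            pred = lambda a, b: breakpoint_distance_match(
                a.breakpoints, b.breakpoints, t.translocation_max_bp_distance)
    elif vclass is VariantClass.INSERTION:
        pred = lambda a, b: any_overlap(a.interval, b.interval)
    else:
        pred = lambda a, b: adjacent_or_overlapping(a.interval, b.interval)

    return [_merge_cluster(cl) for cl in _cluster_calls(calls, pred)]


# ---------------------------------------------------------------------------
# Small-variant summary statistics
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def variant_summary_stats(calls: Iterable[VariantCall]) -> dict[str, Optional[float]]:
    """Homozygous/heterozygous ratio over all genotyped loci and Ts/Tv ratio
    over substitutions.

    A locus is homozygous when all four alleles are identical and
    non-reference; any other genotype with at least one alternate allele is
    heterozygous.  Ratios with a zero denominator are reported as ``None``.
    """
    hom = het = ts = tv = 0
    for c in calls:
        gt = c.genotype
        if gt is not None and any(a != 0 for a in gt):
            if c.is_homozygous_alt:
                hom += 1
            else:
                het += 1
        if c.vclass is VariantClass.SUBSTITUTION and c.ref and c.alt:
            if (c.ref.upper(), c.alt.upper()) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return {
        "hom": hom, "het": het, "ts": ts, "tv": tv,
        "hom_het_ratio": hom / het if het else None,
        "ts_tv_ratio": ts / tv if tv else None,
    }
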