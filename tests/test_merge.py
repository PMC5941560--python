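"""Cross-caller merge engine against a brute-force oracle, plus the
homozygous-deletion filter/swap pipeline and contribution accounting."""

import dataclasses

import numpy as np
import pytest

from tetramerge.calls import Caller, MergedLocus, VariantCall, VariantClass
from tetramerge.intervals import Interval
from tetramerge.merge import (hierarchical_merge, merge_homozygous_deletions,
                              merge_insertions, merge_translocations,
                              passthrough_loci, summarize_contributions)


def call(caller, start, end, vclass=VariantClass.DELETION, cid="", chrom="c", length=None):
    return VariantCall(caller=caller, vclass=vclass,
                       interval=Interval(chrom, start, end),
                       length=length if length is not None else end - start,
                       call_id=cid or f"{caller.value}-{start}-{end}")


# ---------------------------------------------------------------------------
# Brute-force oracle: fixpoint pairwise merging, exhaustive drop checks.
# Deliberately a different algorithm from the union-find implementation.
# ---------------------------------------------------------------------------

def brute_adjacent(a, b):
    return a[0] <= b[1] and b[0] <= a[1]


def brute_union_merge(spans):
    """Repeatedly merge the first adjacent-or-overlapping pair until stable."""
    spans = [list(s) for s in spans]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                if brute_adjacent(spans[i], spans[j]):
                    spans[i] = [min(spans[i][0], spans[j][0]),
                                max(spans[i][1], spans[j][1])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(s) for s in spans)


def brute_rule(a, b, vclass):
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if vclass in (VariantClass.DUPLICATION, VariantClass.INVERSION):
        return ov > 0 and (ov >= 0.25 * (a[1] - a[0]))
    return ov > 0 and ov >= 0.25 * (a[1] - a[0]) and ov >= 0.25 * (b[1] - b[0])


def brute_three_stage(t1, t2, t3, vclass):
    loci = brute_union_merge(t1)
    for tier in (t2, t3):
        keep = [s for s in tier if not any(brute_rule(s, l, vclass) for l in loci)]
        loci = brute_union_merge(list(loci) + keep)
    return loci


def random_spans(rng, n, lo=0, hi=5000, max_len=400):
    out = []
    for _ in range(n):
        s = int(rng.integers(lo, hi))
        out.append((s, s + int(rng.integers(1, max_len))))
    return out


@pytest.mark.parametrize("vclass", [VariantClass.DELETION, VariantClass.DUPLICATION])
def test_hierarchical_merge_equals_brute_force_on_random_instances(vclass):
    rng = np.random.default_rng(2024)
    for trial in range(200):
        t1 = random_spans(rng, int(rng.integers(0, 20)))
        t2 = random_spans(rng, int(rng.integers(0, 20)))
        t3 = random_spans(rng, int(rng.integers(0, 20)))
        calls1 = [call(Caller.SPLIT_READ, s, e, vclass, cid=f"a{i}")
                  for i, (s, e) in enumerate(t1)]
        calls2 = [call(Caller.READ_PAIR, s, e, vclass, cid=f"b{i}")
                  for i, (s, e) in enumerate(t2)]
        calls3 = [call(Caller.READ_DEPTH, s, e, vclass, cid=f"c{i}")
                  for i, (s, e) in enumerate(t3)]
        got = hierarchical_merge(calls1, calls2, calls3, vclass=vclass)
        spans = sorted((m.interval.start, m.interval.end) for m in got)
        assert spans == brute_three_stage(t1, t2, t3, vclass), f"trial {trial}"


def test_precedence_examples():
    sr = [call(Caller.SPLIT_READ, 0, 100)]
    rp_overlapping = [call(Caller.READ_PAIR, 50, 150)]   # reciprocal 50%
    rp_far = [call(Caller.READ_PAIR, 500, 600)]
    merged = hierarchical_merge(sr, rp_overlapping)
    assert [(m.interval.start, m.interval.end) for m in merged] == [(0, 100)]
    assert merged[0].callers == frozenset({Caller.SPLIT_READ})
    merged = hierarchical_merge(sr, rp_far)
    assert len(merged) == 2
    assert {frozenset(m.callers) for m in merged} == {
        frozenset({Caller.SPLIT_READ}), frozenset({Caller.READ_PAIR})}


def test_merge_is_idempotent_and_loci_disjoint():
    rng = np.random.default_rng(7)
    calls1 = [call(Caller.SPLIT_READ, s, e, cid=f"a{i}")
              for i, (s, e) in enumerate(random_spans(rng, 30))]
    calls2 = [call(Caller.READ_PAIR, s, e, cid=f"b{i}")
              for i, (s, e) in enumerate(random_spans(rng, 30))]
    merged = hierarchical_merge(calls1, calls2)
    spans = sorted((m.interval.start, m.interval.end) for m in merged)
    # output loci pairwise non-adjacent, non-overlapping
    assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
    # feeding the merged loci back through changes nothing
    as_calls = [call(Caller.SPLIT_READ, s, e, cid=f"m{i}")
                for i, (s, e) in enumerate(spans)]
    again = hierarchical_merge(as_calls)
    assert sorted((m.interval.start, m.interval.end) for m in again) == spans


def test_no_retained_lower_tier_call_overlaps_a_backbone_locus():
    rng = np.random.default_rng(13)
    calls1 = [call(Caller.SPLIT_READ, s, e, cid=f"a{i}")
              for i, (s, e) in enumerate(random_spans(rng, 25))]
    calls2 = [call(Caller.READ_PAIR, s, e, cid=f"b{i}")
              for i, (s, e) in enumerate(random_spans(rng, 25))]
    backbone = hierarchical_merge(calls1)
    merged = hierarchical_merge(calls1, calls2)
    kept_rp = [m for m in merged if Caller.READ_PAIR in m.callers]
    from tetramerge.intervals import reciprocal_match
    for m in kept_rp:
        for b in backbone:
            # any read-pair-bearing locus reciprocally matching the backbone
            # must actually contain backbone calls (i.e. was union-merged,
            # not a surviving dropped call)
            if reciprocal_match(m.interval, b.interval, 0.25):
                assert Caller.SPLIT_READ in m.callers


def test_conservation_every_call_dropped_or_assigned_once():
    rng = np.random.default_rng(99)
    calls1 = [call(Caller.SPLIT_READ, s, e, cid=f"a{i}")
              for i, (s, e) in enumerate(random_spans(rng, 20))]
    calls2 = [call(Caller.READ_PAIR, s, e, cid=f"b{i}")
              for i, (s, e) in enumerate(random_spans(rng, 20))]
    merged = hierarchical_merge(calls1, calls2)
    assert len(merged) <= len(calls1) + len(calls2)
    assigned = [cid for m in merged for cid in m.source_ids]
    assert len(assigned) == len(set(assigned))
    # every tier-1 call is assigned to exactly one locus
    for c in calls1:
        assert sum(c.call_id in m.source_ids for m in merged) == 1


def test_insertion_merge_overlap_only_no_hierarchy():
    a = VariantCall(caller=Caller.SMALL_VARIANT, vclass=VariantClass.INSERTION,
                    interval=Interval("c", 100, 101), length=5, call_id="a")
    b = dataclasses.replace(a, caller=Caller.SPLIT_READ, length=9, call_id="b")
    c = dataclasses.replace(a, interval=Interval("c", 101, 102), length=3, call_id="c")
    merged = merge_insertions([a], [b, c])
    assert len(merged) == 2            # 100 and 101 are separate loci
    big = next(m for m in merged if m.interval.start == 100)
    assert big.callers == frozenset({Caller.SMALL_VARIANT, Caller.SPLIT_READ})
    assert big.length == 9


def test_translocation_cross_caller_merge():
    def t(caller, p1, p2, cid):
        return VariantCall(caller=caller, vclass=VariantClass.INTER_TRANSLOCATION,
                           breakpoints=(("chr1", p1), ("chr2", p2)), call_id=cid)
    merged = merge_translocations(
        [t(Caller.SPLIT_READ, 1000, 5000, "a")],
        [t(Caller.READ_PAIR, 1500, 5400, "b"), t(Caller.READ_PAIR, 80_000, 5400, "c")])
    assert len(merged) == 2
    joint = next(m for m in merged if len(m.callers) == 2)
    assert joint.breakpoints == (("chr1", 1000), ("chr2", 5000))


# ---------------------------------------------------------------------------
# Homozygous deletions
# ---------------------------------------------------------------------------

def cn0(start, end, cid="cn0"):
    return VariantCall(caller=Caller.READ_DEPTH, vclass=VariantClass.DELETION,
                       interval=Interval("c", start, end), length=end - start,
                       call_id=cid, copy_number=0)


def gatk_sub(pos, cid="g"):
    return VariantCall(caller=Caller.SMALL_VARIANT, vclass=VariantClass.SUBSTITUTION,
                       interval=Interval("c", pos, pos + 1), length=1, call_id=cid,
                       genotype=(0, 1, 1, 1))


def test_cn0_overlapping_any_small_variant_call_is_removed():
    merged = merge_homozygous_deletions(
        [], [cn0(0, 10_000)], all_small_variant_calls=[gatk_sub(500)])
    assert merged == []


def test_cn0_swapped_for_precise_deletion_breakpoints():
    precise = call(Caller.SPLIT_READ, 10, 990, cid="p")   # 98% reciprocal
    merged = merge_homozygous_deletions([], [cn0(0, 1000)],
                                        split_read_deletions=[precise])
    assert [(m.interval.start, m.interval.end) for m in merged] == [(10, 990)]
    assert "replaced" in merged[0].provenance
    assert merged[0].callers == frozenset({Caller.READ_DEPTH, Caller.SPLIT_READ})


def test_cn0_not_swapped_at_exactly_half_reciprocal_overlap():
    # 50% reciprocal overlap: the rule is strictly greater than 50%
    cand = call(Caller.SPLIT_READ, 0, 500, cid="p")
    merged = merge_homozygous_deletions([], [cn0(0, 1000)],
                                        split_read_deletions=[cand])
    assert [(m.interval.start, m.interval.end) for m in merged] == [(0, 1000)]
    assert merged[0].provenance == ""


def test_best_swap_candidate_wins():
    c90 = call(Caller.READ_PAIR, 50, 950, cid="rp90")     # 90% reciprocal
    c98 = call(Caller.SPLIT_READ, 10, 990, cid="sr98")    # 98% reciprocal
    merged = merge_homozygous_deletions([], [cn0(0, 1000)],
                                        split_read_deletions=[c98],
                                        read_pair_deletions=[c90])
    assert merged[0].source_ids[-1] == "sr98"
    # enumerate: best reciprocal fraction among candidates
    fracs = {"rp90": 900 / 1000, "sr98": 980 / 1000}
    assert max(fracs, key=fracs.get) == "sr98"


def test_swapped_and_small_variant_homdels_merge_adjacently():
    sv = VariantCall(caller=Caller.SMALL_VARIANT, vclass=VariantClass.DELETION,
                     interval=Interval("c", 2000, 2030), length=30, call_id="svh",
                     genotype=(1, 1, 1, 1))
    merged = merge_homozygous_deletions([sv], [cn0(0, 1000)])
    assert len(merged) == 2
    assert {m.source_ids[0] for m in merged} == {"svh", "cn0"}


# ---------------------------------------------------------------------------
# Contribution accounting
# ---------------------------------------------------------------------------

def test_contribution_summary_single_and_identical_callsets():
    a = [call(Caller.SPLIT_READ, 0, 100, cid="a1"),
         call(Caller.SPLIT_READ, 500, 600, cid="a2")]
    merged = hierarchical_merge(a)
    df = summarize_contributions("long_deletion", {Caller.SPLIT_READ: a}, merged,
                                 VariantClass.DELETION)
    assert df.loc[0, "overlap_fraction"] == 0.0
    assert df.loc[0, "merged_total"] == 2

    b = [dataclasses.replace(c, caller=Caller.READ_PAIR, call_id=c.call_id + "b")
         for c in a]
    merged = hierarchical_merge(a, b)
    df = summarize_contributions("long_deletion",
                                 {Caller.SPLIT_READ: a, Caller.READ_PAIR: b},
                                 merged, VariantClass.DELETION)
    assert set(df["overlap_fraction"]) == {1.0}
    assert (df["fraction_of_merged"] <= 1.0).all()
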