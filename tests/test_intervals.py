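"""Interval-algebra primitives against a per-base brute-force oracle."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetramerge.intervals import (Interval, adjacent_or_overlapping,
                                  breakpoint_distance_match, oneway_match,
                                  overlap_bp, reciprocal_match, union_interval)


def brute_overlap(a: Interval, b: Interval) -> int:
    """Count shared bases one at a time."""
    if a.chrom != b.chrom:
        return 0
    return sum(1 for x in range(a.start, a.end) if b.start <= x < b.end)


@pytest.mark.parametrize("a,b,expected", [
    (Interval("c", 0, 100), Interval("c", 50, 150), 50),
    (Interval("c", 0, 100), Interval("c", 100, 200), 0),   # half-open: bookended
    (Interval("c", 0, 100), Interval("d", 0, 100), 0),     # different chromosome
    (Interval("c", 10, 20), Interval("c", 0, 100), 10),    # containment
])
def test_overlap_bp_examples(a, b, expected):
    assert overlap_bp(a, b) == expected
    assert overlap_bp(b, a) == expected


intervals = st.tuples(st.integers(0, 300), st.integers(1, 80)).map(
    lambda t: Interval("c", t[0], t[0] + t[1]))


@given(intervals, intervals)
def test_overlap_matches_per_base_oracle(a, b):
    assert overlap_bp(a, b) == brute_overlap(a, b)


@given(intervals, intervals, st.sampled_from([0.25, 0.5, 0.9]))
def test_fractional_rules_match_oracle(a, b, f):
    ov = brute_overlap(a, b)
    assert reciprocal_match(a, b, f) == (ov >= f * len(a) and ov >= f * len(b) and ov > 0)
    assert oneway_match(a, b, f) == (ov > 0 and ov >= f * len(a))
    # strict variants
    assert reciprocal_match(a, b, f, strict=True) == (
        ov > f * len(a) and ov > f * len(b))


def test_reciprocal_is_symmetric_oneway_is_not():
    a, b = Interval("c", 0, 100), Interval("c", 0, 1000)
    assert reciprocal_match(a, b, 0.25) == reciprocal_match(b, a, 0.25) is False
    assert oneway_match(a, b, 0.25)      # all of a covered
    assert not oneway_match(b, a, 0.25)  # only 10% of b covered


def test_ninety_percent_rule_arithmetic():
    # overlap 95 of [0,100) vs [5,100): 95 >= 90 and >= 85.5
    assert reciprocal_match(Interval("c", 0, 100), Interval("c", 5, 100), 0.90)


def test_adjacency_is_bookended_only():
    assert adjacent_or_overlapping(Interval("c", 0, 100), Interval("c", 100, 150))
    assert not adjacent_or_overlapping(Interval("c", 0, 100), Interval("c", 101, 150))
    assert adjacent_or_overlapping(Interval("c", 0, 100), Interval("c", 50, 150))


def test_breakpoint_distance_rule():
    a = (("chr1", 1000), ("chr2", 5000))
    b = (("chr1", 1800), ("chr2", 5600))   # distances 800 and 600
    c = (("chr1", 2100), ("chr2", 5600))   # 1100: too far
    d = (("chr1", 1000), ("chr3", 5000))   # different chromosome pair
    assert breakpoint_distance_match(a, b, 1000)
    assert not breakpoint_distance_match(a, c, 1000)
    assert not breakpoint_distance_match(a, d, 1000)
    # order of the pair does not matter
    assert breakpoint_distance_match(tuple(reversed(a)), b, 1000)


def test_union_interval_rejects_mixed_chromosomes():
    with pytest.raises(ValueError):
        union_interval([Interval("c", 0, 10), Interval("d", 0, 10)])
    u = union_interval([Interval("c", 5, 10), Interval("c", 0, 7)])
    assert (u.start, u.end) == (0, 10)


def test_degenerate_interval_rejected():
    with pytest.raises(ValueError):
        Interval("c", 10, 10)
    with pytest.raises(ValueError):
        Interval("c", -1, 5)
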