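"""Damaged-gene selection and the hypergeometric enrichment test, checked
against exact combinatorial enumeration."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from tetramerge.calls import Caller, MergedLocus, VariantClass
from tetramerge.enrich import (EffectAnnotation, GeneSet, enrich_gene_sets,
                               genes_under_homdel, hypergeom_tail,
                               select_rare_high_impact, union_damaged_genes)
from tetramerge.intervals import Interval


def exact_tail(k, K, n, N) -> Fraction:
    """Exhaustive-enumeration oracle: sum the exact probability of every
    draw outcome with k or more set members, with integer arithmetic."""
    total = comb(N, n)
    return Fraction(sum(comb(K, j) * comb(N - K, n - j)
                        for j in range(k, min(K, n) + 1)), total)


# --- damaged-gene selection -------------------------------------------------

@pytest.mark.parametrize("effect,maf,selected", [
    ("stop_gained", 0.0005, True),
    ("frameshift", 0.001, False),      # strict < cutoff
    ("missense", 0.0, False),          # not high impact
    ("splice_donor", None, True),      # no population record: treated as rare
    ("exon_loss", 0.5, False),
])
def test_rare_high_impact_selection(effect, maf, selected):
    ann = EffectAnnotation("v1", "geneA", effect, maf)
    assert (select_rare_high_impact([ann]) == ["GENEA"]) is selected


def test_rare_high_impact_deduplicates_genes():
    anns = [EffectAnnotation(f"v{i}", "TP53", "stop_gained", None) for i in range(3)]
    assert select_rare_high_impact(anns) == ["TP53"]


def homdel(start, end, chrom="c"):
    return MergedLocus(vclass=VariantClass.DELETION,
                       interval=Interval(chrom, start, end),
                       callers=frozenset({Caller.READ_DEPTH}), source_ids=("x",))


def test_genes_under_homdel_requires_coding_exon_overlap():
    exons = {"A": [Interval("c", 100, 200)],
             "B": [Interval("c", 5000, 5100)],
             "C": [Interval("d", 100, 200)]}
    assert genes_under_homdel([homdel(150, 400)], exons) == ["A"]
    assert genes_under_homdel([homdel(300, 400)], exons) == []   # intronic only


def test_union_damaged_genes_counts():
    assert union_damaged_genes(["a", "B"], ["b", "C"]) == ["A", "B", "C"]
    # the catalog arithmetic: 678 + 129 sharing 26 -> 781 unique
    l1 = [f"g{i}" for i in range(678)]
    l2 = [f"g{i}" for i in range(652, 781)]
    assert len(set(l1) & set(l2)) == 26
    assert len(union_damaged_genes(l1, l2)) == 781


# --- hypergeometric tail ----------------------------------------------------

def test_tail_examples():
    assert hypergeom_tail(0, 5, 4, 10) == 1.0
    # N=10, K=5, n=4, k=3: 55 favorable draws of C(10,4)=210
    assert exact_tail(3, 5, 4, 10) == Fraction(55, 210)
    assert hypergeom_tail(3, 5, 4, 10) == pytest.approx(55 / 210, rel=1e-12)


def test_tail_matches_exact_enumeration_small_universes():
    rng = np.random.default_rng(1)
    for _ in range(300):
        N = int(rng.integers(1, 26))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeom_tail(k, K, n, N) == pytest.approx(
            float(exact_tail(k, K, n, N)), rel=1e-10, abs=1e-300)


def test_pmf_normalizes():
    for (K, n, N) in [(5, 4, 10), (12, 7, 20), (3, 3, 6)]:
        total = sum(exact_tail(k, K, n, N) - exact_tail(k + 1, K, n, N)
                    if k < min(K, n) else exact_tail(k, K, n, N)
                    for k in range(min(K, n) + 1))
        assert total == 1


def test_tail_strictly_decreases_in_k():
    ps = [hypergeom_tail(k, 1009, 781, 26802) for k in range(0, 80)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_impossible_margins_rejected():
    with pytest.raises(ValueError):
        hypergeom_tail(6, 5, 4, 10)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 11, 4, 10)


# --- gene-set enrichment ----------------------------------------------------

def test_small_sets_excluded_and_ranking_ascending():
    damaged = [f"g{i}" for i in range(40)]
    sets = [
        GeneSet("SMALL", "", [f"g{i}" for i in range(49)]),
        GeneSet("HIT", "", [f"g{i}" for i in range(30)] + [f"x{i}" for i in range(40)]),
        GeneSet("MISS", "", [f"y{i}" for i in range(80)]),
    ]
    results = enrich_gene_sets(damaged, sets, background=2000)
    assert [r.set_name for r in results] == ["HIT", "MISS"]
    assert results[0].overlap == 30
    assert results[0].p_value < results[1].p_value
    assert results[1].overlap == 0 and results[1].p_value == 1.0


def test_empty_damaged_set_gives_p_one():
    sets = [GeneSet("S", "", [f"g{i}" for i in range(60)])]
    (r,) = enrich_gene_sets([], sets, background=1000)
    assert r.p_value == 1.0 and r.overlap == 0


def test_bh_adjustment_is_monotone_and_bounded():
    rng = np.random.default_rng(0)
    damaged = [f"g{i}" for i in range(50)]
    sets = [GeneSet(f"S{j}", "", [f"g{i}" for i in rng.choice(500, 60, replace=False)])
            for j in range(20)]
    results = enrich_gene_sets(damaged, sets, background=500)
    adj = [r.p_adjusted for r in results]
    assert all(0 < a <= 1 for a in adj)
    assert all(x <= y + 1e-15 for x, y in zip(adj, adj[1:]))
    assert all(r.p_adjusted >= r.p_value - 1e-15 for r in results)
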