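"""Integer-CN assignment, segment classification, modal CN and the
genome-fraction histogram."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetramerge.cnv import (CopyNumberProfile, assign_integer_cn,
                            classify_cn_segments, cn_genome_fraction_histogram,
                            modal_copy_number, read_depth_bedgraph)
from tetramerge.synth import SimulationConfig, TruthClass, emit_caller_callsets, simulate_truth


@pytest.mark.parametrize("depth,cn", [
    (1.9, 4),     # 2d = 3.8 -> CN 4
    (0.2, 0),     # 2d = 0.4 -> CN 0
    (2.25, 5),    # 2d = 4.5: boundary assigned upward
    (0.0, 0),
    (0.25, 1),    # 2d = 0.5: boundary upward
    (3.0, 6),
])
def test_integer_cn_examples(depth, cn):
    assert assign_integer_cn(depth) == cn


def test_negative_depth_is_an_input_error():
    with pytest.raises(ValueError):
        assign_integer_cn(-0.1)


@given(st.lists(st.floats(0, 5), min_size=2, max_size=50))
def test_assignment_is_a_monotone_step_function(depths):
    xs = sorted(depths)
    cns = [assign_integer_cn(x) for x in xs]
    assert all(a <= b for a, b in zip(cns, cns[1:]))


def profile_from_cn(cn_list, bin_size=100):
    return CopyNumberProfile(bin_size=bin_size,
                             depths={"c": np.asarray(cn_list, dtype=float) / 2.0})


def test_segments_are_maximal_equal_cn_runs():
    prof = profile_from_cn([4, 4, 0, 0, 0, 4, 5, 5])
    segs = prof.segments()
    assert [(s.interval.start, s.interval.end, s.copy_number) for s in segs] == [
        (0, 200, 4), (200, 500, 0), (500, 600, 4), (600, 800, 5)]


def test_cn_class_predicates():
    prof = profile_from_cn([1, 0, 4, 5, 6])
    classes = classify_cn_segments(prof)
    assert {s.copy_number for s in classes["deletion"]} == {0, 1}
    assert {s.copy_number for s in classes["homozygous_deletion"]} == {0}
    assert {s.copy_number for s in classes["duplication"]} == {5, 6}
    # homozygous deletions are a subset of deletions; nothing is both
    # deletion and duplication
    del_ids = {id(s) for s in classes["deletion"]}
    assert all(id(s) in del_ids for s in classes["homozygous_deletion"])
    assert not ({s.copy_number for s in classes["deletion"]}
                & {s.copy_number for s in classes["duplication"]})


def test_modal_cn_on_tetraploid_profile_and_tie_break():
    rng = np.random.default_rng(0)
    cn = np.full(1000, 4)
    cn[:200] = rng.choice([0, 1, 2, 3, 5, 6], size=200)   # 80% of bases CN 4
    assert modal_copy_number(CopyNumberProfile(100, {"c": cn / 2.0})) == 4
    assert modal_copy_number(profile_from_cn([2] * 10)) == 2
    assert modal_copy_number(profile_from_cn([2] * 5 + [3] * 5)) == 2  # tie -> lower


def test_histogram_fractions():
    prof = profile_from_cn([4] * 9 + [0])
    hist = cn_genome_fraction_histogram(prof)
    assert hist == {0: pytest.approx(0.1), 4: pytest.approx(0.9)}
    assert sum(hist.values()) == pytest.approx(1.0, abs=1e-9)


@given(st.lists(st.integers(0, 7), min_size=1, max_size=200))
def test_histogram_sums_to_one_and_is_order_invariant(cns):
    h1 = cn_genome_fraction_histogram(profile_from_cn(cns))
    h2 = cn_genome_fraction_histogram(profile_from_cn(list(reversed(cns))))
    assert sum(h1.values()) == pytest.approx(1.0, abs=1e-9)
    assert h1 == h2


def test_noiseless_track_recovers_truth_cn_for_every_bin(tmp_path):
    cfg = SimulationConfig(
        chromosomes={"chrA": 1_000_000}, seed=5, telomere_bp=5_000,
        centromere_bp=20_000,
        variant_counts={**{tc: 0 for tc in TruthClass},
                        TruthClass.HOMOZYGOUS_DELETION: 3,
                        TruthClass.LONG_DELETION: 4,
                        TruthClass.DUPLICATION: 3}).noiseless()
    truth = simulate_truth(cfg)
    bundle = emit_caller_callsets(truth, tmp_path)
    prof = read_depth_bedgraph(bundle.depth_bedgraph, cfg.bin_size)
    recovered = prof.integer_cn()
    for chrom, arr in truth.cn_bins.items():
        assert np.array_equal(recovered[chrom], arr)
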