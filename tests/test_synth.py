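"""Synthetic-bundle generator: determinism, counts, noiseless limits,
manifest completeness."""

import json

import numpy as np
import pysam
import pytest

from tetramerge.calls import Caller
from tetramerge.synth import (SimulationConfig, SimulationSizeError, TruthClass,
                              emit_caller_callsets, simulate_truth)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        chromosomes={"chrA": 2_000_000, "chrB": 1_000_000},
        variant_counts={
            TruthClass.SUBSTITUTION: 40, TruthClass.SHORT_DELETION: 20,
            TruthClass.SHORT_INSERTION: 15, TruthClass.LONG_DELETION: 8,
            TruthClass.LONG_INSERTION: 6, TruthClass.DUPLICATION: 5,
            TruthClass.INVERSION: 4, TruthClass.INTRA_TRANSLOCATION: 3,
            TruthClass.INTER_TRANSLOCATION: 2, TruthClass.HOMOZYGOUS_DELETION: 6,
        },
        telomere_bp=5_000, centromere_bp=20_000, seed=7)
    base.update(overrides)
    return SimulationConfig(**base)


def test_zero_counts_gives_empty_truth_and_uniform_cn4():
    cfg = small_config(variant_counts={tc: 0 for tc in TruthClass})
    truth = simulate_truth(cfg)
    assert truth.variants == []
    for arr in truth.cn_bins.values():
        assert np.all(arr == 4)


def test_same_seed_reproduces_truth_exactly():
    a, b = simulate_truth(small_config()), simulate_truth(small_config())
    assert a.variants == b.variants
    for chrom in a.cn_bins:
        assert np.array_equal(a.cn_bins[chrom], b.cn_bins[chrom])


def test_emitted_files_byte_identical_across_runs(tmp_path):
    truth = simulate_truth(small_config())
    b1 = emit_caller_callsets(truth, tmp_path / "r1")
    b2 = emit_caller_callsets(truth, tmp_path / "r2")
    for name in ("small_variant_vcf", "split_read_tsv", "read_pair_tsv",
                 "depth_bedgraph", "cnv_tsv", "manifest"):
        assert getattr(b1, name).read_bytes() == getattr(b2, name).read_bytes()


def test_requested_counts_and_size_ranges_are_honored():
    cfg = small_config(
        chromosomes={"chrA": 10_000_000, "chrB": 1_000_000},
        variant_counts={**{tc: 0 for tc in TruthClass},
                        TruthClass.LONG_DELETION: 50},
        size_ranges={**SimulationConfig().size_ranges,
                     TruthClass.LONG_DELETION: (1_000, 10_000)})
    truth = simulate_truth(cfg)
    dels = truth.by_class(TruthClass.LONG_DELETION)
    assert len(dels) == 50
    assert all(1_000 <= len(v.interval) <= 10_000 + cfg.bin_size for v in dels)


def test_oversubscribed_chromosome_raises_sizing_error():
    cfg = small_config(
        chromosomes={"chrA": 60_000, "chrB": 55_000},
        variant_counts={**{tc: 0 for tc in TruthClass},
                        TruthClass.INVERSION: 500},
        telomere_bp=0, centromere_bp=0, modal_fraction_min=0.0)
    with pytest.raises(SimulationSizeError):
        simulate_truth(cfg)


def test_manifest_links_every_call_or_flags_false_positive(tmp_path):
    truth = simulate_truth(small_config())
    bundle = emit_caller_callsets(truth, tmp_path)
    rows = [json.loads(l) for l in bundle.manifest.read_text().splitlines()]
    truth_ids = {v.truth_id for v in truth.variants}
    assert rows, "manifest must not be empty"
    for row in rows:
        if row["false_positive"]:
            assert row["truth_id"] is None
        else:
            assert row["truth_id"] in truth_ids
    # call ids in the files equal the manifest exactly
    vcf_ids = [rec.id for rec in pysam.VariantFile(str(bundle.small_variant_vcf))]
    manifest_sv = [r["call_id"] for r in rows if r["caller"] == "small_variant"]
    assert vcf_ids == manifest_sv


def test_noiseless_breakpoints_equal_truth(tmp_path):
    cfg = small_config().noiseless()
    truth = simulate_truth(cfg)
    bundle = emit_caller_callsets(truth, tmp_path)
    by_id = {v.truth_id: v for v in truth.variants}
    rows = [json.loads(l) for l in bundle.manifest.read_text().splitlines()]
    linked = {r["call_id"]: r["truth_id"] for r in rows
              if r["caller"] == "read_pair" and r["truth_id"]}
    with open(bundle.read_pair_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            v = by_id[linked[row["call_id"]]]
            if v.interval is not None and row["svclass"] != "insertion":
                assert int(row["pos1"]) == v.interval.start
                assert int(row["pos2"]) == v.interval.end


def test_noiseless_depth_track_is_exact(tmp_path):
    cfg = small_config().noiseless()
    truth = simulate_truth(cfg)
    bundle = emit_caller_callsets(truth, tmp_path)
    expected = {c: arr / 2.0 for c, arr in truth.cn_bins.items()}
    seen = {c: [] for c in cfg.chromosomes}
    with open(bundle.depth_bedgraph) as fh:
        for line in fh:
            chrom, s, e, d = line.split("\t")
            seen[chrom].append(float(d))
    for chrom in expected:
        assert np.allclose(seen[chrom], expected[chrom], atol=0)
    # CN-0 truth segments read exactly 0.0
    homdels = [v for v in truth.by_class(TruthClass.HOMOZYGOUS_DELETION)
               if len(v.interval) >= cfg.bin_size]
    for v in homdels:
        b = cfg.bin_size
        assert all(x == 0.0 for x in
                   seen[v.interval.chrom][v.interval.start // b: v.interval.end // b])


def test_all_alt_truth_becomes_four_alt_allele_genotype(tmp_path):
    cfg = small_config().noiseless()
    truth = simulate_truth(cfg)
    bundle = emit_caller_callsets(truth, tmp_path)
    rows = [json.loads(l) for l in bundle.manifest.read_text().splitlines()]
    linked = {r["call_id"]: r["truth_id"] for r in rows
              if r["caller"] == "small_variant" and r["truth_id"]}
    by_id = {v.truth_id: v for v in truth.variants}
    n_checked = 0
    for rec in pysam.VariantFile(str(bundle.small_variant_vcf)):
        v = by_id[linked[rec.id]]
        gt = rec.samples["SAMPLE"]["GT"]
        assert len(gt) == 4
        assert sum(1 for a in gt if a != 0) == v.allele_count
        if v.allele_count == 4:
            assert gt == (1, 1, 1, 1)
            n_checked += 1
    assert n_checked > 0


def test_baseline_fraction_meets_modal_floor():
    truth = simulate_truth(small_config())
    assert truth.baseline_fraction() >= truth.config.modal_fraction_min
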