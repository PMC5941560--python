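"""End-to-end orchestration: simulate -> normalize -> cnv -> merge ->
annotate -> enrich, as one reproducible, seeded run.

Every stage is a pure function of (inputs, config, seed); the run report
records per-stage counts (parsed = retained + removed, with reasons), the
merged catalog per class, database match percentages, enrichment results,
and a sha256 checksum for every output file, so that two runs with the
same configuration are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cnv, dbmatch, enrich, io_qc, merge
from .calls import Caller, MergedLocus, QCThresholds, VariantCall, VariantClass
from .intervals import Interval
from .synth import SimulationConfig, TruthSet, emit_caller_callsets, simulate_truth
from .synthdb import DatabaseBundle, DatabaseConfig, emit_databases

logger = logging.getLogger(__name__)

#: the merged catalog's class groups, in reporting order
CLASS_GROUPS = (
    "substitution", "short_homozygous_deletion", "short_deletion",
    "short_insertion", "long_homozygous_deletion", "long_deletion",
    "long_insertion", "duplication", "inversion",
    "intra_translocation", "inter_translocation",
)


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    db: DatabaseConfig = field(default_factory=DatabaseConfig)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    out_dir: Path = Path("tetramerge_run")
    maf_cutoff: float = enrich.DEFAULT_MAF_CUTOFF
    min_set_size: int = enrich.DEFAULT_MIN_SET_SIZE

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class RunReport:
    config: RunConfig
    truth: TruthSet
    qc_counts: dict
    summary_stats: dict
    modal_cn: int
    cn_histogram: dict[int, float]
    cn_classes: dict[str, int]
    merged: dict[str, list[MergedLocus]]
    contributions: pd.DataFrame
    db_summary: pd.DataFrame
    clinvar_pathogenic: int
    array: dbmatch.ArrayComparison
    damaged_genes: list[str]
    enrichment: list[enrich.EnrichmentResult]
    checksums: dict[str, str]

    def merged_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.merged.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge_each(groups: dict[Caller, list[VariantCall]],
                thresholds: QCThresholds) -> dict[Caller, list[VariantCall]]:
    """Within-caller merge applied per caller (single class expected)."""
    return {c: io_qc.within_caller_merge(v, thresholds) if v else []
            for c, v in groups.items()}


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds

    # ---- stage 1: simulate -------------------------------------------------
    truth = simulate_truth(config.sim)
    bundle = emit_caller_callsets(truth, out / "callsets")
    dbs = emit_databases(truth, out / "databases", config.db)

    # ---- stage 2: parse + QC + mask ---------------------------------------
    gaps = io_qc.read_bed(bundle.gap_bed)
    sv_calls = io_qc.parse_callset(bundle.small_variant_vcf, Caller.SMALL_VARIANT)
    sr_raw = io_qc.parse_callset(bundle.split_read_tsv, Caller.SPLIT_READ)
    rp_raw = io_qc.parse_callset(bundle.read_pair_tsv, Caller.READ_PAIR)
    rd_raw = io_qc.parse_callset(bundle.cnv_tsv, Caller.READ_DEPTH)

    sr_qc = io_qc.filter_split_read_calls(sr_raw, t)
    rp_qc = io_qc.filter_read_pair_calls(rp_raw, t)
    rd_qc = io_qc.filter_cnv_calls(rd_raw, t)
    sr_mask = io_qc.mask_gap_regions(sr_qc.retained, gaps)
    rp_mask = io_qc.mask_gap_regions(rp_qc.retained, gaps)
    rd_mask = io_qc.mask_gap_regions(rd_qc.retained, gaps)

    def _reasons(res: io_qc.FilterResult) -> dict[str, int]:
        return dict(Counter(reason for _, reason in res.removed))

    qc_counts = {
        "small_variant": {"parsed": len(sv_calls), "retained": len(sv_calls),
                          "removed": {}},
        "split_read": {"parsed": len(sr_raw),
                       "retained": len(sr_mask.retained),
                       "removed": {**_reasons(sr_qc), **_reasons(sr_mask)}},
        "read_pair": {"parsed": len(rp_raw),
                      "retained": len(rp_mask.retained),
                      "removed": {**_reasons(rp_qc), **_reasons(rp_mask)}},
        "read_depth": {"parsed": len(rd_raw),
                       "retained": len(rd_mask.retained),
                       "removed": {**_reasons(rd_qc), **_reasons(rd_mask)}},
    }
    summary_stats = io_qc.variant_summary_stats(sv_calls)

    # ---- stage 3: copy-number profile -------------------------------------
    profile = cnv.read_depth_bedgraph(bundle.depth_bedgraph, config.sim.bin_size,
                                      config.sim.baseline_copy_number)
    modal = cnv.modal_copy_number(profile)
    histogram = cnv.cn_genome_fraction_histogram(profile)
    cn_classes = {k: len(v) for k, v in cnv.classify_cn_segments(profile).items()}

    # ---- stage 4: group calls by class and merge ---------------------------
    sv_subs = [c for c in sv_calls if c.vclass is VariantClass.SUBSTITUTION]
    sv_dels = [c for c in sv_calls if c.vclass is VariantClass.DELETION]
    sv_homdels = [c for c in sv_dels if c.is_homozygous_alt]
    sv_other_dels = [c for c in sv_dels if not c.is_homozygous_alt]
    sv_ins = [c for c in sv_calls if c.vclass is VariantClass.INSERTION]
    sv_short_del, sv_long_del = io_qc.split_by_length(sv_other_dels, t.short_long_cutoff)
    sv_short_ins, sv_long_ins = io_qc.split_by_length(sv_ins, t.short_long_cutoff)

    def pick(calls, vclass):
        return [c for c in calls if c.vclass is vclass]

    sr_dels = pick(sr_mask.retained, VariantClass.DELETION)
    sr_short_del, sr_long_del = io_qc.split_by_length(sr_dels, t.short_long_cutoff)
    sr_ins = pick(sr_mask.retained, VariantClass.INSERTION)
    sr_short_ins, sr_long_ins = io_qc.split_by_length(sr_ins, t.short_long_cutoff)
    rp_dels = pick(rp_mask.retained, VariantClass.DELETION)
    rp_short_del, rp_long_del = io_qc.split_by_length(rp_dels, t.short_long_cutoff)
    rp_ins = pick(rp_mask.retained, VariantClass.INSERTION)
    _, rp_long_ins = io_qc.split_by_length(rp_ins, t.short_long_cutoff)

    # read-depth roles: CN 0 feeds the homozygous-deletion pipeline, CN 1 the
    # long-deletion merge, CN >= 5 duplications; single-copy losses (CN 2-3 on
    # the tetraploid background) are counted in the CN summary only.
    rd_cn0 = [c for c in rd_mask.retained if c.copy_number == 0]
    rd_del1 = [c for c in rd_mask.retained if c.copy_number == 1]
    rd_dups = [c for c in rd_mask.retained
               if c.copy_number >= config.sim.baseline_copy_number + 1]

    wm = lambda calls: io_qc.within_caller_merge(calls, t) if calls else []

    per_caller_inputs: dict[str, dict[Caller, list[VariantCall]]] = {
        "short_deletion": {Caller.SMALL_VARIANT: wm(sv_short_del),
                           Caller.SPLIT_READ: wm(sr_short_del),
                           Caller.READ_PAIR: wm(rp_short_del)},
        "long_deletion": {Caller.SMALL_VARIANT: wm(sv_long_del),
                          Caller.SPLIT_READ: wm(sr_long_del),
                          Caller.READ_PAIR: wm(rp_long_del),
                          Caller.READ_DEPTH: wm(rd_del1)},
        "short_insertion": {Caller.SMALL_VARIANT: wm(sv_short_ins),
                            Caller.SPLIT_READ: wm(sr_short_ins)},
        "long_insertion": {Caller.SMALL_VARIANT: wm(sv_long_ins),
                           Caller.SPLIT_READ: wm(sr_long_ins),
                           Caller.READ_PAIR: wm(rp_long_ins)},
        "duplication": {Caller.SPLIT_READ: wm(pick(sr_mask.retained,
                                                   VariantClass.DUPLICATION)),
                        Caller.READ_DEPTH: wm(rd_dups)},
        "inversion": {Caller.SPLIT_READ: wm(pick(sr_mask.retained,
                                                 VariantClass.INVERSION)),
                      Caller.READ_PAIR: wm(pick(rp_mask.retained,
                                                VariantClass.INVERSION))},
        "intra_translocation": {Caller.READ_PAIR: wm(pick(rp_mask.retained,
                                                          VariantClass.INTRA_TRANSLOCATION))},
        "inter_translocation": {Caller.SPLIT_READ: wm(pick(sr_mask.retained,
                                                           VariantClass.INTER_TRANSLOCATION)),
                                Caller.READ_PAIR: wm(pick(rp_mask.retained,
                                                          VariantClass.INTER_TRANSLOCATION))},
    }

    pci = per_caller_inputs
    merged: dict[str, list[MergedLocus]] = {}
    merged["substitution"] = merge.passthrough_loci(sv_subs, VariantClass.SUBSTITUTION)
    merged["short_deletion"] = merge.hierarchical_merge(
        pci["short_deletion"][Caller.SMALL_VARIANT] + pci["short_deletion"][Caller.SPLIT_READ],
        pci["short_deletion"][Caller.READ_PAIR], vclass=VariantClass.DELETION)
    merged["long_deletion"] = merge.hierarchical_merge(
        pci["long_deletion"][Caller.SMALL_VARIANT] + pci["long_deletion"][Caller.SPLIT_READ],
        pci["long_deletion"][Caller.READ_PAIR],
        pci["long_deletion"][Caller.READ_DEPTH], vclass=VariantClass.DELETION)
    merged["short_insertion"] = merge.merge_insertions(
        pci["short_insertion"][Caller.SMALL_VARIANT],
        pci["short_insertion"][Caller.SPLIT_READ])
    merged["long_insertion"] = merge.merge_insertions(
        pci["long_insertion"][Caller.SMALL_VARIANT],
        pci["long_insertion"][Caller.SPLIT_READ],
        pci["long_insertion"][Caller.READ_PAIR])
    merged["duplication"] = merge.hierarchical_merge(
        pci["duplication"][Caller.SPLIT_READ], (),
        pci["duplication"][Caller.READ_DEPTH], vclass=VariantClass.DUPLICATION)
    merged["inversion"] = merge.hierarchical_merge(
        pci["inversion"][Caller.SPLIT_READ],
        pci["inversion"][Caller.READ_PAIR], vclass=VariantClass.INVERSION)
    merged["intra_translocation"] = merge.passthrough_loci(
        pci["intra_translocation"][Caller.READ_PAIR], VariantClass.INTRA_TRANSLOCATION)
    merged["inter_translocation"] = merge.merge_translocations(
        pci["inter_translocation"][Caller.SPLIT_READ],
        pci["inter_translocation"][Caller.READ_PAIR],
        max_bp_distance=t.translocation_max_bp_distance)

    homdel_loci = merge.merge_homozygous_deletions(
        wm(sv_homdels), wm(rd_cn0),
        split_read_deletions=sr_dels, read_pair_deletions=rp_dels,
        all_small_variant_calls=sv_calls)
    merged["short_homozygous_deletion"] = [
        m for m in homdel_loci if (m.length or len(m.interval)) < t.short_long_cutoff]
    merged["long_homozygous_deletion"] = [
        m for m in homdel_loci if (m.length or len(m.interval)) >= t.short_long_cutoff]

    contrib_frames = []
    rule_class = {"short_deletion": VariantClass.DELETION,
                  "long_deletion": VariantClass.DELETION,
                  "short_insertion": VariantClass.INSERTION,
                  "long_insertion": VariantClass.INSERTION,
                  "duplication": VariantClass.DUPLICATION,
                  "inversion": VariantClass.INVERSION,
                  "inter_translocation": VariantClass.INTER_TRANSLOCATION}
    for name, vclass in rule_class.items():
        contrib_frames.append(merge.summarize_contributions(
            name, per_caller_inputs[name], merged[name], vclass))
    contributions = pd.concat(contrib_frames, ignore_index=True)

    # ---- stage 5: database matching ----------------------------------------
    sub_alts = {f"{c.interval.chrom}:{c.interval.start}": c.alt
                for c in sv_subs if c.alt}
    dbsnp = dbmatch.load_vcf_database(dbs.dbsnp_vcf, "dbSNP")
    clin_raw = dbmatch.load_vcf_database(dbs.clinvar_vcf, "ClinVar")
    dgv = dbmatch.load_sv_database(dbs.dgv_tsv, "DGV")
    dbvar = dbmatch.load_sv_database(dbs.dbvar_tsv, "dbVar")

    results = {
        "substitution_dbsnp": dbmatch.match_short_variants(
            merged["substitution"], dbsnp, "dbSNP", alt_alleles=sub_alts),
        "short_deletion_dbsnp": dbmatch.match_short_variants(
            merged["short_deletion"] + merged["short_homozygous_deletion"],
            dbsnp, "dbSNP"),
        "short_insertion_dbsnp": dbmatch.match_short_variants(
            merged["short_insertion"], dbsnp, "dbSNP"),
        "long_deletion_dgv": dbmatch.match_long_population(merged["long_deletion"], dgv),
        "long_insertion_dgv": dbmatch.match_long_population(merged["long_insertion"], dgv),
        "duplication_dgv": dbmatch.match_long_population(merged["duplication"], dgv),
    }
    clin_records = dbmatch.filter_clinical_records(clin_raw)
    clin_result = dbmatch.match_clinical_short(
        merged["substitution"] + merged["short_deletion"], clin_records,
        alt_alleles=sub_alts)
    results["clinical_short"] = clin_result
    clinvar_pathogenic = len({
        id(locus) for locus, rec in clin_result.matched
        if (rec.clinical_significance or "").lower() == "pathogenic"})
    results["pathogenic_long"] = dbmatch.match_pathogenic_long(
        merged["long_deletion"] + merged["duplication"] + merged["long_insertion"],
        dbvar)
    db_summary = dbmatch.db_match_summary(results)

    array_df = pd.read_csv(dbs.array_tsv, sep="\t", dtype={"rsid": str, "chrom": str,
                                                           "pos": int})
    ref_df = pd.read_csv(dbs.array_ref_tsv, sep="\t", dtype=str)
    ref_map = dict(zip(ref_df["rsid"], ref_df["ref"]))
    array_cmp = dbmatch.compare_array_genotypes(sv_subs, array_df, ref_map)

    # ---- stage 6: damaged genes + enrichment -------------------------------
    annotations = enrich.read_effect_annotations(dbs.annotations_tsv, dbs.maf_tsv)
    rare_genes = enrich.select_rare_high_impact(annotations, config.maf_cutoff)
    exons = enrich.read_exon_bed(dbs.exon_bed)
    homdel_genes = enrich.genes_under_homdel(homdel_loci, exons)
    damaged = enrich.union_damaged_genes(rare_genes, homdel_genes)
    gene_sets = enrich.read_gmt(dbs.gmt)
    universe = [g for g in dbs.universe_txt.read_text().splitlines() if g]
    enrichment = enrich.enrich_gene_sets(damaged, gene_sets,
                                         background=len(universe),
                                         min_set_size=config.min_set_size)

    # ---- stage 7: write report + checksums ---------------------------------
    merged_dir = out / "merged"
    merged_dir.mkdir(exist_ok=True)
    for name, loci in merged.items():
        with open(merged_dir / f"{name}.bed", "w") as fh:
            for m in loci:
                if m.interval is not None:
                    callers = ",".join(sorted(c.value for c in m.callers))
                    fh.write(f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}"
                             f"\t{callers}\n")
                else:
                    (c1, p1), (c2, p2) = m.breakpoints
                    callers = ",".join(sorted(c.value for c in m.callers))
                    fh.write(f"{c1}\t{p1}\t{p1 + 1}\t{callers};mate={c2}:{p2}\n")
    contributions.to_csv(out / "contributions.tsv", sep="\t", index=False)
    db_summary.to_csv(out / "db_summary.tsv", sep="\t", index=False)
    enrich.enrichment_table(enrichment).to_csv(out / "enrichment.tsv", sep="\t",
                                               index=False)

    report_json = {
        "seed": config.seed,
        "qc_counts": qc_counts,
        "summary_stats": summary_stats,
        "modal_copy_number": modal,
        "cn_histogram": {str(k): v for k, v in histogram.items()},
        "cn_segment_classes": cn_classes,
        "merged_counts": {k: len(v) for k, v in merged.items()},
        "clinvar_pathogenic_matches": clinvar_pathogenic,
        "array_agreement": array_cmp.agreement,
        "n_damaged_genes": len(damaged),
        "top_enriched_set": enrichment[0].set_name if enrichment else None,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=1, sort_keys=True))

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file():
            checksums[str(path.relative_to(out))] = _sha256(path)
    (out / "checksums.json").write_text(json.dumps(checksums, indent=1, sort_keys=True))
    checksums.pop("checksums.json", None)

    return RunReport(
        config=config, truth=truth, qc_counts=qc_counts, summary_stats=summary_stats,
        modal_cn=modal, cn_histogram=histogram, cn_classes=cn_classes, merged=merged,
        contributions=contributions, db_summary=db_summary,
        clinvar_pathogenic=clinvar_pathogenic, array=array_cmp,
        damaged_genes=damaged, enrichment=enrichment, checksums=checksums)
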