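"""Synthetic external databases, gene models and gene sets.

Companion to :mod:`tetramerge.synth`: given a truth set, emits
dbSNP/ClinVar-style VCFs, DGV/dbVar-style SV tables, a population-frequency
table, SNP-array genotypes with a reference-allele map, a coding-exon BED,
and GMT gene-set collections — each with a configurable fraction of planted
matches so downstream match rates have a known expectation.  A JSON
manifest records everything planted (matching truth ids, the damaged-gene
list, the name of the enriched set) for use as a test oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
from intervaltree import IntervalTree

from .enrich import HIGH_IMPACT_CATEGORIES
from .intervals import Interval
from .synth import NUCLEOTIDES, TRANSITION, SimulationConfig, TruthClass, TruthSet


@dataclass
class DatabaseConfig:
    """What to plant in each synthetic database.

    ``db_match_fraction`` is the probability that a truth variant gets a
    matching record in the population databases (dbSNP-style for short
    variants, DGV-style for long ones); pathogenic counts are planted
    exactly.
    """

    db_match_fraction: float = 0.7
    clinvar_pathogenic_matches: int = 10
    dbvar_pathogenic_matches: int = 6
    n_genes: int = 2000                 # gene universe (GMT background)
    n_placed_genes: int = 200           # genes given exon coordinates
    exons_per_gene: int = 3
    exon_length: int = 150
    n_high_impact: int = 40             # substitutions annotated high-impact
    rare_fraction: float = 0.85         # of high-impact variants with MAF < 0.001
    n_decoy_sets: int = 120
    decoy_size_range: tuple[int, int] = (60, 300)
    planted_set_size: int = 150
    planted_overlap: int = 25           # damaged genes forced into the planted set
    array_fraction: float = 0.8
    array_concordance: float = 0.97
    array_homref_count: int = 30
    array_unresolvable_count: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.db_match_fraction <= 1:
            raise ValueError("match fraction must be in [0, 1]")
        if self.planted_overlap > self.planted_set_size:
            raise ValueError("planted overlap larger than the planted set")


@dataclass
class DatabaseBundle:
    dbsnp_vcf: Path
    clinvar_vcf: Path
    dgv_tsv: Path
    dbvar_tsv: Path
    maf_tsv: Path
    annotations_tsv: Path
    array_tsv: Path
    array_ref_tsv: Path
    exon_bed: Path
    gmt: Path
    universe_txt: Path
    manifest: Path


def _vcf_header(config: SimulationConfig) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, length in config.chromosomes.items():
        h.contigs.add(chrom, length=length)
    h.info.add("CLNSIG", 1, "String", "Clinical significance")
    h.info.add("ASSERT", 1, "Integer", "Assertion criteria provided (0/1)")
    h.info.add("SUBMITTER", 1, "String", "Submitting organization")
    h.info.add("COMMON", 1, "Integer", "Common variant flag (0/1)")
    h.info.add("AF", "A", "Float", "Population allele frequency")
    return h


def _indel_alleles(v) -> tuple[int, str, str]:
    """(vcf 0-based start, REF, ALT) for a truth short indel."""
    iv = v.interval
    if v.insert_length is not None:
        return iv.start - 1, "A", "A" + "N" * v.insert_length
    return iv.start - 1, "A" + "N" * len(iv), "A"


def emit_databases(truth: TruthSet, out_dir: str | Path,
                   db_config: DatabaseConfig | None = None) -> DatabaseBundle:
    """Write all synthetic database files and the planting manifest."""
    cfg = db_config or DatabaseConfig()
    sim = truth.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([sim.seed, 91])
    (rng_snp, rng_clin, rng_sv, rng_gene, rng_set, rng_array) = (
        np.random.default_rng(s) for s in ss.spawn(6))

    chrom_order = {c: i for i, c in enumerate(sim.chromosomes)}
    manifest: dict = {}

    subs = truth.by_class(TruthClass.SUBSTITUTION)
    short_dels = truth.by_class(TruthClass.SHORT_DELETION)
    short_ins = truth.by_class(TruthClass.SHORT_INSERTION)
    short_homdels = [v for v in truth.by_class(TruthClass.HOMOZYGOUS_DELETION)
                     if len(v.interval) < 50]
    long_homdels = [v for v in truth.by_class(TruthClass.HOMOZYGOUS_DELETION)
                    if len(v.interval) >= 50]
    long_dels = truth.by_class(TruthClass.LONG_DELETION)
    long_ins = truth.by_class(TruthClass.LONG_INSERTION)
    dups = truth.by_class(TruthClass.DUPLICATION)

    # occupied coordinates, so decoy records never collide with truth loci
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in sim.chromosomes}
    for v in truth.variants:
        if v.interval is not None:
            occupied[v.interval.chrom].addi(max(0, v.interval.start - 200),
                                            v.interval.end + 200)

    def random_free_position(rng, pad: int = 1) -> tuple[str, int]:
        chroms = list(sim.chromosomes)
        for _ in range(500):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1000, sim.chromosomes[chrom] - 1000))
            if not occupied[chrom].overlap(pos, pos + pad):
                return chrom, pos
        raise RuntimeError("no free position for a decoy record")

    # --- dbSNP-style VCF ----------------------------------------------------
    dbsnp_path = out / "dbsnp.vcf"
    header = _vcf_header(sim)
    rows = []
    planted_dbsnp: list[str] = []
    rs = 1000
    for v in subs:
        if rng_snp.random() < cfg.db_match_fraction:
            rows.append((v.interval.chrom, v.interval.start, v.ref, v.alt, f"rs{rs}"))
            planted_dbsnp.append(v.truth_id)
            rs += 1
    for v in short_dels + short_ins + short_homdels:
        if rng_snp.random() < cfg.db_match_fraction:
            start, ref, alt = _indel_alleles(v)
            rows.append((v.interval.chrom, start, ref, alt, f"rs{rs}"))
            planted_dbsnp.append(v.truth_id)
            rs += 1
    for _ in range(40):  # decoys nowhere near truth loci
        chrom, pos = random_free_position(rng_snp)
        ref = str(rng_snp.choice(NUCLEOTIDES))
        rows.append((chrom, pos, ref, TRANSITION[ref], f"rs{rs}"))
        rs += 1
    rows.sort(key=lambda r: (chrom_order[r[0]], r[1], r[4]))
    with pysam.VariantFile(str(dbsnp_path), "w", header=header) as vf:
        for chrom, start, ref, alt, rid in rows:
            rec = vf.new_record(contig=chrom, start=start, stop=start + len(ref),
                                alleles=(ref, alt), id=rid)
            vf.write(rec)
    manifest["dbsnp_planted_truth_ids"] = planted_dbsnp

    # --- ClinVar-style VCF ---------------------------------------------------
    clinvar_path = out / "clinvar.vcf"
    clin_rows = []
    eligible = [v for v in subs + short_dels if v.truth_id not in ()]
    idx = rng_clin.permutation(len(eligible))
    planted_path_ids = []
    take = [eligible[i] for i in idx[:cfg.clinvar_pathogenic_matches]]
    for j, v in enumerate(take):
        # half the pathogenic records rely on the OMIM exemption
        has_assert, submitter = (1, "LabX") if j % 2 == 0 else (0, "OMIM")
        if v.tclass is TruthClass.SUBSTITUTION:
            clin_rows.append((v.interval.chrom, v.interval.start, v.ref, v.alt,
                              "Pathogenic", has_assert, submitter, 0))
        else:
            start, ref, alt = _indel_alleles(v)
            clin_rows.append((v.interval.chrom, start, ref, alt,
                              "Pathogenic", has_assert, submitter, 0))
        planted_path_ids.append(v.truth_id)
    # records that must be screened out: no criteria + non-OMIM, or common
    removable = [eligible[i] for i in idx[cfg.clinvar_pathogenic_matches:
                                          cfg.clinvar_pathogenic_matches + 8]]
    for j, v in enumerate(removable):
        if v.tclass is TruthClass.SUBSTITUTION:
            base = (v.interval.chrom, v.interval.start, v.ref, v.alt)
        else:
            start, ref, alt = _indel_alleles(v)
            base = (v.interval.chrom, start, ref, alt)
        if j % 2 == 0:
            clin_rows.append(base + ("Pathogenic", 0, "LabY", 0))   # zero stars
        else:
            clin_rows.append(base + ("Pathogenic", 1, "LabX", 1))   # common flag
    # benign matches with criteria (match, not pathogenic)
    for v in [eligible[i] for i in idx[cfg.clinvar_pathogenic_matches + 8:
                                       cfg.clinvar_pathogenic_matches + 14]]:
        if v.tclass is TruthClass.SUBSTITUTION:
            clin_rows.append((v.interval.chrom, v.interval.start, v.ref, v.alt,
                              "Benign", 1, "LabX", 0))
        else:
            start, ref, alt = _indel_alleles(v)
            clin_rows.append((v.interval.chrom, start, ref, alt, "Benign", 1, "LabX", 0))
    clin_rows.sort(key=lambda r: (chrom_order[r[0]], r[1], r[3]))
    header = _vcf_header(sim)
    with pysam.VariantFile(str(clinvar_path), "w", header=header) as vf:
        for i, (chrom, start, ref, alt, sig, has_assert, submitter, common) in enumerate(clin_rows):
            rec = vf.new_record(contig=chrom, start=start, stop=start + len(ref),
                                alleles=(ref, alt), id=f"RCV{i:06d}")
            rec.info["CLNSIG"] = sig
            rec.info["ASSERT"] = has_assert
            rec.info["SUBMITTER"] = submitter
            rec.info["COMMON"] = common
            vf.write(rec)
    manifest["clinvar_pathogenic_truth_ids"] = planted_path_ids

    # --- DGV-style and dbVar-style SV tables ---------------------------------
    dgv_path = out / "dgv.tsv"
    long_all = long_dels + long_ins + dups
    planted_dgv = []
    with open(dgv_path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsvclass\n")
        i = 0
        for v in long_all:
            if rng_sv.random() < cfg.db_match_fraction:
                iv = v.interval
                if v.insert_length is not None:
                    s, e = iv.start, iv.start + 1
                else:  # 60% reciprocal overlap — above the strict 25% rule
                    s = iv.start + int(0.4 * len(iv))
                    e = min(iv.end + int(0.4 * len(iv)), sim.chromosomes[iv.chrom])
                cname = ("insertion" if v.insert_length is not None else
                         "duplication" if v.tclass is TruthClass.DUPLICATION else "deletion")
                fh.write(f"dgv{i}\t{iv.chrom}\t{s}\t{e}\t{cname}\n")
                planted_dgv.append(v.truth_id)
                i += 1
        for _ in range(20):
            chrom, pos = random_free_position(rng_sv, pad=2000)
            fh.write(f"dgv{i}\t{chrom}\t{pos}\t{pos + 2000}\tdeletion\n")
            i += 1
    manifest["dgv_planted_truth_ids"] = planted_dgv

    dbvar_path = out / "dbvar.tsv"
    planted_dbvar = []
    with open(dbvar_path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsvclass\tclinical_significance\n")
        pool = [v for v in long_dels + dups if len(v.interval) >= 100]
        pick = rng_sv.permutation(len(pool))
        i = 0
        for v in [pool[j] for j in pick[:cfg.dbvar_pathogenic_matches]]:
            iv = v.interval
            shift = max(1, int(0.02 * len(iv)))   # ~96% reciprocal overlap
            cname = "duplication" if v.tclass is TruthClass.DUPLICATION else "deletion"
            fh.write(f"nsv{i}\t{iv.chrom}\t{iv.start + shift}\t{iv.end}\t{cname}\tpathogenic\n")
            planted_dbvar.append(v.truth_id)
            i += 1
        for v in [pool[j] for j in pick[cfg.dbvar_pathogenic_matches:
                                        cfg.dbvar_pathogenic_matches + 4]]:
            iv = v.interval
            shift = int(0.3 * len(iv))           # ~70% — below the 90% rule
            cname = "duplication" if v.tclass is TruthClass.DUPLICATION else "deletion"
            fh.write(f"nsv{i}\t{iv.chrom}\t{iv.start + shift}\t{iv.end}\t{cname}\tpathogenic\n")
            i += 1
    manifest["dbvar_planted_truth_ids"] = planted_dbvar

    # --- gene models, effect annotations, gene sets --------------------------
    universe = [f"G{i:05d}" for i in range(cfg.n_genes)]
    universe_path = out / "gene_universe.txt"
    universe_path.write_text("\n".join(universe) + "\n")

    exon_path = out / "exons.bed"
    homdel_genes = []
    exon_rows = []
    gene_iter = iter(universe)
    for v in long_homdels:
        gene = next(gene_iter)
        iv = v.interval
        # one exon inside the deletion, the rest outside
        s = iv.start + len(iv) // 4
        exon_rows.append((iv.chrom, s, min(s + cfg.exon_length, iv.end), gene))
        exon_rows.append((iv.chrom, iv.end + 500, iv.end + 500 + cfg.exon_length, gene))
        homdel_genes.append(gene)
    n_rest = max(0, cfg.n_placed_genes - len(homdel_genes))
    for _ in range(n_rest):
        gene = next(gene_iter)
        chrom, pos = random_free_position(rng_gene, pad=cfg.exon_length)
        for e in range(cfg.exons_per_gene):
            s = pos + e * (cfg.exon_length + 200)
            exon_rows.append((chrom, s, s + cfg.exon_length, gene))
    exon_rows.sort(key=lambda r: (chrom_order[r[0]], r[1], r[3]))
    with open(exon_path, "w") as fh:
        for chrom, s, e, gene in exon_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{gene}\n")

    ann_path = out / "annotations.tsv"
    maf_path = out / "exac_maf.tsv"
    high_cats = sorted(HIGH_IMPACT_CATEGORIES)
    rare_genes = []
    ann_rows, maf_rows = [], []
    hi_subs = subs[:cfg.n_high_impact]
    for v in hi_subs:
        gene = next(gene_iter)
        effect = high_cats[int(rng_gene.integers(0, len(high_cats)))]
        ann_rows.append((v.truth_id, gene, effect))
        u = rng_gene.random()
        if u < cfg.rare_fraction:
            if rng_gene.random() < 0.3:
                pass  # no population record at all: treated as rare
            else:
                maf_rows.append((v.truth_id, f"{rng_gene.uniform(0, 0.0009):.6f}"))
            rare_genes.append(gene)
        else:
            maf_rows.append((v.truth_id, f"{rng_gene.uniform(0.002, 0.3):.6f}"))
    for v in subs[cfg.n_high_impact:cfg.n_high_impact + 60]:
        gene = next(gene_iter)
        effect = "missense" if rng_gene.random() < 0.7 else "synonymous"
        ann_rows.append((v.truth_id, gene, effect))
    with open(ann_path, "w") as fh:
        fh.write("variant_id\tgene\teffect\n")
        for r in ann_rows:
            fh.write("\t".join(r) + "\n")
    with open(maf_path, "w") as fh:
        fh.write("variant_id\tmaf\n")
        for r in maf_rows:
            fh.write("\t".join(r) + "\n")

    damaged = sorted(set(rare_genes) | set(homdel_genes))
    manifest["homdel_genes"] = sorted(homdel_genes)
    manifest["rare_high_impact_genes"] = sorted(set(rare_genes))
    manifest["damaged_genes"] = damaged

    gmt_path = out / "gene_sets.gmt"
    planted_name = "PLANTED_DAMAGED_PROCESS"
    non_damaged = [g for g in universe if g not in set(damaged)]
    with open(gmt_path, "w") as fh:
        n_overlap = min(cfg.planted_overlap, len(damaged))
        members = (list(rng_set.choice(damaged, size=n_overlap, replace=False))
                   + list(rng_set.choice(non_damaged,
                                         size=cfg.planted_set_size - n_overlap,
                                         replace=False)))
        fh.write(planted_name + "\tplanted enriched set\t" + "\t".join(sorted(members)) + "\n")
        lo, hi = cfg.decoy_size_range
        for i in range(cfg.n_decoy_sets):
            size = int(rng_set.integers(lo, hi + 1))
            members = rng_set.choice(universe, size=size, replace=False)
            fh.write(f"DECOY_{i:03d}\trandom set\t" + "\t".join(sorted(members)) + "\n")
        tiny = rng_set.choice(universe, size=30, replace=False)
        fh.write("TINY_SET\tbelow the size floor\t" + "\t".join(sorted(tiny)) + "\n")
    manifest["planted_set_name"] = planted_name
    manifest["planted_overlap"] = int(min(cfg.planted_overlap, len(damaged)))

    # --- SNP-array genotypes --------------------------------------------------
    array_path = out / "array_genotypes.tsv"
    ref_path = out / "array_ref_alleles.tsv"
    arr_rows, ref_rows = [], []
    rsn = 500000
    n_concordant = n_shared = 0
    for v in subs:
        if rng_array.random() >= cfg.array_fraction:
            continue
        rsid = f"rs{rsn}"
        rsn += 1
        ref_rows.append((rsid, v.ref))
        hom_truth = v.allele_count == 4
        concordant = rng_array.random() < cfg.array_concordance
        hom_array = hom_truth if concordant else not hom_truth
        a1, a2 = (v.alt, v.alt) if hom_array else (v.ref, v.alt)
        arr_rows.append((rsid, v.interval.chrom, v.interval.start, a1, a2))
        n_shared += 1
        n_concordant += int(concordant)
    for _ in range(cfg.array_homref_count):
        chrom, pos = random_free_position(rng_array)
        rsid = f"rs{rsn}"
        rsn += 1
        ref = str(rng_array.choice(NUCLEOTIDES))
        ref_rows.append((rsid, ref))
        arr_rows.append((rsid, chrom, pos, ref, ref))
    for _ in range(cfg.array_unresolvable_count):
        chrom, pos = random_free_position(rng_array)
        rsid = f"rs{rsn}"
        rsn += 1  # deliberately missing from the reference-allele map
        arr_rows.append((rsid, chrom, pos, "A", "G"))
    with open(array_path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tallele1\tallele2\n")
        for r in arr_rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    with open(ref_path, "w") as fh:
        fh.write("rsid\tref\n")
        for r in ref_rows:
            fh.write("\t".join(r) + "\n")
    manifest["array_expected_shared"] = n_shared
    manifest["array_expected_concordant"] = n_concordant

    manifest_path = out / "db_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return DatabaseBundle(dbsnp_path, clinvar_path, dgv_path, dbvar_path, maf_path,
                          ann_path, array_path, ref_path, exon_path, gmt_path,
                          universe_path, manifest_path)
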