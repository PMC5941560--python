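"""Damaged-gene selection and hypergeometric gene-set enrichment.

The damaged-gene set is the union of (a) genes carrying a rare (population
minor allele frequency below 0.1%) high-impact small variant and (b) genes
with a coding exon under a homozygous deletion.  Enrichment of that set in
a gene-set collection is scored by the upper-tail hypergeometric
probability against a fixed background universe of N genes (26,802 nuclear
genes by default, the hg19 count).

High impact means one of: stop gained, stop lost, start lost, splice
acceptor, splice donor, exon loss, frameshift.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .calls import MergedLocus
from .intervals import Interval

HIGH_IMPACT_CATEGORIES = frozenset({
    "stop_gained", "stop_lost", "start_lost", "splice_acceptor",
    "splice_donor", "exon_loss", "frameshift",
})

DEFAULT_BACKGROUND = 26_802
DEFAULT_MIN_SET_SIZE = 50
DEFAULT_MAF_CUTOFF = 0.001


@dataclass
class EffectAnnotation:
    """One predicted functional effect of a small variant."""

    variant_id: str
    gene: str
    effect: str
    maf: Optional[float] = None   # population minor allele frequency; absent = unseen

    @property
    def is_high_impact(self) -> bool:
        return self.effect in HIGH_IMPACT_CATEGORIES


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int            # K: genes in the set
    damaged_size: int        # n: genes drawn
    background: int          # N: universe
    overlap: int             # k: shared genes
    overlap_genes: tuple[str, ...]
    p_value: float
    p_adjusted: Optional[float] = None  # Benjamini-Hochberg, reported additionally

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.damaged_size):
            raise ValueError("overlap exceeds margins")


class GeneSet:
    def __init__(self, name: str, description: str, genes: Iterable[str]):
        self.name = name
        self.description = description
        self.genes = frozenset(g.upper() for g in genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member genes,
    tab-separated."""
    sets = []
    with open(path) as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def read_effect_annotations(path: str | Path,
                            maf_table: str | Path | None = None) -> list[EffectAnnotation]:
    """Effect-annotation TSV (variant_id, gene, effect[, maf]); a separate
    MAF table (variant_id, maf) overrides or supplies frequencies."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mafs: dict[str, float] = {}
    if maf_table is not None:
        mdf = pd.read_csv(maf_table, sep="\t", dtype=str, keep_default_na=False)
        mafs = {r["variant_id"]: float(r["maf"]) for _, r in mdf.iterrows() if r["maf"]}
    out = []
    for _, row in df.iterrows():
        maf = mafs.get(row["variant_id"])
        if maf is None and "maf" in row and row["maf"] != "":
            maf = float(row["maf"])
        out.append(EffectAnnotation(row["variant_id"], row["gene"], row["effect"], maf))
    return out


def select_rare_high_impact(annotations: Iterable[EffectAnnotation],
                            maf_cutoff: float = DEFAULT_MAF_CUTOFF) -> list[str]:
    """Genes with a high-impact variant that is rare in the population.

    Rare means MAF strictly below the cutoff; a variant with no frequency
    record is treated as rare (absence from a 60k-sample panel is itself
    evidence of rarity).  Returns distinct upper-cased gene symbols.
    """
    genes: dict[str, None] = {}
    for a in annotations:
        if not a.is_high_impact:
            continue
        if a.maf is not None and a.maf >= maf_cutoff:
            continue
        genes.setdefault(a.gene.upper())
    return list(genes)


def read_exon_bed(path: str | Path) -> dict[str, list[Interval]]:
    """4-column BED of coding exons; column 4 is the gene symbol."""
    exons: dict[str, list[Interval]] = defaultdict(list)
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            chrom, s, e, gene = raw.rstrip("\n").split("\t")[:4]
            exons[gene.upper()].append(Interval(chrom, int(s), int(e)))
    return dict(exons)


def genes_under_homdel(homdel_loci: Sequence[MergedLocus | Interval],
                       exons: dict[str, list[Interval]]) -> list[str]:
    """Genes with at least one coding exon overlapping (>= 1 bp) a
    homozygous-deletion locus."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for locus in homdel_loci:
        iv = locus.interval if isinstance(locus, MergedLocus) else locus
        if iv is not None:
            trees[iv.chrom].addi(iv.start, iv.end)
    out = []
    for gene, ivs in exons.items():
        if any(trees[iv.chrom].overlap(iv.start, iv.end) for iv in ivs):
            out.append(gene)
    return sorted(out)


def union_damaged_genes(*gene_lists: Iterable[str]) -> list[str]:
    """Deduplicated, case-normalized union of damaged-gene lists."""
    seen: dict[str, None] = {}
    for lst in gene_lists:
        for g in lst:
            seen.setdefault(g.upper())
    return sorted(seen)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for X ~
    Hypergeom(N, K, n): drawing n genes from a universe of N that contains
    K set members, the probability of k or more hits.

    Evaluated through the survival function, which accumulates the tail in
    log space, so values around 1e-5 and far smaller are exact to double
    precision.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"impossible margins: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(damaged_genes: Sequence[str],
                     gene_sets: Sequence[GeneSet],
                     background: int = DEFAULT_BACKGROUND,
                     min_set_size: int = DEFAULT_MIN_SET_SIZE) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the damaged-gene set in each
    collection set, sorted ascending by raw p-value.

    Sets with fewer than ``min_set_size`` genes are excluded.  Raw p-values
    are reported unadjusted; a Benjamini-Hochberg column is attached as a
    convenience but is not part of the ranking.
    """
    damaged = frozenset(g.upper() for g in damaged_genes)
    n = len(damaged)
    results = []
    for gs in gene_sets:
        if len(gs) < min_set_size:
            continue
        shared = tuple(sorted(damaged & gs.genes))
        p = hypergeom_tail(len(shared), len(gs), n, background) if n else 1.0
        results.append(EnrichmentResult(
            set_name=gs.name, set_size=len(gs), damaged_size=n,
            background=background, overlap=len(shared), overlap_genes=shared,
            p_value=p))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    m = len(results)
    # BH adjustment over the ascending p-values
    prev = 1.0
    for rank in range(m, 0, -1):
        r = results[rank - 1]
        adj = min(prev, r.p_value * m / rank)
        r.p_adjusted = adj
        prev = adj
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_set": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
        "p_value": r.p_value, "p_adjusted_bh": r.p_adjusted,
        "genes": ",".join(r.overlap_genes),
    } for r in results])
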