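"""Matching the merged catalog against external variant databases.

Each database has its own match rule, following how the corresponding real
resources are used:

* dbSNP-style short variants: indels match on any overlap; substitutions
  match on locus and alternate allele;
* ClinVar-style clinical records: records without assertion criteria are
  removed unless submitted by OMIM, common-flagged records are removed,
  and matching requires 25% reciprocal overlap (inclusive);
* DGV-style population SVs: reciprocal overlap strictly above 25%;
* dbVar-style pathogenic SVs: reciprocal overlap strictly above 90%;
* SNP-array genotypes: records homozygous for the reference allele or with
  unresolvable reference alleles are screened out, then zygosity
  concordance is computed on shared loci.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .calls import DatabaseRecord, MergedLocus, VariantCall, VariantClass
from .intervals import Interval, any_overlap, reciprocal_match

logger = logging.getLogger(__name__)

OMIM_SUBMITTER = "OMIM"


@dataclass
class MatchResult:
    """Partition of one variant set against one database."""

    database: str
    matched: list[tuple[MergedLocus, DatabaseRecord]]
    unmatched: list[MergedLocus]

    @property
    def n_total(self) -> int:
        return len({id(m) for m, _ in self.matched}) + len(self.unmatched)

    @property
    def matched_loci(self) -> list[MergedLocus]:
        seen, out = set(), []
        for m, _ in self.matched:
            if id(m) not in seen:
                seen.add(id(m))
                out.append(m)
        return out

    @property
    def match_fraction(self) -> float:
        n = self.n_total
        return len(self.matched_loci) / n if n else 0.0


# ---------------------------------------------------------------------------
# Record loading / normalization
# ---------------------------------------------------------------------------

def vcf_indel_to_interval(pos0: int, ref: str, alt: str,
                          max_len: int = 100) -> Optional[tuple[VariantClass, Interval]]:
    """BED-style interval for a VCF-encoded short variant.

    ``pos0`` is the record's 0-based start (anchor base for indels).
    Deletions span the REF minus the anchor; insertions occupy the point
    after the anchor; substitutions the substituted base.  Indels of length
    ``max_len`` or more are excluded from short-variant matching (returns
    ``None``), as are symbolic alleles.  Input is assumed biallelic —
    decompose multi-allelic records first.
    """
    if alt.startswith("<") or "," in alt:
        return None
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SUBSTITUTION, (pos0, pos0 + 1)
    length = abs(len(ref) - len(alt))
    if length >= max_len:
        return None
    if len(ref) > len(alt):
        return VariantClass.DELETION, (pos0 + 1, pos0 + len(ref))
    return VariantClass.INSERTION, (pos0 + 1, pos0 + 2)


def load_vcf_database(path: str | Path, database: str,
                      max_indel_len: int = 100) -> list[DatabaseRecord]:
    """dbSNP/ClinVar-style VCF into database records.

    Multi-allelic records are decomposed into biallelic records.  Clinical
    INFO fields read when present: ``CLNSIG`` (significance), ``ASSERT``
    (assertion criteria, 0/1), ``SUBMITTER``, ``COMMON`` (0/1), ``AF``.
    """
    records: list[DatabaseRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            for alt in (rec.alts or ()):
                conv = vcf_indel_to_interval(rec.start, rec.ref, alt, max_indel_len)
                if conv is None:
                    continue
                vclass, (s, e) = conv

                def _get(key):
                    return info.get(key) if key in info else None

                common = _get("COMMON")
                assertion = _get("ASSERT")
                af = _get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                records.append(DatabaseRecord(
                    database=database, interval=Interval(rec.contig, s, e),
                    vclass=vclass, identifier=rec.id or "", ref=rec.ref, alt=alt,
                    clinical_significance=_get("CLNSIG"),
                    has_assertion_criteria=None if assertion is None else bool(int(assertion)),
                    submitter=_get("SUBMITTER"),
                    is_common=None if common is None else bool(int(common)),
                    allele_frequency=None if af is None else float(af)))
    return records


def load_sv_database(path: str | Path, database: str) -> list[DatabaseRecord]:
    """DGV/dbVar-style tab-separated SV records.

    Required columns: chrom, start, end, svclass; optional: id,
    clinical_significance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(DatabaseRecord(
            database=database,
            interval=Interval(row["chrom"], int(row["start"]), int(row["end"])),
            vclass=VariantClass(row["svclass"]),
            identifier=row.get("id", ""),
            clinical_significance=row.get("clinical_significance") or None))
    return out


# ---------------------------------------------------------------------------
# Match rules
# ---------------------------------------------------------------------------

def match_short_variants(loci: Sequence[MergedLocus],
                         records: Sequence[DatabaseRecord],
                         database: str = "dbSNP",
                         alt_alleles: dict[str, str] | None = None) -> MatchResult:
    """Any-overlap matching for short indels; locus + allele for
    substitutions.

    ``alt_alleles`` maps a substitution locus key ``"chrom:start"`` to its
    alternate allele; substitutions match only when the database record
    carries the same alternate allele at the same base.
    """
    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rec in records:
        by_chrom[rec.interval.chrom].addi(rec.interval.start, rec.interval.end, rec)
    matched, unmatched = [], []
    for locus in loci:
        iv = locus.interval
        hits = []
        for node in by_chrom[iv.chrom].overlap(iv.start, iv.end):
            rec = node.data
            if locus.vclass is VariantClass.SUBSTITUTION:
                if rec.vclass is not VariantClass.SUBSTITUTION or rec.interval != iv:
                    continue
                if alt_alleles is not None:
                    key = f"{iv.chrom}:{iv.start}"
                    if key in alt_alleles and rec.alt is not None \
                            and rec.alt.upper() != alt_alleles[key].upper():
                        continue
            hits.append(rec)
        if hits:
            matched.extend((locus, h) for h in hits)
        else:
            unmatched.append(locus)
    return MatchResult(database, matched, unmatched)


def filter_clinical_records(records: Iterable[DatabaseRecord]) -> list[DatabaseRecord]:
    """Clinical-record screen: keep records that have assertion criteria or
    were submitted by OMIM, and drop records flagged as common variants."""
    out = []
    for r in records:
        if not (r.has_assertion_criteria or r.submitter == OMIM_SUBMITTER):
            continue
        if r.is_common:
            continue
        out.append(r)
    return out


def match_clinical_short(loci: Sequence[MergedLocus],
                         records: Sequence[DatabaseRecord],
                         f: float = 0.25,
                         alt_alleles: dict[str, str] | None = None) -> MatchResult:
    """25% reciprocal overlap (inclusive) against filtered clinical records;
    substitutions require exact locus and allele."""
    matched, unmatched = [], []
    for locus in loci:
        hits = []
        for rec in records:
            if locus.vclass is VariantClass.SUBSTITUTION:
                if rec.vclass is VariantClass.SUBSTITUTION and rec.interval == locus.interval:
                    if alt_alleles is not None:
                        key = f"{locus.interval.chrom}:{locus.interval.start}"
                        if key in alt_alleles and rec.alt is not None \
                                and rec.alt.upper() != alt_alleles[key].upper():
                            continue
                    hits.append(rec)
            elif reciprocal_match(locus.interval, rec.interval, f):
                hits.append(rec)
        if hits:
            matched.extend((locus, h) for h in hits)
        else:
            unmatched.append(locus)
    return MatchResult("clinical", matched, unmatched)


def match_long_population(loci: Sequence[MergedLocus],
                          records: Sequence[DatabaseRecord],
                          f: float = 0.25) -> MatchResult:
    """Population-SV matching: reciprocal overlap strictly above 25%."""
    return _reciprocal_sv_match(loci, records, f, strict=True, database="population_sv")


def match_pathogenic_long(loci: Sequence[MergedLocus],
                          records: Sequence[DatabaseRecord],
                          f: float = 0.90) -> MatchResult:
    """Pathogenic-SV annotation: reciprocal overlap strictly above 90% with
    a record whose clinical significance is pathogenic."""
    path_records = [r for r in records
                    if (r.clinical_significance or "").lower() == "pathogenic"
                    or r.clinical_significance is None]
    return _reciprocal_sv_match(loci, path_records, f, strict=True, database="pathogenic_sv")


def _reciprocal_sv_match(loci, records, f, *, strict, database) -> MatchResult:
    matched, unmatched = [], []
    for locus in loci:
        if locus.interval is None:
            unmatched.append(locus)
            continue
        hits = [r for r in records
                if reciprocal_match(locus.interval, r.interval, f, strict=strict)]
        if hits:
            matched.extend((locus, h) for h in hits)
        else:
            unmatched.append(locus)
    return MatchResult(database, matched, unmatched)


# ---------------------------------------------------------------------------
# Array-genotype concordance
# ---------------------------------------------------------------------------

@dataclass
class ArrayComparison:
    n_array_input: int
    n_array_retained: int
    n_shared_loci: int
    n_concordant: int

    @property
    def agreement(self) -> Optional[float]:
        return self.n_concordant / self.n_shared_loci if self.n_shared_loci else None


def compare_array_genotypes(calls: Sequence[VariantCall],
                            array_df: pd.DataFrame,
                            reference_alleles: dict[str, str]) -> ArrayComparison:
    """Zygosity concordance between tetraploid genotype calls and diploid
    SNP-array genotypes.

    ``array_df`` needs columns rsid, chrom, pos (0-based), allele1, allele2.
    Array records are screened first: a record is dropped when its rsID has
    no resolvable reference allele or when it is homozygous for the
    reference.  On the shared loci, a tetraploid genotype with all four
    alleles alternate corresponds to array homozygous-alternate; any other
    alt-bearing genotype to heterozygous.
    """
    retained = []
    for _, row in array_df.iterrows():
        ref = reference_alleles.get(row["rsid"])
        if ref is None:
            logger.info("array record %s dropped: unresolvable rsID", row["rsid"])
            continue
        a1, a2 = row["allele1"].upper(), row["allele2"].upper()
        if a1 == ref.upper() and a2 == ref.upper():
            continue  # homozygous reference
        retained.append((row["chrom"], int(row["pos"]), a1 == a2))
    array_hom = {(c, p): hom for c, p, hom in retained}

    shared = concordant = 0
    for call in calls:
        if call.vclass is not VariantClass.SUBSTITUTION or call.genotype is None:
            continue
        key = (call.interval.chrom, call.interval.start)
        if key not in array_hom:
            continue
        shared += 1
        if call.is_homozygous_alt == array_hom[key]:
            concordant += 1
    return ArrayComparison(len(array_df), len(retained), shared, concordant)


def db_match_summary(results: dict[str, MatchResult]) -> pd.DataFrame:
    """Match percentages per variant class and database (Fig-4-style)."""
    rows = []
    for name, res in results.items():
        rows.append({
            "comparison": name, "database": res.database,
            "n_variants": res.n_total, "n_matched": len(res.matched_loci),
            "percent_matched": 100.0 * res.match_fraction,
        })
    return pd.DataFrame(rows)
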