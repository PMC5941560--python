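"""Database match rules, clinical-record screening, and array-genotype
concordance."""

import pandas as pd
import pytest

from tetramerge.calls import Caller, DatabaseRecord, MergedLocus, VariantCall, VariantClass
from tetramerge.dbmatch import (compare_array_genotypes, db_match_summary,
                                filter_clinical_records, match_clinical_short,
                                match_long_population, match_pathogenic_long,
                                match_short_variants, vcf_indel_to_interval)
from tetramerge.intervals import Interval


def locus(start, end, vclass=VariantClass.DELETION, chrom="c"):
    return MergedLocus(vclass=vclass, interval=Interval(chrom, start, end),
                       callers=frozenset({Caller.SPLIT_READ}), source_ids=("x",))


def record(start, end, vclass=VariantClass.DELETION, chrom="c", db="dbSNP", **kw):
    return DatabaseRecord(database=db, interval=Interval(chrom, start, end),
                          vclass=vclass, **kw)


@pytest.mark.parametrize("pos1,ref,alt,expected", [
    # 1-based pos 100 -> 0-based 99; REF=ACGT,ALT=A deletes [100,103)
    (100, "ACGT", "A", (VariantClass.DELETION, (100, 103))),
    (100, "A", "ACGT", (VariantClass.INSERTION, (100, 101))),
    (100, "A", "G", (VariantClass.SUBSTITUTION, (99, 100))),
])
def test_vcf_indel_to_interval_coordinates(pos1, ref, alt, expected):
    assert vcf_indel_to_interval(pos1 - 1, ref, alt) == expected


def test_long_indels_and_symbolic_alleles_excluded():
    assert vcf_indel_to_interval(99, "A" + "N" * 120, "A") is None
    assert vcf_indel_to_interval(99, "A" + "N" * 100, "A") is None    # boundary: 100 bp
    assert vcf_indel_to_interval(99, "A" + "N" * 99, "A") is not None # 99 bp converted
    assert vcf_indel_to_interval(99, "A", "<DEL>") is None


def test_any_overlap_matching_for_short_indels():
    res = match_short_variants([locus(100, 150)], [record(149, 160)])
    assert len(res.matched_loci) == 1
    res = match_short_variants([locus(100, 150)], [record(150, 160)])
    assert res.matched == [] and len(res.unmatched) == 1


def test_substitutions_need_position_and_allele():
    sub = locus(100, 101, VariantClass.SUBSTITUTION)
    same = record(100, 101, VariantClass.SUBSTITUTION, alt="G")
    other = record(100, 101, VariantClass.SUBSTITUTION, alt="T")
    alts = {"c:100": "G"}
    assert match_short_variants([sub], [same], alt_alleles=alts).matched_loci
    assert not match_short_variants([sub], [other], alt_alleles=alts).matched_loci


@pytest.mark.parametrize("has_assert,submitter,common,kept", [
    (False, "OMIM", False, True),    # OMIM exemption
    (False, "LabY", False, False),   # zero stars, no exemption
    (True, "LabX", True, False),     # common-variant flag
    (True, "LabX", False, True),
])
def test_clinical_record_screen(has_assert, submitter, common, kept):
    rec = record(0, 10, db="ClinVar", has_assertion_criteria=has_assert,
                 submitter=submitter, is_common=common,
                 clinical_significance="Pathogenic")
    assert (filter_clinical_records([rec]) == [rec]) is kept


def test_filtering_and_matching_commute():
    loci = [locus(0, 100), locus(300, 340)]
    records = [
        record(0, 100, db="ClinVar", has_assertion_criteria=True, is_common=False),
        record(300, 340, db="ClinVar", has_assertion_criteria=False,
               submitter="LabY", is_common=False),
    ]
    filtered_first = match_clinical_short(loci, filter_clinical_records(records))
    matched_first = match_clinical_short(loci, records)
    kept = set(map(id, filter_clinical_records(records)))
    surviving = [(l, r) for l, r in matched_first.matched if id(r) in kept]
    assert [(id(l), id(r)) for l, r in filtered_first.matched] == \
        [(id(l), id(r)) for l, r in surviving]


def test_clinical_reciprocal_quarter_rule():
    assert match_clinical_short([locus(0, 100)], [record(0, 100)]).matched_loci
    # overlap 10 bp: 10% of one, 3.2% of the other
    assert not match_clinical_short([locus(0, 100)], [record(90, 400)]).matched_loci


def test_population_sv_rule_is_strict_quarter():
    a = locus(0, 1000)
    assert match_long_population([a], [record(0, 1000)]).matched_loci
    # exactly 25% reciprocal: strict rule rejects
    assert not match_long_population([locus(0, 100)], [record(75, 175)]).matched_loci
    assert not match_long_population([a], [record(5000, 6000)]).matched_loci


def test_pathogenic_rule_is_strict_ninety():
    a = locus(0, 1000)
    hit = record(50, 1000, clinical_significance="pathogenic")      # 95%
    near = record(200, 1000, clinical_significance="pathogenic")    # 80%
    benign = record(50, 1000, clinical_significance="benign")
    assert match_pathogenic_long([a], [hit]).matched_loci
    assert not match_pathogenic_long([a], [near]).matched_loci
    assert not match_pathogenic_long([a], [benign]).matched_loci


def sub_call(pos, ref, alt, gt, chrom="c"):
    return VariantCall(caller=Caller.SMALL_VARIANT, vclass=VariantClass.SUBSTITUTION,
                       interval=Interval(chrom, pos, pos + 1), length=1,
                       call_id=f"s{pos}", genotype=gt, ref=ref, alt=alt)


def test_array_screen_and_exact_concordance_fixture():
    """100 shared loci constructed with exactly 97 concordant."""
    calls, rows, refs = [], [], {}
    for i in range(100):
        pos = 1000 + i * 10
        hom_truth = i % 2 == 0
        gt = (1, 1, 1, 1) if hom_truth else (0, 1, 1, 1)
        calls.append(sub_call(pos, "A", "G", gt))
        concordant = i >= 3                      # first three discordant
        hom_array = hom_truth if concordant else not hom_truth
        a1, a2 = ("G", "G") if hom_array else ("A", "G")
        rows.append({"rsid": f"rs{i}", "chrom": "c", "pos": pos,
                     "allele1": a1, "allele2": a2})
        refs[f"rs{i}"] = "A"
    # screened records: hom-ref and unresolvable rsID
    rows.append({"rsid": "rsHR", "chrom": "c", "pos": 5, "allele1": "A", "allele2": "A"})
    refs["rsHR"] = "A"
    rows.append({"rsid": "rsNA", "chrom": "c", "pos": 7, "allele1": "A", "allele2": "G"})
    cmp = compare_array_genotypes(calls, pd.DataFrame(rows), refs)
    assert cmp.n_array_retained == 100           # hom-ref + unresolvable dropped
    assert cmp.n_shared_loci == 100
    assert cmp.agreement == pytest.approx(0.97)


def test_match_summary_percentages():
    full = match_short_variants([locus(0, 10)], [record(0, 10)])
    empty = match_short_variants([locus(0, 10)], [])
    df = db_match_summary({"all": full, "none": empty})
    by = df.set_index("comparison")
    assert by.loc["all", "percent_matched"] == 100.0
    assert by.loc["none", "percent_matched"] == 0.0
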