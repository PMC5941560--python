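"""Hierarchical cross-caller merging.

Split-read-precision calls form the backbone; read-pair calls reciprocally
overlapping the backbone (>= 25%) are dropped as redundant; the remainder
is union-merged in (adjacent-or-overlapping clusters).  Insertions merge
by direct overlap only, with no hierarchy.
"""

from tetramerge import Caller, VariantCall, VariantClass, Interval
from tetramerge.merge import hierarchical_merge, merge_insertions


def call(caller, start, end, cid):
    return VariantCall(caller=caller, vclass=VariantClass.DELETION,
                       interval=Interval("chr1", start, end), length=end - start,
                       call_id=cid)


backbone = [call(Caller.SPLIT_READ, 1000, 1400, "sr1"),
            call(Caller.SPLIT_READ, 1400, 1600, "sr2")]   # bookended: one locus
redundant = [call(Caller.READ_PAIR, 1100, 1500, "rp1")]    # 67% reciprocal: dropped
novel = [call(Caller.READ_PAIR, 9000, 9500, "rp2")]        # disjoint: merged in

merged = hierarchical_merge(backbone, redundant + novel)
for m in merged:
    callers = "+".join(sorted(c.value for c in m.callers))
    print(f"locus {m.interval.chrom}:{m.interval.start}-{m.interval.end}  "
          f"from {callers}  (source calls: {', '.join(m.source_ids)})")

ins = [VariantCall(caller=c, vclass=VariantClass.INSERTION,
                   interval=Interval("chr1", 500, 501), length=ln, call_id=cid)
       for c, ln, cid in [(Caller.SMALL_VARIANT, 12, "sv1"), (Caller.SPLIT_READ, 30, "sr3")]]
(locus,) = merge_insertions(ins)
print(f"insertion locus at {locus.interval.start}: longest inserted length "
      f"{locus.length} bp kept from {len(locus.source_ids)} calls")
print("note rp1 is absent: the precise backbone takes precedence over "
      "redundant imprecise calls.")
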