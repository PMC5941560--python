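# Methods

## The harmonization model

The package treats a variant catalog as the fixed point of a set of
interval-algebra rules applied to four caller families with very different
breakpoint precision. All coordinates are 0-based half-open internally;
VCF boundaries convert to/from 1-based at parse/emit time. "Adjacent" means
bookended under half-open coordinates (end of one interval equals start of
the next, zero gap): that is the only gap-free reading of
"adjacent or overlapping". An insertion occupies the point interval
`[pos, pos+1)` so that insertions have a well-defined overlap algebra.

Merging is always the transitive closure of a pairwise predicate, computed
by union-find over all pairs. This makes every merge deterministic and
independent of input order; single-linkage chaining (a cluster held
together by intermediate calls) is accepted as a consequence.

### Threshold inclusivity

Boundary sides follow the operating rules exactly and are pinned by tests:

| rule | side |
|---|---|
| split-read: supporting reads | ≥ 2 kept |
| split-read: summed mapping score | ≥ 100 kept |
| split-read: mean mapping score | **strictly > 10** kept |
| read-pair: confidence / pairs | ≥ 80, ≥ 4 kept |
| CNV: t-test p, q0 fraction | removed at ≥ 0.01 / ≥ 0.5 |
| short/long indel split | length ≥ 50 is long (NCBI SV convention) |
| caller comparison / clinical match | reciprocal ≥ 25% (inclusive) |
| population SV match | reciprocal **> 25%** (strict) |
| pathogenic SV match | reciprocal **> 90%** (strict) |
| homozygous-deletion swap | reciprocal **> 50%** (strict) |
| translocation clustering | both breakpoint distances **< 1000 bp** |
| rarity | MAF **< 0.001** (strict); absent record counts as rare |
| tested gene sets | K ≥ 50 |

A variant with no population-frequency record is treated as rare: absence
from a panel of over 60,000 samples is itself evidence of rarity.

### Hierarchical merge

Stage 1 union-merges the split-read-precision calls. Stage 2 drops
read-pair calls that overlap a stage-1 locus under the class comparison
rule and union-merges the remainder in; stage 3 repeats for read-depth
calls. The drop rule during merging reuses each class's comparison rule
(reciprocal 25% for deletions, one-way 25% for duplications and
inversions, applied from the lower-tier call's side); the merge prose does
not state a separate threshold for the drop step, so reusing the
comparison rule is a design choice. Substitutions come from a single
caller and pass through unmerged.

For the homozygous-deletion swap, when two candidates both exceed 50%
reciprocal overlap, the one with the higher reciprocal fraction wins, then
the split-read candidate, then the leftmost — the rule's source is silent
on ties, so the order is fixed for determinism.

### Copy number

Integer CN assignment doubles the normalized depth and rounds into
half-open unit bins `[k − 0.5, k + 0.5)`; the boundary is assigned upward
(2d = 4.5 → CN 5). The published cut points (0.5, 1.5, 2.5, ...) do not
fix a side; upward assignment is the package convention and is
configurable. Modal CN ties break toward the lower CN. Segments are
maximal runs of equal per-bin CN with no minimum length.

On real data a depth track normalized to the genome average would put the
modal normalized depth near 1 and hence CN 2 under the ×2 rule; this
package fixes the convention **normalized depth = CN / 2**, under which
the ×2 rule recovers CN exactly and a tetraploid genome has modal depth 2.
Consumers of real CNVnator output must normalize to the same convention.

The homozygous-deletion pipeline consumes CN-0 calls from the read-depth
caller's call table (after its QC filter and gap masking), not a
re-segmentation of the depth track: the caller's calls *are* its
segmentation, and this keeps one QC path for all read-depth evidence. The
depth track itself feeds the modal-CN and genome-fraction summaries. CN 2
and CN 3 segments (single-copy losses on the tetraploid background) appear
in those summaries but join no merge group, since deletion sites are
defined diploid-relative (CN ≤ 1).

### Enrichment

The hypergeometric upper tail is evaluated through `scipy`'s survival
function, which accumulates the tail in log space; an exact
integer-arithmetic enumeration oracle (binomial coefficients, `Fraction`)
pins it for every universe N ≤ 25 in the tests. Raw p-values are reported
and ranked, matching how the top sets are usually printed; a
Benjamini–Hochberg column is attached as a clearly-labelled extra. Gene
identity is uppercase symbol equality — no alias resolution (a documented
limitation). Ranking is within one collection file at a time.

## The synthetic generator

The generator emulates the *structure* of the real inputs, not their
content: coordinates, ploidy-4 genotypes, support metrics and copy
numbers, but no sequence, no reads, no alignment. Defaults describe a
10 Mb two-chromosome genome at baseline CN 4 with ~95% of bins at
baseline (comfortably above the 65% modal floor), 100 bp depth bins,
telomeric and centromeric gap intervals, and per-class variant counts in
the tens-to-hundreds so a full pipeline run takes well under a second.
These sizes are the package's desk-scale study conditions; every
downstream count scales with them.

Choices worth knowing:

* **Sensitivity model.** Each caller detects each truth variant
  independently with a per-(class, caller) probability whose default
  pattern mirrors which real tools report which classes (only the
  read-pair caller sees intra-chromosomal translocations, only split-read
  and read-pair callers see translocations at all, the read-depth caller
  only copy-number events). A *canonical* map (`SimulationConfig.noiseless()`)
  sets exactly the class-appropriate callers to sensitivity 1 with no
  jitter, no metric failures, no false positives and no depth noise; under
  it the merged catalog is provably set-equal to the truth, which the
  tests assert per class.
* **Support metrics** are rejection-sampled so that a configured fraction
  of true calls fails the downstream QC predicate — the knob calibrates
  how much each filter removes without modelling the real tools' score
  distributions (which the package makes no claim about).
* **Jitter** (Gaussian, sd 120 bp by default) applies only to the
  read-pair and read-depth emulators; the depth caller's jitter is
  quantized to whole bins.
* **Copy-number-bearing truth variants** (long homozygous deletions, long
  deletions at CN 1 or 3, duplications at CN 5–6) are snapped to bin
  boundaries so the binned track represents them without partial-bin
  averaging, making noiseless CN recovery exact. Homozygous deletions
  shorter than 50 bp are emitted only through the small-variant caller
  (as all-alternate-allele deletion genotypes) and do not enter the
  binned CN map — a 30 bp event is invisible at 100 bp resolution.
* **Allele counts**: plain deletions draw 1–3 alternate alleles out of 4,
  because an all-alternate deletion *is* a homozygous deletion and would
  change class. The all-alt probability mass (0.53 for other classes) puts
  the catalog-wide hom/het ratio near 0.635 and the transition probability
  0.677 puts Ts/Tv near 2.1, the values typical of real human catalogs.
* **False positives** are placed uniformly outside gap regions with
  metrics from the same distributions as true calls — one noise model
  exercises both the QC filters and the masking.
* **Databases** plant matches by construction: population-SV records at
  60% reciprocal overlap (above the strict 25% rule), pathogenic records
  at ~98% (above the strict 90% rule), clinical pathogenic records planted
  exactly (half relying on the OMIM exemption), plus records designed to
  be screened out. One GMT set is planted with inflated damaged-gene
  overlap among 120 random decoys; a 30-gene set exercises the size floor.
* **Determinism**: one master seed; every emitter draws from its own
  deterministically spawned substream, so outputs are byte-identical for a
  fixed seed and adding calls to one file never perturbs another.

What passing tests on this generator do **not** show: anything about the
real tools' error profiles, insert-size effects, GC bias, alignment
artifacts, or the absolute match rates of live databases. The synthetic
bundle validates the *rules* — boundaries, precedence, closure,
conservation — not the biology.

## Numerical and degenerate-input choices

* Hypergeometric margins are validated (`0 ≤ k ≤ min(K, n)`, `K, n ≤ N`);
  k = 0 returns exactly 1.0.
* Ratios with zero denominators (hom/het, Ts/Tv) are reported as absent,
  never as 0 or infinity.
* Negative normalized depth is an input error; depth noise is clipped at 0
  during emission, which slightly right-biases CN-0 bins (harmless at the
  default noise sd).
* The CN genome-fraction histogram sums to 1 within 1e-9 by construction
  (integer bin counts over a common denominator).
* Empty inputs: empty call lists merge to empty; an empty damaged set
  yields p = 1 for every set.

## Problem sizes

Default test-suite sizes: 10 Mb synthetic genome (100k depth bins),
~930 emitted calls across four callers, 2,000-gene universe, 121 gene
sets. The brute-force merge oracle is exercised on 1,000 random three-tier
instances of up to 50 calls per tier, and the hypergeometric oracle on
every margin combination for N ≤ 25. The full suite runs in about a
minute on one CPU.

## Known limitations

* Substitution merging across callers is not implemented (a single caller
  reports them here); translocation loci carry representative leftmost
  breakpoints rather than confidence intervals.
* Database schemas are minimal dialects — the fields the match rules need,
  not full dbSNP/ClinVar/DGV/dbVar mirrors; no liftover.
* Genotype likelihoods, VQSR, breakpoint refinement beyond the
  homozygous-deletion swap, and GSEA-style weighted enrichment are out of
  scope.
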