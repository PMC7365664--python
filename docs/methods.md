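# Methods

This note documents the models behind `starrcre`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the published procedure left the design open.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED convention); 1-based
inputs (association tables) are converted once, at the parser boundary.
Merging at `max_gap = 0` joins bookended intervals, matching interval
merging at maximum feature distance 0. Strand is carried but ignored by
merge and intersect: reporter activity is defined on either strand.
Gene-relative offsets ("−245 kb from the TSS") are ordinary intervals on a
synthetic axis anchored at a configurable TSS, which keeps locus-relative
arithmetic (deletion spans of 69 kb and 51 kb, variant-region spans)
testable without a genome sequence.

## STARR-seq activity model

A fragment increments every 50-bp bin it overlaps by ≥ 1 bp (fragment
coverage, not 5′-end counting). Libraries are depth-normalized by scaling
each to the mean of the two library sizes; a pseudocount of 1 is added
after scaling, so every bin has a finite log2 ratio. The coverage filter
(default ≥ 75) applies to the **unscaled combined** treat+control count per
bin: filtering on either library alone would preferentially retain
asymmetric noise. Both the pseudocount and the normalization mode are
plain, reproducible choices exposed as parameters; the comparison records
them in its output.

Region calling proceeds: (1) drop coverage-failing bins; (2) keep bins
whose log2 ratio **strictly** exceeds the threshold (default 0.585, i.e. a
fold change > 1.5); (3) merge surviving bins separated by at most
`max_gap` bins (default 0, so only adjacent bins merge and any dropped bin
breaks contiguity); (4) recompute the region-level fold change from the
depth-scaled, pseudocounted counts **summed** over the merged span and
require it to clear the threshold as well. Summation rather than averaging
of bin-level log ratios is variance-stabilizing and matches a count model.

The alternative order — merge all coverage-passing bins first, threshold
only at region level — is available as `merge_before_threshold=True` for
sensitivity analysis on sparse libraries. It is not the default because
with uniformly deep coverage (the regime a well-constructed tiling library
produces, and the regime the input-library QC checks for) every bin passes
the coverage filter, all bins coalesce into a single locus-wide region
whose pooled fold change is ~1, and nothing is ever called. On the
four-bin worked example in the README both orders give identical output.

Accessible-region selection for ATAC-style signal uses a locus-specific
threshold: every maximal run of signal strictly above the user-supplied
threshold becomes one region. No genome-wide peak model is fitted; the
threshold is a required parameter because no universal value exists for a
single-locus analysis.

Input-library QC reports mean bin coverage inside single-BAC segments and
inside two-BAC overlap segments: an equimolar, evenly represented library
shows a ratio of ≈ 2.

## Orthology mapping

Chain alignments are parsed with their block-sum invariants verified
(blocks must exactly tile the header spans; the final block carries no
gaps). An interval maps through the single highest-scoring overlapping
chain, liftOver's default single-mapping behavior; multi-chain split
mapping is out of scope for determinism. The target interval spans
min..max of the mapped bases, absorbing unaligned gaps internal to the
span — regions, not alignments, are the downstream currency. Reverse-
strand chains produce forward-strand target coordinates with base order
reversed. The default minimum mapped fraction is 0.1, the customary
cross-species liftover setting; it is configurable because the published
counts depend on it.

## Variant prioritization

Selection keeps every SNP with p < 0.05 (strict) lying inside a locus
anchored by genome-wide significant SNPs (p < 5×10⁻⁸, strict). "Locus" is
operationalized as: merge the significant SNP positions at
`locus_gap = 100 kb`, then admit sub-threshold SNPs within `locus_gap` of a
merged span. The 100-kb default is chosen so that two variant regions
~136 kb apart remain distinct clusters — the topology the method is meant
to resolve — and is an explicit assumption, not a published value.

LD is computed from phased haplotypes: r² = D²/(p_A(1−p_A)p_B(1−p_B)) with
D = p_AB − p_A·p_B taken from haplotype counts. Unphased EM estimation is
deliberately out of scope: the haplotype definition is exact and testable,
and real use would draw r² from a reference panel anyway (the panel must
then be specified by the user). Monomorphic sites have undefined r² and
are reported absent with a warning. LD expansion adds every site with
r² > 0.5 (strict) to any lead SNP.

Variant regions are single-linkage clusters of selected SNPs with
inter-SNP gap ≤ `locus_gap`, spanning [min pos, max pos + 1), labelled
VR1, VR2, … in genomic order.

The variant window takes the variant nucleotide plus 10 bases either side
(21 bp); windows that would leave the sequence raise rather than silently
truncate, and only single-nucleotide variants are supported. Motifs
matched (relative score ≥ 0.8 on either strand) in exactly one allele's
window are reported lost or gained.

## Motif enrichment

Count matrices are normalized with a pseudocount of 0.8 distributed
proportionally to the background (common JASPAR practice; configurable).
Scores are log2 odds against the background; N contributes 0. A match is
an offset on either strand whose score reaches 0.8 of the way between the
matrix's minimum and maximum attainable scores ("relative score", the
usual interpretation of default JASPAR scanning).

Set-vs-set enrichment is per-sequence presence/absence with a one-sided
hypergeometric tail on the pooled hit counts, BH-corrected across motifs.
Presence/absence is robust at the 67–181-region scale this pipeline
targets; a per-position binomial model was considered and rejected as more
sensitive to sequence-length imbalance. Both sets can be subsampled to
equal size with a seeded generator (bit-reproducible), mirroring equal-n
comparisons between region sets of different cardinality. Background
sequences are **not** GC- or length-matched; that is a known caveat for
real genomic backgrounds.

## Enhancer prediction

Feature tracks are summarized per bin (default 100 bp): region sets become
0/1 overlap indicators, signals become bin means, absent signal is 0.
Training is scikit-learn's L2-penalized logistic regression (C = 1/λ,
default λ = 1.0, lbfgs, deterministic given data and seed) on labelled
bins only; unlabeled bins (−1) are excluded, and single-class label sets
are an error. When negatives are not given, they default to a seeded
random sample of unlabeled bins at 10× the positive count — standard
practice for enhancer classifiers and configurable. The mechanism, not any
published weight set or the real multi-hundred-dataset compendium, is the
deliverable; the candidate-selection threshold on the probability track is
a required user parameter because no published value exists.

## Evidence integration

Candidates are the merged union of the four evidence streams at ≥ 1 bp
overlap (bookended intervals stay apart); each candidate carries the union
of evidence flags and its source intervals. The 50-bp minimum-overlap rule
is reserved for set-vs-set conservation comparisons, where it is the
stated convention. VR membership is ≥ 1 bp overlap ("location within"),
with a containment mode available. A SNP annotates a candidate iff its
position lies inside the half-open span (start inclusive, end exclusive).
Deduplicated counts are available via `RegionSet.deduplicated()` for
set-comparison bookkeeping.

## Synthetic data: what it emulates, and what it does not

All generators are bit-reproducible given their seed and ship the truth
needed to recompute expected outputs.

**STARR libraries.** The locus (default 1.3 Mb, the size of the
topological domain the design targets) is tiled by overlapping BACs
(default 13); fragments of 500–1000 bp are drawn uniformly within a
uniformly chosen BAC, so two-BAC overlap segments receive ~2× coverage —
the QC signature of an even, equimolar library. Reporter counts per
fragment are negative-binomial (default dispersion 0.1; Poisson at 0)
around `mean_count × weight`. The default depth (250,000 fragments at mean
count 1, ≈ 150 reads per 50-bp bin per library) represents the deep, even
input coverage a locus-tiling screen is built to achieve.

A **planted responsive element** is a multi-kb span of uniformly active
sequence; a fragment transcribes at the elevated rate for a condition only
when it lies **entirely inside** the span. Under this model the activation
footprint coincides with the planted interval, so sensitivity and bp-
precision are well defined against the planted truth. This idealizes two
features of real data: real enhancers have small cores (a fragment
containing the core is active regardless of flanking sequence, which
smears real activation footprints beyond the core), and real fragment
counts carry PCR and transfection covariance the generator omits. Passing
tests therefore demonstrate correctness of the calling arithmetic and its
operating characteristics under the stated model — not calibration on any
particular real library.

**Association/LD.** Each variant region gets a lead SNP at frequency 1/2
(p < 5×10⁻⁸), sub-threshold satellites (p drawn in (0.005, 0.045)),
excluded satellites (p in (0.06, 0.5)), and linked sites copying the lead
haplotype with 5 % per-site flips (E[r²] ≈ 0.81, safely above the 0.5
expansion threshold at 400 haplotypes). Recombination exists only at
block boundaries; no allele-frequency spectrum or imputation noise is
modelled.

**Chains.** Indel chains are built from random breakpoints with sizes
5–50 bp and an exact per-base truth map; inversions emit minus-strand
chains. No rearrangements beyond a single chain per contig.

**End-to-end study.** `simulate_candidate_study` plants 25 candidates —
7 in a distal VR (40 kb span), 13 in a proximal VR (79 kb span), the VR
spans 136 kb apart, 5 outside both — cycling through the four evidence
streams, with 6 variant-bearing candidates per VR (one reachable only
through LD expansion). The higher default depth (mean count 2) keeps the
per-comparison false-positive expectation ≪ 1 bin so the planted counts
are recovered exactly; occasional single-bin strays outside the VRs do
not affect the per-VR truth comparison.

## Numerical choices and degenerate inputs

- Strict inequalities throughout (> 0.585, p < 0.05, r² > 0.5), matching
  their printed forms; ties are rejections.
- Empty fragment sets give all-zero tracks (library size 0), not errors;
  depth scales fall back to 1 for empty libraries.
- Coverage QC with no two-BAC segment reports the ratio as absent rather
  than raising.
- Monomorphic LD pairs: warning + absent, never NaN propagation.
- bedGraph inputs with overlapping spans are rejected at parse time.
- Chain parsing validates block sums against header spans and names the
  offending chain id.

## Problem sizes

The test suite and the acceptance script run the locus simulations at the
full 1.3-Mb geometry with 250,000 fragments per library and the logistic
recovery at 5,000 bins × 10 datasets; oracle-equivalence checks use
≤ 1,000-element random instances. The complete suite runs in well under a
minute on one CPU.

## Known limitations

- No BAM/bigWig random access, tabix, UMI handling or duplicate marking;
  the pipeline consumes aligned fragments as BED or text SAM.
- Best-chain-only liftover; split mappings are dropped, so counts near
  assembly breakpoints are conservative.
- Motif enrichment has no GC/length-matched background construction and
  makes no attempt to replicate any specific scanner's score internals;
  rank agreement, not p-value equality, is the meaningful comparison
  against other tools.
- Real-data region counts depend on the deposited libraries, catalogue
  versions, chain files and unpublished thresholds; the package reproduces
  mechanisms and their operating characteristics on synthetic truth, and
  exposes every such threshold as a parameter.
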