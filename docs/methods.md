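# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind each stage of the pipeline. Coordinates are
0-based half-open throughout (BED convention); GFF3 input (1-based closed)
is converted at the I/O boundary. The overlap predicate is "shares ≥ 1
base" unless a stage states otherwise.

## Coding-potential partition

Genic space is the union of (i) every annotated gene — high **and** low
confidence — extended `tss_ext` (default 500 bp) upstream of its TSS on its
own strand, and (ii) every externally thresholded transcribed region
(RNA-seq signal > 1 TPM) and lncRNA, extended `transcribed_ext` (500 bp) in
both directions. Intergenic space is the complement; the two tile each
chromosome exactly, which `GenomePartition.check_tiling` asserts. The TSS
extension is deliberately upstream-only: the gene body is already genic and
the promoter-proximal margin is what contaminates intergenic CRE calls.
Whether the margin should also apply at the transcription end site is
genuinely open; we extend the TSS only. TPM computation is out of scope —
transcribed regions arrive pre-thresholded.

## UMR calling

The methylome is summarized on a fixed, genome-anchored grid of
non-overlapping 300-bp windows (the last partial window of a chromosome is
allowed). Within a window and context, the level is coverage-weighted,
`Σ n_meth / Σ n_total` over cytosines with depth ≥ `min_cov` (5) — the same
estimator as the genome-wide level, and robust to shallow sites, unlike a
mean of per-site fractions. A window is unmethylated iff every context
**with covered cytosines** is ≤ `max_meth` (1 %); a context with no covered
cytosine passes vacuously, but a window with no covered cytosine in *any*
context is "no-data" and can never join a UMR — this keeps unmappable,
TE-dense regions from surfacing as spurious UMRs. Runs of adjacent
unmethylated windows merge (strict adjacency; no methylated window may
intervene), merged blocks are clipped to intergenic space, and each piece
carries the window count of its parent block. Lowering `max_meth` can only
remove windows (monotone). "Permanent" UMRs default to A-anchored ≥ 1 bp
overlap with the second sample's set; B-anchored and base-level
intersection are available via `mode=`.

## Robust cCREs and chromatin-state summaries

A robust cCRE is an intergenic ATAC peak overlapping ≥ 1 UMR and ≥ 1 H3K9ac
peak; its geometry is the ATAC peak itself (ATAC-anchored counting), not
the three-way intersection region. "Intergenic" for a peak defaults to the
midpoint rule — a peak straddling the 500-bp genic margin should not be
discarded wholesale, and the midpoint is deterministic; `any`-overlap and
`fully-contained` modes are available. Weak E7 segments are open-chromatin
state segments with zero overlap against ATAC, UMR and H3K9ac sets; by
construction they are disjoint from robust cCREs. Pooling across stages
merges the per-stage E7 sets into union elements; each pooled element's
stage membership is ≥ 1 bp overlap with that stage's set (pooled elements
are merged unions, so exact identity across stages does not exist), and the
Venn cells always sum to the pooled total. Stage-specific robust cCRE sets
do not subtract other stages' E7 segments.

## CAGE directionality

Tag clusters are first pruned to strictly intergenic space: a cluster
survives only if its gap to every gene and every RNA-seq signal region
exceeds 500 bp (`> margin`, so a cluster exactly 500 bp away is removed and
one at 501 bp is kept) and it overlaps no lncRNA. Antisense merging links
two opposite-strand clusters when their dominant TSSs — not cluster edges;
the merged unit is delimited by dominant TSSs, so the same anchor keeps the
rule self-consistent — are ≤ 600 bp apart (inclusive) and at least one of
the two, viewed as the other's antisense partner, has TPM > 0.1 and more
than one CTSS position. The eligibility is deliberately one-sided: a
singleton may nucleate a merge when its partner qualifies; two mutual
singletons never merge. Connected components (union-find) holding both
strands become one bidirectional unit spanning from the component's minimum
minus-strand dominant TSS to its maximum plus-strand dominant TSS; if that
span would be empty (convergent geometry) the coordinate span of all
dominant TSSs is used so the interval stays valid. Strand TPMs are sums
over member clusters. Classification: U for single-stranded components;
otherwise `log2fc = log2(plus/minus)`, BB iff −1 ≤ log2fc ≤ 1 (bounds
inclusive), else BU; zero TPM on one strand yields BU with a ±∞ sentinel.
Merging is order-independent (inputs are canonically sorted first).

## HiChIP loop annotation

Loops are FitHiChIP-style bin pairs; anchors are snapped to the resolution
grid (`floor(start/r)·r`), oriented so anchor1 ≤ anchor2, and duplicate bin
pairs keep the smallest q-value. Significance filtering applies q ≤ FDR
(0.05) and midpoint distance ≤ 2 Mb. Each anchor takes the first label in
the fixed hierarchy active promoter → silent promoter → terminator →
intron → E7 → E4 → TE with ≥ 1 bp overlap, else "other"; missing tracks are
skipped. Promoter and terminator tracks are built as TSS/TES ± half a
resolution window, promoters split into active/silent by H3K4me3/H3K27me3
peak overlap (a mark-status split at the promoter; the window size is
configurable since no canonical promoter window exists at 5-kb bins).
Interaction classes are unordered label pairs (loops have no orientation);
a "centric" restriction keeps loops with ≥ 1 anchor of the stated label and
reports both anchors' labels, so either centric convention can be
recomputed. Spanned genes are genes fitting inside the half-open gap
`[anchor1.end, anchor2.start)`; per-promoter degree counts distinct loops
with ≥ 1 anchor on the promoter (a loop touching it with both anchors
counts once); self-loops join one gene's promoter window and the same
gene's terminator window in different bins; bivalent interactions are bin
pairs present in both the H3K4me3 and H3K27me3 sets at equal resolution
(bin identity, symmetric in the two inputs); distances are anchor-midpoint
separations.

## Statistics

*Permutation overlap test.* Observed = number of query intervals
overlapping the reference (≥ 1 bp). Each of `n_perm` (500) permutations
re-places every query interval uniformly at random over all valid start
positions inside the merged universe, preserving length and chromosome;
placed intervals may overlap each other (the standard behaviour of genomic
randomization tools — the universe argument is how callers restrict to
intergenic space). z = (obs − mean)/sd of the permuted counts; the
empirical p uses the add-one estimator `(1 + #extreme)/(1 + n_perm)`, so
p is never 0 and equals 1/501 when the observation beats all 500 permuted
values.

*Co-cluster chi-square.* For gene pairs with cluster assignments,
`P(same) = Σ_k f_k²` with `f_k` the cluster frequencies among the distinct
genes appearing in pairs (each gene once; genome-wide marginals available
via `marginals="all"`), and a 1-df goodness-of-fit chi-square compares the
(same, different) split with expectation. Pairs with an unassigned gene are
excluded and counted. A single observed cluster is degenerate and raises.
The contingency-table form is not used; goodness-of-fit is the default and
only form exposed.

*Hypergeometric overlap* is the exact upper tail P(X ≥ |A∩B|) with
population |universe|, successes |B|, draws |A| (scipy). *Rank-sum* is the
two-sided Mann-Whitney/Wilcoxon normal approximation with tie correction
(scipy's asymptotic method). The permutation machinery is implemented here;
the closed-form distributions come from scipy — reimplementing them would
add risk without adding science.

## Conservation averaging

The track is sparse: bases without alignment support are missing. Per
interval, aligned-only mode averages defined bases only (an interval with
none has no mean and is reported missing); missing-as-zero mode divides the
sum of defined scores by the full interval length. Since scores are
non-negative, missing-as-zero ≤ aligned-only for every interval. The
set-level mean is the unweighted mean of per-interval means (element-level
summary — distributions are compared per element, and a base-weighted mean
would let a few long elements dominate); both per-interval values and the
set mean are emitted so a base-weighted summary can be recomputed.
Size-matched random regions preserve each template's length and chromosome
and place uniformly within a universe, erroring (with the offending
template named) when a length fits nowhere.

## Synthetic data: what it emulates and what it does not

The generator lays the genome out in 30-kb slots — a common multiple of the
300-bp methylation window and the 5-kb loop resolution — each hosting at
most one planted feature, centered so that a single 5-kb bin overlaps
exactly that feature. This makes planted loop-anchor labels unambiguous and
planted mixtures identifiable. Defaults (two 3.9-Mb chromosomes; 70 active
+ 24 silent + 8 long self-loop genes; 50 planted 900-bp UMRs of which 30
host cCREs; 36 E4 blocks with embedded 300-bp UMRs; 20 TEs; 6 weak-E7 and 6
stage-specific E7 segments; 34 CAGE units across U/BU/BB/decoy/singleton
architectures; 2,000 planted loops in a 30/25/20/15/10 five-class mixture
plus 100 decoys above the FDR cut, 60 silent-silent H3K27me3 loops and 40
bivalent pairs) are sized so that every planted feature class is
recoverable and the distinct-bin-pair demand of the loop mixture stays
below pool capacity with margin. Methylation is Beta-Binomial: per-cytosine
levels Beta-distributed with means 0.886/0.581/0.014 (CpG/CHG/CHH,
concentration 2) — the genome-wide levels of a highly methylated cereal —
with Poisson(10) read depth and ~6-bp cytosine spacing; planted UMRs are
fully unmethylated. CAGE partner distances are drawn strictly inside
(100–550 bp) or outside (700–1,500 bp) the 600-bp merge window and BB/BU
log-ratios strictly inside (±0.9) or outside (±1.2–3) the balance bound, so
classification on clean geometry must be exact. Loops are planted as
*distinct* bin pairs: with-replacement sampling would collide with bin-pair
deduplication and distort the recovered mixture. Interacting
active-promoter pairs co-cluster with probability 0.45 against a 5-cluster
uniform background; TF labels are enriched (0.5 vs 0.05) among
E7-interacting genes. Conservation scores are elevated over cCREs
(0.4–0.9) and exons (0.5–0.95) against sparse low background patches
(0–0.08).

What it does **not** emulate: read-level data (no FASTQ/BAM), sequence
content, mappability structure, replicate noise, peak-boundary uncertainty,
overlapping or nested features, partial methylation at CRE shores, and
distance-decay of contact frequency. Passing tests therefore demonstrate
the correctness of the downstream logic on well-posed inputs — recovery
rates on real data will be bounded by upstream peak calling, alignment and
loop-calling quality, which are outside this package.

All randomness flows from one `numpy.random.Generator` seeded once; the
bundle is byte-identical across runs with the same seed.

## Pipeline determinism and problem sizes

`run_all` is a pure function of inputs plus config: the summary is
sorted-key JSON without timestamps, so identical configs produce
byte-identical reports. The default synthetic problem sizes (7.8-Mb genome,
~1.2 M cytosines, 2,000 planted loops, 500 permutations) were chosen so the
full chain completes in seconds while every statistic operates far from
small-sample degeneracy. The statistical calibrations in the test suite use
200 permutation-test runs (null z mean/sd), and 500 replicates each for the
chi-square and rank-sum type-I error, with 400-gene pools and 500 pairs per
replicate — large enough that the estimated-marginal chi-square sits near
its nominal level.

## Known limitations

* UMR merging is strictly adjacent; window-gap tolerance (as some windowed
  methylome methods allow) is not implemented.
* `interactions_per_promoter` and per-block UMR clipping are per-record
  Python loops — fine at the tested scales (10³–10⁴ records), not tuned
  for millions of loops.
* The hierarchical annotation assigns one label per anchor; co-occupancy
  within a bin is invisible by design (that is what the hierarchy is for).
* The chi-square concordance test treats pairs as independent; shared genes
  across pairs mildly violate this, as they do in the analogous analysis on
  real interactomes.
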