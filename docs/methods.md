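# Methods

This note documents the models, defaults, numerical choices and known
limitations of splicemeth. Every empirical number quoted here is computed
by the test suite or the analysis scripts in this repository.

## Annotation model

Coordinates are 1-based inclusive (GTF convention); BED output is 0-based
half-open. A gene is a set of transcripts, each an ordered list of
non-overlapping exons on one strand. Flattening cuts the union of a gene's
transcript exons at every distinct exon boundary, giving disjoint counting
bins labelled `E001…` in transcription order (reversed genomic order on the
minus strand). Maximal gaps between genomically consecutive bins are introns
`I001…`, also 5'→3', each carrying its two flanking bin ids; adjacent bins
produce no intron. The promoter is the ≤ 3 kb window immediately upstream of
the gene's 5'-most TSS across transcripts, clipped at position 1. Genes are
flattened independently; overlapping genes are not aggregated (region
assignment resolves cross-gene conflicts by a fixed category precedence and,
within a category, the lowest gene id — deterministic, configurable).
Per-transcript promoters are not modelled; the promoter window and the
TSS rule are parameters.

## Count models and tests

**Size factors.** Median-of-ratios: the reference is the per-feature
geometric mean over samples, computed over features with no zero counts;
each sample's factor is the median ratio to the reference. When no feature
is everywhere-positive, an optional zero-ignoring pseudo-reference is
available (used for sparse exon-bin matrices). Note that the *absolute*
factors are defined only up to the reference: scaling one sample's column
by c scales its factor by c^(1−1/m) and everyone else's by c^(−1/m);
factor *ratios* are exactly equivariant, which is the invariant the tests
assert.

**NB-GLM.** Counts are NB2 (variance μ + αμ²) with a log link and
log-size-factor offset. Fitting is ridge-stabilized (λ = 1e-8) iteratively
reweighted least squares with step-halving; convergence is declared at
max |score| < 1e-8 or a Newton decrement ½·sᵀI⁻¹s < 1e-10 (scale-invariant;
plain score magnitude is meaningless when rest-of-gene sums reach 1e4),
with a 100-iteration cap and an explicit non-converged flag (p set to NaN,
never silently dropped).

**Dispersion.** Per-feature profile maximum likelihood over log α
(bounded scalar optimization in [1e-8, 30], tolerance 5e-3 on log α), with
a method-of-moments fallback on optimizer failure and a 1e-8 floor for
degenerate features. The profile likelihood carries the **Cox–Reid
adjustment** (−½ log det XᵀWX): without it the MLE is biased low at
study-sized designs (n = 19) because the mean parameters are estimated from
the same few samples, and the downstream Wald p-values are visibly
non-uniform under the null (type-I ≈ 0.078 at α = 0.05, KS-vs-uniform
p ≈ 5×10⁻⁴ over 2000 null features). With the adjustment the same
simulation gives type-I ≈ 0.06 and KS-uniformity p ≈ 0.4, and the
dispersion estimate is approximately unbiased (median ≈ 0.095 at true 0.1).
No empirical-Bayes shrinkage across features is applied — each feature is
tested with its own dispersion, and calibration is established by the null
simulations in `tests/test_acceptance.py`, not by matching any external
tool.

**DIE.** Isoforms with ≥ 2 reads in ≥ 9 samples (group-agnostic) are tested
by a Wald test on the condition coefficient; log2FC = β̂/ln 2. Nominal
p-values drive the significance flag (default 0.01); a Benjamini–Hochberg
column can be emitted for reference but is never used for calling.

**DEU.** Genes whose summed bin counts pass the same 2-in-9 rule and that
have ≥ 2 bins are tested bin by bin: the response stacks, per sample, the
bin's count and the sum of the gene's other bins; the model has condition,
part (this bin vs rest) and their interaction, with the same offsets in
both parts; the LRT against the no-interaction model has 1 df. This
"this-bin-vs-rest" formulation tests the same per-bin null hypothesis as a
joint all-bins model at a fraction of the cost; size factors are computed
once from the full bin matrix. All-zero bins are skipped with a flag but
still contribute to their siblings' rest sums. Each part carries its own
Cox–Reid profile-ML dispersion (estimated from the bin counts and the rest
counts separately, entering the stacked fit as a per-observation
dispersion): the rest-of-gene sum is genuinely less dispersed than a single
bin, and forcing one shared dispersion left the bin part under-dispersed in
the fit — the null simulation showed a mildly anticonservative LRT
(uniformity KS p ≈ 0.002 over 2000 null genes) that the per-part
dispersions repair (type-I ≈ 0.06, uniformity p ≈ 0.26).

**DM.** Cytosine reports are merged by (chrom, pos, strand); CpG-context
records with coverage ≥ 8 are kept, dropping under-covered samples
record-wise and requiring ≥ 2 covered samples per condition (an
all-samples rule is available). Each strand of a CpG is tested separately
(an optional palindrome merge pools pos/pos+1); single-cytosine resolution
only, no tiling. For a single two-level factor the binomial-logistic MLE is
the pooled per-group proportion, so the LRT is computed in closed form and
vectorized across cytosines; boundary proportions are exact via x·log x → 0,
so complete separation needs no special-casing. The effect is the
difference in fitted group proportions in percentage points. No
overdispersion correction is applied (the generator's counts are binomial;
a beta-binomial switch in the generator lets the user probe sensitivity).

## Integration

Every evaluated cytosine is assigned to exactly one category with
precedence exon > intron > promoter > intergenic (position-based; cytosine
strand ignored). The methylation level of a region set is
n_DM / n_evaluated; levels with n_eval = 0 are undefined and excluded (and
counted: the report records how many DEU/DIE genes had methylation data).
For each gene with ≥ 1 differentially used bin, bins are partitioned into
significant vs non-significant and introns into contiguous (sharing a
boundary with a significant bin in 5'→3' order, ≤ 2 per significant exon)
vs non-contiguous. For each gene with ≥ 1 significant isoform, bins are
partitioned by interval overlap with the significant isoform's exons. Five
KS comparisons are reported: the two DEU partitions, the DIE partition, and
promoter levels of DIE vs non-DIE and DEU vs non-DEU genes. KS p-values are
nominal (no multiplicity correction across the five comparisons), exact for
n_a·n_b ≤ 10⁴ and asymptotic otherwise.

**Pooled vs per-gene distributions.** The distributions entering the KS
tests are pooled per-feature by default: one level per exon bin, intron or
promoter. The per-gene aggregation (one value per gene per class) is
implemented behind a flag but is *anticonservative for the exon
comparison*: the significant class is typically a single short bin whose
level is a ratio over a handful of cytosines, while the non-significant
class pools several bins; the resulting difference in zero-inflation is a
distribution-shape difference that KS detects even when DM sites are placed
uniformly at random. In the null simulation (coupling = 1, 80 genes) the
per-gene exon comparison rejected at p ≤ 0.001 in roughly a fifth of seeds,
while the pooled comparison is exchangeable under the null and rejected in
none of 30 design-check seeds. Per-feature pooling compares similar-sized
regions and avoids the artifact; per-gene levels are still always written
to the region-level table. Users applying the per-gene mode to real data
should interpret the exon comparison with this caveat in mind.

## Synthetic data generator

The generator emulates the study design: 9 control vs 10 treatment RNA
samples and 7 vs 9 bisulfite samples over (by default) 300 non-overlapping
genes on one synthetic chromosome. Per gene, a skeleton of 3–9 exons
(80–300 bp, introns 200–1500 bp) is built; transcript 1 carries the full
skeleton and 1–2 further transcripts drop internal exons at random, so
flattened bins coincide with skeleton exons and planted per-bin effects stay
identifiable. Isoform baseline expression is log-normal (median ≈ 150
counts, log-sd 1), per-sample depth is log-normal (sd 0.2), and per-feature
NB dispersions are log-normal around 0.1. Bin means distribute each
transcript's mean over its exons by length; bin counts are NB-resampled.

Planted effects: a fraction (default 10 %) of isoforms get their treatment
mean multiplied by 2^2; a fraction (default 30 %) of genes get one bin's
usage share shifted ×4 in treatment with shares renormalized within the
gene. The planted bin is first rebased to a **minor usage share (3 %)** in
both conditions — the profile of a minor alternative exon. This matters:
renormalization gives every sibling bin a real fold-change
1/(1 + w(s − 1)); with uniformly chosen bins (mean share ~1/6) that is
≈ 0.67, a genuine usage change that flagged ~47 % of sibling bins, whereas
at w = 0.03 planted bins are recovered at ≈ 99 % with ≈ 6 % sibling flags.

The methylome places CpG sites at 2 per 100 bp (a genic-region density;
the genome-wide average including CpG deserts is nearer 1) in gene bodies,
promoters and intergenic gaps, with ≥ 2 bp spacing. Each site emits a +
strand record and a − strand record at pos + 1 sharing the site's
methylation state, with independent Poisson(20) coverage per strand and
sample and binomial methylated counts. Baselines are drawn from a bimodal
beta mixture (0.6·Beta(8,2) + 0.4·Beta(2,8), the usual
high/low-methylation split); DM sites move by ±0.30 toward the side with
headroom. DM sites are drawn as exact stratified counts:
round(min(1, 0.04·coupling)·n) sites inside coupled regions (planted bins
plus their flanking introns) and round(0.04·n) outside, so ground-truth
sizes are deterministic given the seed. Randomness is split into three
independent substreams (annotation, counts, methylome) spawned from one
seed, so changing methylome parameters never alters the count matrices.

What the generator does **not** emulate: read-level artifacts (mapping,
M-bias, PCR duplicates), batch effects, extra-binomial methylation variance
(optional beta-binomial switch aside), sequence content, overlapping genes,
and correlated methylation between neighbouring CpGs. Passing tests
therefore show that the pipeline's statistics behave as designed under
their stated models — not that those models capture every property of real
bisulfite or RNA-seq data.

## Problem sizes used by the checks

The acceptance run uses 300 genes (≈ 600 isoforms, ≈ 1800 bins, ≈ 200k
cytosine records) and finishes in about a minute. Null-test calibration
uses 2000 features per test at the study's sample sizes; parameter-recovery
uses 200 planted replicates; the null-specificity loop runs 100 seeds at 80
genes each. These sizes were chosen once as the smallest at which the
binomial confidence bands in the criteria are meaningful.

## Known limitations

* Per-feature dispersion without information sharing loses power relative
  to shrinkage estimators at very low counts; the filters (2-in-9) keep the
  tested features away from that regime.
* The this-bin-vs-rest DEU model treats the rest-of-gene sum as NB with the
  bin's dispersion; the sum of NB bins is formally less dispersed. The null
  simulations show the resulting LRT is calibrated at the study design, but
  heavy per-gene bin-count imbalance could stress the approximation.
* The ratio-based methylation level is undefined for regions without
  evaluated cytosines and noisy for regions with few; the per-gene KS mode
  inherits the granularity artifact described above.
* The enrichment module tests terms independently and reports raw Fisher
  p-values; no term-size bounds or cross-database deduplication.
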