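# Methods

`plureval` re-implements, as a tested and reusable pipeline, a methodology
for comparing transcriptomes across ploidy levels in synthetic allohexaploid
wheat: a diploid *Aegilops tauschii*-like parent (genome DD), a tetraploid
durum-like parent (AABB) and synthetic hexaploid derivatives (AABBDD). The
package operates from the count-table level down — read trimming, mapping
and feature counting are out of scope — and is exercised end to end on a
synthetic-data generator with known ground truth.

## Why cross-ploidy comparisons need special handling

A diploid library and a hexaploid library of equal sequencing depth spread
their reads over transcriptomes of very different size: a D-subgenome gene
that takes fraction *p* of the diploid's library takes roughly *p*/3 of the
hexaploid's. Naive whole-library normalization therefore manufactures an
apparent ~3-fold "downregulation" of every parent-native gene — right at a
fold-change-3 significance threshold — and the residual is amplified by
cross-mapping between near-identical homoeologous copies. The pipeline
neutralizes both effects with three devices:

1. **Subgenome-mismatch correction.** Reads from one parent that map to the
   other parent's subgenomes (AB-assigned reads in the diploid, D-assigned
   reads in the tetraploid) measure the cross-mapping contamination that the
   hexaploid unavoidably carries. Each parent's mismatch RPMs are scaled by
   the share of the hexaploid transcriptome the donor genome represents (1/3
   diploid, 2/3 tetraploid), averaged across the donor's replicates, and
   added to every library of the *other* parent. The averaged RPM is
   converted to the recipient's count scale through its hexaploid-equivalent
   depth, `column_total / native_share` (native share 1/3 for the diploid,
   2/3 for the tetraploid). Dividing by the native share is what makes the
   transfer balance exactly against the contamination accumulating in the
   hexaploid once the split-group library sizes (below) are used; converting
   with the bare column total would leave the transferred signal 3× (D side)
   or 1.5× (AB side) short, parking contaminated features exactly at the
   fold-change threshold.

2. **Split-by-subgenome normalization.** Hexaploid tables are split into
   their AB- and D-parts; each part is TMM-normalized *together with the
   matching parent* and never against a whole library of different ploidy.
   Library sizes are recomputed per partition. Only identical genotype
   lineages are normalized together (one group per parent genotype and
   partition).

3. **Parental TE redistribution.** TE families are quantified per family
   with randomly placed multi-mappers, which smears each family's reads
   roughly evenly across the A/B/D/un subgenome buckets regardless of their
   true origin. In the parents the origin is known, so the smeared counts
   are reassigned: diploid — everything to the D bucket; tetraploid — the D
   and unassigned buckets split equally between A and B (the equal split is
   our choice; the source rule does not specify one). Synthetic samples keep
   their buckets; the midparent test consumes family totals (A+B+D+un), so
   the choice is inconsequential there.

## Statistical machinery

**TMM.** Trimmed mean of M-values with the published defaults: reference =
library whose upper-quartile count fraction is closest to the mean upper
quartile; genes positive in both libraries; 30% two-sided trim on M, 5% on
absolute intensity; inverse-asymptotic-variance gene weights; factors
rescaled to geometric mean 1. The implementation reproduces
`edgeR::calcNormFactors(method="TMM")` to 9 decimals on every matrix we
tested. Note that exact invariance under multiplying one library by a
constant does not hold with precision weights (the canonical implementation
behaves identically); the residual is below 1% for replicate-like libraries
and nil for pure depth scaling.

**Dispersion.** Per-feature NB dispersion φ (variance = μ + φμ²) by a
method-of-moments estimator on depth-normalized counts, pooled over
conditions with ≥ 2 replicates, shrunk toward the 10%-trimmed common
dispersion with a prior weight of 10 degrees of freedom, floored at 1e-6.
With no replicated condition the estimator falls back to a fixed 0.1 with a
logged warning.

**Differential expression.** Per feature, an NB likelihood-ratio test of
equal means with log effective library sizes (partition totals × TMM factor)
as offsets, fitted by Newton iterations on the log-mean. Because the
χ²₁ reference is liberal in the extreme tail with 3 replicates per side and
estimated dispersions, the signed root of the LRT is referred to a
t distribution with (residual df + dispersion prior df) degrees of freedom —
the moderated-t idea. Under the generator's NB null at n = 3+3 and φ = 0.1
this yields a raw p < 0.05 fraction of 0.045–0.047 and essentially no false
DEGs at the reporting thresholds, while retaining > 99% power for 8-fold
changes at baseline mean 100. p-values are Benjamini–Hochberg adjusted per
normalization group; a gene is a DEG at FDR < 0.01 and fold change > 3
(|log2FC| > 1.585, strict).

**TE midparent test.** Midparent pseudo-libraries MPV = 1/3·RPM(diploid) +
2/3·RPM(tetraploid) per TE family, one per combination of parental
replicates. Family RPMs are always per million reads of the *whole* library
(genes + TEs), never of the TE subset alone — renormalizing within the TE
subset distorts relative family levels whenever any family moves. Rounded
RPM totals are tested with the same NB machinery on a common unit depth.
The pseudo-libraries are not independent (they share replicates), which
makes the test mildly anti-conservative; the fold-change-3 requirement
absorbs this at the family counts used here.

**In-silico karyotyping.** Genes with TPM > 0.01 in fewer than two samples
are removed; windows of 200 position-ordered genes per chromosome
(non-overlapping; a final partial window is kept if it holds at least half a
window); per-window median TPM of the polyploid sample is divided by the
median of the replicate-averaged parental reference (AB genes from the
tetraploid, D genes from the diploid). Because raw hexaploid-vs-parent
ratios sit near 1/3 (D) and 2/3 (AB) for euploid chromosomes, ratios are
rescaled by the median raw ratio within the sample's subgenome partition,
restoring the 1 / ~0.5 / ~1.5 semantics for euploidy / monosomy / trisomy.
Chromosomes are flagged from their median rescaled window ratio (monosomy
band [0.35, 0.65], trisomy band [1.35, 1.65]). Flagged samples are kept
with a warning by default and excluded when `exclude_flagged: true`.

**Homoeolog bias.** Per triad, replicate-mean RPMs of the A/B/D homoeologs
give a point on the 2-simplex; triads with total mean RPM below 5 are
removed (exactly 5 is kept). Categories are nearest-of-seven centroids in
Euclidean ("eigen") distance: centre (1/3,1/3,1/3) = Balanced, vertices =
Dominant A/B/D, edge midpoints = Suppressed A/B/D; ties (a measure-zero
event) break by fixed centroid order, Balanced first. The in-silico parent
is 0.33·diploid RPM + 0.67·tetraploid RPM, replicate-averaged. Movement
between two categorized states is the Euclidean distance between
contribution vectors; movements are reported when the category changed and
the distance exceeds 0.3. Bias–DE association uses a two-sided Welch
T-test on log2 fold changes of dominant (> 2/3 contribution) vs suppressed
(< 1/6) homoeologs — exact fractions, strict comparisons — and a 2×2
chi-square (no continuity correction) of triad-has-DEG × triad-unbalanced.

**Overlap statistics.** Exact upper-tail hypergeometric P(X ≥ k) with a
continuity-corrected normal approximation and the representation factor
k/(n1·n2/N); the background is the genes expressed in both compared
analyses. Direction concordance of shared DEGs uses a two-sided exact
binomial test at rate 1/2 on the discordant count (sidedness is our choice;
both tails are implied by the two-sided p).

## The synthetic-data generator

The generator emulates post-mapping count tables, not reads. Counts are NB
(variance = μ + φμ²; gamma–Poisson sampling; Poisson at φ = 0) around
expected values built from: a per-triad baseline (lognormal with location
`baseline_mean` = 100 and spread σ = 0.5), a per-triad bias vector on the
simplex (Dirichlet(8,8,8) by default — mostly balanced triads, i.e.
parental legacy shared by parents and synthetics), optional DE effects in
the synthetics, chromosome dosage for planted aneuploidies, and library
depth. Every library is sequenced to a comparable total (default
n_genes × baseline_mean, with 0.1 lognormal jitter), so parent-native genes
take proportionally larger shares of parent libraries — the property that
makes naive cross-ploidy normalization fail. Genomes have 7 chromosomes per
subgenome, as in wheat. Cross-mapping is injected by moving a
Binomial(count, mismatch_rate) portion of each gene's reads to its homoeolog
partners (triad members split the moved reads equally; singleton genes feed
a dedicated decoy feature), conserving library totals; the default rate is
0.02, a free parameter since no measured value is available. TE families
draw a per-library family total NB around the role-specific RPM level
(synthetic level = MPV × 2^effect) and smear it multinomially across
A/B/D/un buckets with equal default weights.

What the generator does *not* emulate: gene-length biases in counting,
positional/GC effects, correlated gene modules, isoform structure, partial
homoeologous exchange, or realistic wheat annotation densities. Passing
recovery tests therefore demonstrates the internal consistency and
calibration of the pipeline under the stated statistical model, not
performance on any particular real dataset.

## Benchmark experiments and problem sizes

`plureval.benchmarks` wires the generator to the pipeline at desk scale
(seconds to ~1 minute per experiment on one CPU):

- karyotype copy-ratio recovery: 5600 triads (800 genes per chromosome,
  4 windows of 200), baseline 100, φ = 0.1, 3 replicates, no cross-mapping
  overlay; the affected chromosome's median rescaled ratio lands at
  ~0.50 (monosomy) and ~1.47 (trisomy) with seed-to-seed spread ≈ 0.015 and
  0.05 respectively;
- DE calibration: ~2000 gene features, n = 3+3, φ = 0.1, 20 seeded null
  runs (zero DEGs expected) and 8-fold-change power runs;
- mismatch-correction efficacy: 800 triads + 300 singletons with decoys,
  mismatch rate 0.05, no true DE; spurious DEGs on contamination-receiving
  features, corrected vs uncorrected (observed ≈ 1 vs ≈ 300);
- split-vs-whole-library normalization: no-DE ploidy contrast with default
  contamination; false DEGs ≈ 0 (split) vs hundreds (whole-library);
- TE MPV recovery: 20 null families and 5 families at 8× MPV across RPM
  levels 100–800, 20 seeded runs.

## Numerical choices and degenerate inputs

Newton fits cap the log-mean in [-30, 30] and the step at ±3; all-zero
features report log2FC 0 and p 1. Dispersions floor at 1e-6. BH ties break
by (p, feature_id) for reproducibility. Karyotype windows with a zero
reference median are dropped with a warning. Zero-count features are
removed after group normalization (in that order). TSV I/O is UTF-8,
tab-separated, `NA` for missing, 12 significant digits.

## Known limitations

- The DE machinery is calibrated against its own generative model; it is
  not a numerical clone of edgeR's Cox–Reid/GLM path (only TMM is
  reproduced exactly).
- MPV pseudo-library correlation is ignored by design (all parental
  replicate combinations are treated as libraries).
- The karyotype screen detects whole-chromosome dosage; sub-chromosomal
  events are visible in the window tracks but not auto-called.
- Homoeolog bias uses triads only; paralog expansion and dyads are out of
  scope.
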