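# Methods

## The screening model

The screening pipeline treats a pooled microarray compendium as a single
log2-scale genes × samples matrix with three annotation columns per
sample: tissue class (diseased/normal glomeruli or tubules, bladder,
bladder cancer, UTI leukocytes), dataset of origin, and platform.

**Harmonization.** Different array generations share only part of their
probe catalog, so pooling starts from the intersection of feature sets
across platforms (sorted lexicographically for deterministic output).
Quantile normalization then forces every sample onto the common
distribution of across-sample sorted means; within-sample ties receive
the mean of the reference values at the tied ranks, which makes the
transform deterministic and invariant to row order. Probe-level
summarization by Tukey median polish (alternating row/column median
sweeps; the per-sample summary is overall + column effect) is available
for probe-grouped inputs but is not required by the matrix-level
pipeline. Convolution-style background correction is out of scope: it
needs probe-level raw data that a pooled expression matrix no longer
carries.

**Quality control runs before normalization.** Per-array scale factors
(median of 2%-trimmed linear-scale means over arrays, divided by each
array's trimmed mean), fraction of features detected above a log2
threshold, relative log expression (RLE = value minus gene-wise median
across samples), and PCA batch scoring are all computed on the raw pooled
matrix. This ordering matters: quantile normalization removes exactly the
additive per-array/per-dataset biases these diagnostics are designed to
find, so QC after normalization would be vacuous. A dataset is discarded
when the median of its arrays' |RLE medians| exceeds 0.15 log2 (a
conventional scale for "visible global bias"; configurable). The pipeline
never discards every dataset of a tissue class — losing a class entirely
would silently change the meaning of every downstream contrast — and
instead keeps one dataset and logs a warning.

**Batch detection.** Gene-centered SVD gives per-PC sample scores; each
of the first two PCs (configurable) is decomposed into between-group
variance fractions (R²) for the dataset grouping and for the tissue-class
grouping. Because datasets are nested inside classes, the raw
between-dataset R² is mathematically ≥ the class R², so the batch flag
uses the *within-class* batch R² (dataset R² of class-residualized
scores): it is raised when that exceeds 0.5 on some PC and the raw
dataset R² also exceeds that PC's biology R². The flag is diagnostic
only; it does not alter the data. It is deliberately sensitive — a
coherent shift of even ~0.05 log2 across thousands of genes is easily
visible in within-class residuals — so a raised flag on otherwise
passing data signals residual batch structure to inspect, not a failed
run.

## Differential expression

Each contrast (disease vs. reference class, oriented disease-minus-
reference) fits per-gene group means and the pooled residual variance
s²_g on d_g = n₁ + n₂ − 2 df. The hierarchical model places a scaled
inverse-chi-square prior on gene variances — equivalently s²_g follows a
scaled F distribution around s₀² — and the prior parameters are
estimated by moment matching on

    e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2),

whose model mean is ln s₀² − ψ(d₀/2) + ln(d₀/2) and whose excess
variance over sampling noise is ψ′(d₀/2). d₀ comes from the trigamma
inverse (Newton iteration, tolerance 1e−8, ≤ 50 steps; series fallbacks
for extreme arguments), with d₀ = ∞ when the observed spread of log
variances is fully explained by sampling (then s₀² = exp(mean e) and the
posterior variance is s₀² for every gene, p-values from the normal).
Zero-variance genes are floored at 1e−8 before logs — far below any
simulated variance, so the floor only prevents −∞. The implementation is
cross-checked in the test suite against the Bioconductor limma `eBayes`
fit (prior parameters, t, and p agree to ≤ 1e−4 relative).

BH adjustment is transcriptome-wide within each contrast (the tested
family is every gene in the contrast, not a candidate subset). DEG calls
use adjusted p < 0.05 and linear fold change > 2, two-sided p with
direction taken from the fold-change sign, since the screen wants
up-regulated genes from a two-class comparison.

## Candidate rules

"Low expression in a confounder tissue" is operationalized as a gene's
mean log2 expression lying below the 25th percentile of all genes' means
within that class (configurable; 100 disables the filter). The two rules
are pure set logic over the per-contrast up-DEG sets, filtered and then
ranked by the rule's fold change with lexicographic gene-ID tie-breaks,
truncated to top_k (default 8 per rule per compartment, mirroring the
scale of a 16-candidate screen; fully configurable). The Venn
decomposition of the up-DEG sets is computed by exact per-element
membership arithmetic and reported alongside.

## Clinical statistics

Relative expression is 2^−ΔCt with ΔCt = target Ct − arithmetic mean of
the housekeeping Cts (the geometric-mean reference on the linear scale).
Group contrasts use fold changes of medians (rounded half-up to 1
decimal, the printed-table convention), tie-corrected Kruskal–Wallis, and
pairwise two-sided rank-sum tests (normal approximation with tie and
continuity correction) with BH across the tested pair family. Fully tied
inputs return H = 0, p = 1 instead of raising, so constant fixtures pass
through. Spearman correlation uses the t-approximation p-value.

ROC analysis evaluates every observed threshold; the trapezoid AUC
equals the rank statistic U/(n₁n₀) with ties counted ½ (verified
exhaustively in tests), the AUC p-value uses the tie-corrected rank-sum
normal approximation, and the optimal cutoff maximizes Youden's
sensitivity + specificity with ties resolved toward higher sensitivity,
then the lower cutoff. AUC bands: > 0.9 excellent, 0.8–0.9 good, 0.7–0.8
moderate, 0.6–0.7 poor, ≤ 0.6 below-poor.

Replicate CVs are σ/μ in percent, rounded half-up to 2 decimals, with the
n-denominator (population) SD by default: that convention reproduces six
of the eight bundled printed dilution-series cells exactly; the two
500 ng cells are reproducible under neither SD convention from their
printed replicates (one matches the n−1 form, one neither), which the
package surfaces rather than hides — `sd_mode="sample"` is provided, and
the per-gene average CV is defined as the mean of the (rounded)
per-dilution CVs because that is how the printed per-gene averages arise
from the printed cells.

## Synthetic data: what it emulates and what it does not

The compendium generator draws each matrix entry as baseline + signature
baseline offset + signature effect (in target classes) + dataset batch
shift + N(0, σ²_g), with σ²_g ~ s₀²·d₀/χ²(d₀) drawn once per gene. The
variance prior is deliberately the same family the moderated t assumes,
so prior-parameter recovery is a meaningful end-to-end check of the
estimator, not a tautology (the estimator never sees the true values).
Platform feature subsets are random but always carry the planted
signatures: candidates can only come from the shared feature space, so
planting a signature off-platform would make recovery undefined.
Signatures get disjoint gene blocks from one seeded permutation. A single
master seed expands into independent substreams (assignment, variances,
batch, noise, platforms), making any component reproducible in isolation.

Default study design: class sizes mirror a pooled compendium with
7/40/23/19/5 arrays for disease glomeruli / normal glomeruli / bladder /
bladder cancer / UTI leukocytes, realized as 2×4, 4×10, 2×12, 2×10 and
1×5 dataset×sample blocks; two platforms sharing 80% of 2000 features;
baseline 8 log2 units; prior d₀ = 4, s₀² = 0.05 (typical array-scale
shrinkage regime); residual batch SD 0.05 log2. The batch scale is
chosen *below* the RLE discard threshold on purpose: the fixture
represents a compendium whose grossly biased datasets have already been
discarded, and a fixture that the pipeline's own QC would shred tests
nothing. Gross-bias detection is exercised separately with planted 1–3
log2 shifts.

Kidney-disease-specific genes are planted with a −1.5 log2 baseline
offset (constitutively low outside the kidney — the defining property of
a urinary kidney-specific marker) plus a +2 log2 disease effect;
confounder sets are +2 log2 in bladder or leukocytes with no offset.

Cohort tables draw the marker log-normally per group (medians and
log-scale σ for the default stage-1/stage-2 templates are derived from
published-style group medians and interquartile ranges via
σ = ln(q75/q25)/1.349) and couple covariates to the marker with a
Gaussian copula: target Spearman ρ maps to copula correlation
r = 2·sin(πρ/6), realized by a single-factor construction (covariate
latent = r·marker latent + √(1−r²)·noise) that is positive semi-definite
for any valid targets and exactly comonotone at ρ = 1. Ct columns are
derived from the marker so ΔCt quantification round-trips exactly.
Dilution series follow Ct = intercept − slope·log10(amount) + noise,
slope 3.32 Ct/log10 ng (100% amplification efficiency).

What the generators do *not* emulate — and therefore what passing tests
do not show about real data: probe-level effects (multiple probes per
gene, positional bias, background), non-additive or gene-specific batch
distortions, platform-specific intensity response curves, heavy-tailed
or outlier-contaminated arrays, within-subject repeat measurements, and
covariate correlation structure beyond the single-factor copula (pooled
across groups, observed correlations exceed the within-group targets
whenever group medians of marker and covariate are aligned — visible in
the stage-1/2 templates and intentional, as real cohorts behave the same
way).

## Problem sizes and numerical choices

The bundled benchmarks run at 2000–5000 genes, ~100 arrays, and cohorts
of 80–82 subjects — the scale of the emulated study — so the full suite
and the acceptance script each complete in seconds. Quantile
normalization and BH use stable mergesort ordering; candidate tables
break fold-change ties lexicographically; repeated runs with one
configuration are byte-identical. The trigamma inverse switches to its
asymptotic series outside [1e−6, 1e7]. Degenerate inputs (constant
genes, all-tied groups, single-dataset batch R², empty candidate sets)
return defined values rather than raising, and every configuration error
names the offending field.

## Known limitations

* The pipeline consumes expression matrices, not raw probe-level files;
  array-level QC is proxied at matrix level (trimmed-mean scale factors,
  fraction detected) rather than recomputed from probe intensities.
* eGFR is consumed as a covariate, never computed from serum creatinine.
* The pairwise post-hoc procedure after Kruskal–Wallis is rank-sum + BH;
  other conventions (Dunn's test, Bonferroni) are not implemented.
* The PCA batch flag is a diagnostic, not a correction; no batch
  adjustment (e.g. empirical-Bayes location/scale correction) is applied.
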