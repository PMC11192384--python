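# Methods

This note records the statistical models `chondroseq` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Differential expression

Each gene's counts are modelled as negative binomial,
`Var(Y) = μ + α μ²`, with a log link. For a two-group contrast the model
is saturated in the group means, so the fit decouples: for each group
the log-mean solves the one-dimensional NB score equation
`Σ_j (y_j − μ_j) / (1 + α μ_j) = 0` with `μ_j = s_j e^η` (size factors
`s_j` enter as fixed offsets), by vectorised Newton iteration (step
clipped to ±5, convergence at 1e-10, at most 50 iterations). The log2
fold-change is the difference of the two fitted log-means divided by
ln 2; its standard error comes from the summed Fisher informations,
`SE² = 1/I_num + 1/I_den` with `I = Σ μ_j/(1 + α μ_j)`. When known
covariate factors are requested the contrast no longer decouples and the
engine falls back to a per-gene NB GLM (statsmodels) with the same
offsets and dispersion.

**Size factors** are median-of-ratios: per sample, the median over
reference genes of the count divided by that gene's geometric mean
across samples, using genes positive in every sample (falling back to
genes positive in ≥ 90% of samples, then erroring). Factors are rescaled
to geometric mean exactly 1, which fixes the otherwise arbitrary scale.

**Dispersion** is per-gene pooled method-of-moments on normalised
counts: within each group, the sample variance in excess of the Poisson
term `m · mean(1/s_j)` estimates `α m²`; group estimates are pooled with
`n_g − 1` weights, the denominator uses the moment-corrected `m² − v/n_g`
(since `E[m̂²] = μ² + Var(m̂)`, the naive denominator biases α low), and
the result is floored at 1e-8. This is deliberately simpler than the
empirical-Bayes trend shrinkage of dedicated DE packages: gene-level
results are comparable in structure, not in value, and the Wald test
ignores dispersion-estimation uncertainty. The consequence is mild
anticonservatism at small replicate numbers — under the generator's null
with 5 vs 5 replicates the fraction of raw p < 0.05 averages about
0.076, which is the documented tolerance band [0.03, 0.08] for this
approximation.

**Filtering** keeps genes whose median count over all samples is at
least 10 (a gene exactly at the threshold survives). **FDR** is
Benjamini–Hochberg step-up (the conventional default where only an "FDR
threshold" is named), computed per contrast over genes with defined
p-values; genes with all-zero counts in both groups get missing p and
padj and do not enter the BH denominator. A gene that is all-zero in
only one group keeps a numeric result via the floored group mean
(1e-8), which yields an extreme fold-change with a large standard
error — such genes are effectively dropped from discovery rather than
declared infinitely significant. No LFC shrinkage, no independent
filtering beyond the median rule, and no outlier replacement are
performed. Surrogate-variable estimation is out of scope; unknown
structure can only be absorbed through explicitly supplied covariates.

## Competitive gene-set test

The statistic is the rank-sum `W = Σ_{g∈S} rank(p_g)` of the matched set
genes' raw DE p-values among all n expressed genes, with midranks under
ties. W and the Mann–Whitney U differ by the constant `m(m+1)/2`, so the
choice is inert for permutation inference. The null draws N size-m
groups uniformly without replacement from the full expressed universe —
including the set's own genes, which is what makes the test competitive
— with midranks computed once and reused. The set size used for the
null is the *matched* size (members actually expressed), not the list's
nominal size.

The empirical p-value uses the plus-one correction
`(1 + #extreme)/(N + 1)`, so it is never exactly zero and its floor at
the default N = 10,000 is 1/10,001. Two-sided extremity (the default) is
the absolute deviation from the exchangeable-null mean `m(n+1)/2`;
one-sided alternatives ("less" = enriched for small p) are available.
An exhaustive enumerator computes the exact subset distribution whenever
`C(n, m) ≤ 200,000` and serves as the oracle for the Monte-Carlo path in
the tests.

The |LFC| density-shift summary compares absolute log2 fold-changes of
set genes against the background with stratum means and the two-sample
Kolmogorov–Smirnov distance.

## Concordance analytics

Two DE tables are paired by inner join on gene id. Conditional p-value
histograms take one contrast's raw p-values, stratify genes by
significance (padj < α) in the other contrast, and normalise each
stratum's histogram to unit area on 20 uniform [0, 1] bins so strata of
different sizes are comparable; a flat pair indicates independent
programs, a near-zero spike in the significant stratum a shared one.
Sign concordance restricts to genes significant in both contrasts and
classifies them by fold-change sign pair; the concordant percentage is
rounded half-up to one decimal. A fold-change of exactly zero in a
both-significant row (possible only in synthetic data) counts as
discordant, with a warning. Raw (unshrunken) fold-changes are used
throughout, including the FC–FC scatter tables.

The contrast battery never pools wild-types across arms: each knockout
is compared only against its own arm's matched wild-type clones, and the
differentiation trajectory (Day 14 vs Day 7) is contrasted within each
arm's knockouts.

The PCA overview operates on `log2(normalised count + 1)` for the 500
most variable genes (configurable; clamped with a warning when fewer
exist), gene-centered, via SVD; variance fractions are squared singular
values over their total. The transform is a package choice — a
variance-stabilising transform would serve equally — and is documented
here because the inputs to PCA materially shape the picture.

## Synthetic generator

The generator emulates a two-arm knockout experiment in a chondrogenic
cell line: per arm, clonal knockout replicates and matched wild-type
clones (default 5 each, the realistic scale for CRISPR-derived clonal
lines), at Day 7 and Day 14 of differentiation. Per-gene baseline means
and NB dispersions are log-normal (defaults: natural-log mean 3.0/sd 1.5
for means — median ≈ 20 counts, so roughly two-thirds of genes pass the
median-10 filter; log mean −3.0/sd 0.5 for dispersions, i.e. α ≈ 0.05,
typical for clonal cell-line replicates). Each arm's DE program flags a
fraction of genes (default 0.2); a gene DE in one arm is DE in the other
with the overlap probability (default 0.8), and jointly DE genes draw
their fold-change pair from a correlated bivariate normal (default
sd 1.0, correlation 0.9), which is the simplest model producing high
cross-arm sign concordance. The designated gene set (default size 164)
can have both its DE probability and |LFC| scaled by an enrichment
multiplier. The knockout effect of an arm is identical at both days; the
differentiation trajectory is a separate additive per-gene LFC applied
to every Day-14 sample (default sd 0.5), making the Day14-vs-Day7
trajectory shared across arms. Library sizes are uniform multipliers on
[0.7, 1.4]. All draws derive from a single seed through independent
named streams, so outputs are bit-identical given a config.

What the generator does **not** emulate: batch or surrogate-variable
structure, clone-to-clone variance components beyond NB noise (clones
are exchangeable replicates), gene–gene correlation, length/GC biases,
or annotation structure (gene ids are synthetic symbols). Passing
recovery and calibration tests on this generator therefore demonstrates
correctness of the inference machinery under its assumed model, not
robustness to the full messiness of real RNA-seq.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 2,000 genes
for recovery, calibration and the enriched permutation bound; 500 genes
× 500 datasets (permutation iterations 500) for permutation type-I
error; exhaustive-oracle fixtures with `C(n, m) ≤ 200,000`. These sizes
give Monte-Carlo error comfortably inside each documented tolerance
while keeping the whole suite fast. Ties in ranks are handled by
midranks everywhere; empirical p-values are plus-one corrected; BH is
order-invariant and NaN-aware; degenerate inputs (all-identical samples
in PCA, empty strata, zero-matched sets, sub-replicated contrast levels)
raise or flag rather than silently returning numbers.

## Known limitations

- The Wald test with moment dispersions is slightly anticonservative at
  n = 5 per group (see above); it is not a drop-in replacement for
  shrinkage-based DE engines at the individual-gene level.
- The permutation test inherits whatever miscalibration the per-gene
  p-values carry; its type-I error is nevertheless close to nominal
  because the competitive null permutes gene labels, not samples.
- Cross-dataset validation assumes shared gene identifiers; no identifier
  mapping is performed.
- One-sided set tests assume the direction of interest is enrichment for
  small p; depletion is available but untested against real use.
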