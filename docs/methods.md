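# Methods

This note documents the statistical models implemented in
`toxpotency`, the choices made where the methodology was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Differential expression

Expression is analysed on the log2 scale. Two-channel intensities, when
present, are normalized per array by subtracting a LOWESS fit of
M = log2(R/G) on A = (log2 R + log2 G)/2 (default span 0.4); a
common-reference design cancels the reference channel in group
contrasts, so no dye-effect term is modelled and downstream analysis
works on per-sample log-ratio columns. No blocking term is fitted by
default (the generator can plant a per-exposure batch shift to study
its effect).

The treatment-effect test per gene is a one-way F statistic or its
variance-shrunken variant Fs, in which the per-gene mean squared error
is replaced by a James–Stein-shrunken value: log variances are shrunk
toward their across-gene mean with a method-of-moments weight
(sampling variance of log s² is trigamma(df/2); the excess spread
estimates the true between-gene variance). p-values come from residual
shuffling: residuals from the full (group-means) model are permuted
across samples — the same permutation for all genes, preserving
cross-gene correlation — and added back to the grand mean;
p = (1 + #{null ≥ observed}) / (1 + nperm). The production default is
nperm = 30,000; tests and examples use 200–4,000 (problem sizes are
listed at the end). FDR control is Benjamini–Hochberg. Fold changes
use least-square means (cell means in the one-way layout) with the
symmetric signed convention (a halving is −2.0), and a DEG requires
q ≤ 0.05 **and** |FC| ≥ 1.5, both inclusive. The q-value is the
omnibus dose-effect q combined with the per-dose fold change; a
per-contrast test would be a reasonable alternative but the omnibus
form matches the analysis this pipeline reproduces.

## Williams-trend prefilter

The trend statistic is
t = (µ̂_k − ȳ₀) / √(s²(1/n_k + 1/n₀)), where µ̂_k is the isotonic
(pooled-adjacent-violators) estimate of the highest-dose mean over all
dose groups, ȳ₀ the raw control mean, and s² the pooled within-group
variance. `direction="auto"` evaluates both orientations and keeps the
larger statistic; the permutation null (sample-to-dose label shuffling)
applies the same rule, so the auto mode is correctly calibrated.
Tabulated Williams critical values are replaced by these permutation
p-values throughout. The vectorized scan computes the isotonic value
at the last position for all genes at once by enumerating the 2^(k−1)
contiguous partitions of the k dose groups — exact, and fast for the
k ≤ 10 of any realistic design.

The prefilter passes genes with p ≤ 0.05 and max |FC| across doses
≥ 1.5 by default. A far more permissive p ≤ 0.5 setting is in
circulation for this prefilter; it is available as `paper_mode` /
`trend_p_cutoff=0.5` rather than being the default, since 0.05 is the
conventional choice and the permissive value is likely a transcription
artifact. The fold-change screen uses the largest group-mean departure
from control at **any** dose (configurable), since restricting it to
the top dose would miss saturating responders.

## Benchmark-dose engine

Per gene, seven mean models are fitted by maximum likelihood under
Normal errors with constant variance (so mean fitting is least
squares): Linear a+bd; Poly2 a+bd+cd²; Power a+bd^g (g ∈ [1, 18]);
Exp2 a·e^{bd}; Exp3 a·e^{s(bd)^g}; Exp4 a(c−(c−1)e^{−bd});
Exp5 a(c−(c−1)e^{−(bd)^g}). The shape cap g ≤ 18 prevents degenerate
step-function fits. Constant variance on the log scale is the standard
assumption for log-expression benchmark-dose work and matches the
generator's noise model.

Fitting exploits two exact reductions: (i) the total RSS decomposes
into the count-weighted RSS on dose-group means plus the within-group
SS, so optimization works on ≤ #doses points; (ii) every nonlinear
family is linear in its scale parameters given the shape/rate, which
are profiled out in closed form, leaving a 1–2 dimensional problem
solved over a deterministic coarse grid with Nelder–Mead refinement of
the best grid points. This is deterministic, start-independent, and
verified against dense grid searches of the likelihood.

Goodness of fit is the exact lack-of-fit F test against the saturated
(per-dose-group means) model: F = ((RSS − RSS_sat)/df) /
(RSS_sat/(n − k)) with df = #doses − #mean-parameters and n − k
pure-error degrees of freedom. The F form is used rather than the χ²
likelihood-ratio approximation because at the n = 20–23 of a typical
dose design the χ² version over-rejects (measured ~20% below p = 0.1
under a true model instead of the nominal 10%; the F test is exactly
uniform, verified by simulation). With four dose groups the
four-parameter Exp5 has df = 0; the test is then vacuous and p is
reported as 1, leaving AIC (2k − 2·loglik with k counting mean
parameters plus σ) to arbitrate. Model selection takes
the lowest AIC among converged fits with fit p ≥ 0.1; ties break by
fewer parameters, then a fixed model order.

The BMD solves |µ(d) − µ(0)| = f·σ̂ with f = 1.349 (the 10%
tail-probability convention), by closed form for Linear, Power and
Exp2 and by a scanned bracket plus Brent root otherwise; a response
plateau below the benchmark response, or a near-zero slope, yields an
absent BMD with a reason code rather than an exception.

BMDL/BMDU are profile-likelihood bounds. The benchmark-response
constraint ties σ to the mean parameters — σ(θ) = |µ_θ(δ) − µ_θ(0)|/f
— so maximizing the likelihood over θ with that substitution profiles
out every nuisance parameter including σ, and equals the unconstrained
maximum exactly at δ = BMD̂. The bound is where the profile drops by
½·χ²₁(0.90) (two-sided 90%, hence one-sided 95% per bound, the usual
benchmark-dose convention; configurable). The search warm-starts each
candidate δ from the previous optimum. Sides where the profile never
reaches the threshold report 0 or ∞ with a reason code. Coverage of
the lower bound is verified by simulation (≈ 95% on linear truth).

Post-filters, all inclusive: BMD ≤ highest dose; fit p ≥ 0.1;
BMDU/BMDL ≤ 40; BMDU/BMD ≤ 20; BMD/BMDL ≤ 20. Every violated rule is
listed, not just the first.

## Potency estimators

All three operate on the gene → BMD map of post-filter-passing genes;
lower values mean a more potent exposure, and all three are monotone
under rescaling of the BMDs.

* **NTP pathway approach**: a gene set qualifies with ≥ 3 BMD genes
  covering ≥ 5% of the set (set size as listed in the GMT — whether
  the 5% should instead count against a platform universe is not
  determinable, so the listed size is used); the potency is the lowest
  qualifying median.
* **25th ranked gene**: the 25th-smallest BMD, ties broken by gene ID;
  undefined below 25 genes.
* **LCRD**: the published wording supports two readings, and both are
  computed: (A) the smallest BMD after which every consecutive ratio
  BMD₍ₙ₊₁₎/BMD₍ₙ₎ stays below 1.66, and (B) the smallest BMD of the
  earliest run of ≥ 2 consecutive BMDs each within a quarter-log
  (10^0.25 ≈ 1.78×, base configurable) of a neighbour. The estimate is
  the minimum of the defined candidates and both appear in the
  evidence, so disagreement between readings is visible.

## Gene-set analysis

GSEA uses the weighted Kolmogorov–Smirnov running sum (hit increments
∝ |score|, weight 1; miss decrement 1/(N−N_h)); the ES is the signed
extremum. The default ranking metric is direction × |statistic|
(signed −log₁₀p and log2 FC are available). The null permutes gene
labels — with five animals per dose group a phenotype-permutation null
is underpowered — drawing random same-size sets; NES divides the ES by
the mean |null ES| of matching sign, p is the matching-sign tail with
+1 smoothing, and BH adjustment runs across sets. Over-representation
is the one-sided hypergeometric tail; "perturbed" requires
−log₁₀p ≥ 1.3 (inclusive) with overlap strictly greater than 5 DEGs.
The activation z-score over a set with expected per-gene directions is
(concordant − discordant)/√overlap (activated > 2, inhibited < −2,
no overlap → no activity pattern); expected directions travel in the
GMT-extension format `gene:+1` / `gene:-1` since no public knowledge
base is bundled. The deposited-surface-area correlation is Spearman's
rho of a per-(exposure, dose) quantity against BET × dose, pooled
across exposures and doses by default.

## Signature classifier

Query conditions are described by the log2 fold changes of a fixed
signature panel (17 genes by default; the panel is an input, not
bundled). The panel matrix of a labelled reference compendium and the
queries are projected jointly by centered, unscaled PCA (component
signs fixed by the first panel gene's loading); a Gaussian linear
discriminant with pooled covariance and empirical class priors
(uniform available) on the first two PCs yields the pro-fibrotic
posterior. Calls use strict thresholds: > 0.8 pro-fibrotic, < 0.2
non-fibrotic, boundary values unknown. A singular pooled covariance is
ridge-regularized with a recorded ε.

## Synthetic-data generator

The generator emulates an in vivo transcriptomic dose-response design:
doses {0, 6, 18, 54} µg/mouse, 8 vehicle controls and 5 treated
replicates per dose per exposure, additive Normal(0, 0.2) log2 noise
(constant variance, deliberately matching the BMD likelihood so
planted truth and estimator share one definition). Responsive genes
draw a model family, a direction, a baseline in [6, 12] log2 units and
a log-uniform true BMD, and are anchored so the mean curve departs
from background by exactly 1.349·σ at the true BMD. Shape parameters
of unbounded-growth families (Power, Exp2/3, and the quadratic share
of Poly2) are capped so top-dose effects stay within ~30× the
benchmark response — unboundedly exploding curves are neither
realistic nor informative. Per-exposure potency differences are
planted as multiplicative scales on the true BMDs. Bioassay tables
draw overdispersed negative-binomial neutrophil counts and
gamma-distributed % tail DNA with geometric dose-effect interpolation
up to a top-dose multiplier (default 10, reflecting the strong
inflammation such exposures produce; 1.5 for the milder genotoxicity
endpoint).

The reference compendium follows a severity-factor model: each
condition's fold-change vector is a scalar severity score times the
unit signature direction plus a small isotropic residual (30% of the
severity SD). This mirrors how real fold-change compendia vary chiefly
along a response-severity gradient and is what makes the first two
PCs retain the class axis; with isotropic 17-dimensional noise the
leading PCs of a ~100-row compendium would be noise directions
(Marchenko–Pastur), which no real signature compendium resembles.
"Separation" counts within-class SDs from each class centroid to the
class midpoint, so the default 2 puts the centroids 4 SDs apart; the
planted pro-fibrotic exposure-dose condition (one per experiment, by
default the first exposure at the top dose) sits at the pro-fibrotic
centroid. Query fold changes inherit group-mean estimation noise,
σ·√(1/5 + 1/8) ≈ 0.11 — small against the between-study scatter of
the compendium, as for a real replicated condition.

What the generator does **not** emulate: array-probe chemistry,
spatial artifacts, probe-to-gene collapsing, heavy-tailed or
variance–mean-dependent noise, correlated co-expression beyond the
planted modules, and real pathway topology. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every feature of real microarray data.

## Numerical choices and degenerate inputs

Optimizer grids and tolerances: Nelder–Mead xatol 1e-8 (fit) / 1e-7
(profile), Brent xtol 1e-12 for BMD roots; permutation p-values use
+1 smoothing everywhere; zero within-group variance yields a
degenerate flag with p = 1 (F test) or falls back to the shrunken
denominator (Fs); all-identical data gives H = 0, p = 1 in
Kruskal–Wallis; Dunn uses Bonferroni over the many-to-one family;
Dunnett family-wise p comes from the multivariate-t distribution
(Monte-Carlo, seeded). Ties break by gene ID wherever an ordering
feeds a downstream decision.

## Problem sizes

Simulation-based checks run at sizes chosen to give stable Monte-Carlo
estimates on one CPU: 1,000 genes / 200 sets at nperm = 1,000 for the
null-calibration checks, 500 planted genes for BMD recovery, 500
linear replicates for BMDL coverage, 100 seeds for the tenfold
potency-rank recovery, and 200 seeds for classifier calibration. The
acceptance script reports the same quantities at reduced sizes
(150 genes, 20 and 100 seeds) with its seed taken from the command
line.

## Known limitations

* The goodness-of-fit gate is vacuous for Exp5 with four dose groups
  (df = 0); adding dose levels restores it.
* Profile bounds assume a unimodal profile; multi-modal likelihoods
  (possible for Exp5 at low signal) may yield conservative bounds.
* The Fs shrinkage recipe is one reasonable choice among several; the
  recipe is recorded in output metadata.
* The activation z-score implements only the direction-concordance
  core of commercial causal-network scores.
* No probe-level preprocessing: inputs are assumed collapsed to genes.
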