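# Methods

This note documents the models and procedures the package implements, the
defaults it ships, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. Everything quantitative stated here is computed by the test suite or
`scripts/acceptance.py`; nothing is quoted from external runs.

## Study design being modeled

The analyses target a two-group (CIE vapor vs Air), two-sex mouse design
in which the same subjects are profiled by 3'-tag RNA-seq in whole blood
and up to three brain regions (PFC, AMY, HYP), with voluntary drinking
traits (ethanol consumption in g/kg, preference as a fraction) measured
per subject. All stages run separately per sex; subjects are matched
across tissues by subject id, which is what makes within-subject
blood-brain correlation and cross-tissue module comparison possible.

## Normalization

Counts are converted to log2 counts-per-million with a prior count:

    value(g, s) = log2((count + 0.5) / (library + 1) * 1e6)

The prior of 0.5 (and its doubled value in the denominator) keeps the
transform defined at zero counts and makes the values exact log
proportions; the tests pin the formula with hand-evaluated fixtures.
Library size is the column sum of the count matrix — no TMM or
median-ratio scaling is applied (a hook exists in the pipeline config if a
user wants to add factors externally).

For differential expression the log-CPM values carry per-observation
precision weights: each gene is fitted to the design by least squares, the
square root of the residual standard deviation is smoothed against average
log2 count with lowess (span 0.5, configurable), and each observation's
weight is the inverse fourth power of the trend evaluated at its fitted
log-count. On data that is homoscedastic on the log scale the weights are
flat (test: max deviation < 20% around the median); on gamma-Poisson
counts they increase with expression, as the mean-variance relationship
implies. Network construction uses unweighted log-CPM: the coexpression
similarity is defined on plain Pearson correlation of expression, and
weights are a DE-stage device.

## Moderated t-statistics

Per gene, (optionally weighted) least squares gives the effect
c'β̂, its unscaled variance c'(X'WX)⁻¹c, the residual variance s²_g and
residual degrees of freedom d_g. The empirical-Bayes prior (d₀, s₀²) is
estimated by moment matching on z_g = log s²_g: under the scaled-χ² model
E[z] and Var[z] involve digamma/trigamma terms, so the excess of the
empirical variance of z over trigamma(d_g/2) determines d₀ through a
Newton inversion of the trigamma function, and the mean determines s₀².
If the observed spread does not exceed the sampling spread, d₀ = ∞ and all
posterior variances equal s₀². The moderated t uses

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

in the standard error, with d₀ + d_g degrees of freedom. Limiting cases
are pinned by tests: d₀ = 0 reproduces the ordinary t exactly (1e-10), and
d₀ → ∞ pins every posterior variance at s₀². Under a global null
simulation the fraction of p < 0.05 falls in the 99% binomial band around
5%. DEGs are called at nominal p < 0.05 (a Benjamini-Hochberg column is
emitted but unused by default), and sexes are always fitted separately
with a group-only design.

## Signed networks and module detection

Similarity S_ij = (1 + cor(x_i, x_j))/2 maps anti-correlated genes to 0
and co-regulated genes to 1; zero-variance genes get the uninformative
value 0.5, are flagged, and are excluded from module seeding. The
soft-threshold power β is either supplied per tissue (the defaults
shipped in the pipeline config are, per sex, M: PFC 6, AMY 8, HYP 7,
BLD 10; F: PFC 5, AMY 9, HYP 11, BLD 6) or chosen as the smallest
candidate whose network reaches a signed scale-free fit index of 0.8,
computed from 10 logarithmic connectivity bins (empty bins dropped, index
negated when the log-log slope is positive).

The topological overlap measure is computed exactly as

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with l_ij the shared-neighbour sum and k the connectivity; a triple-loop
oracle pins the vectorized implementation entrywise at 1e-12 for matrices
up to 30 genes.

Module detection clusters 1 − TOM by average linkage and applies a
dynamic tree cut of the "tree" flavour. The implementation identifies
*distinct branches*: a branch qualifies as a module candidate when it
joins its nearest substantial sibling (≥ min module size) at least
`branch_gap` = 0.05 above its own internal completion height. With deep
split enabled (the default) the finest nested distinct branches win; the
resulting cores are then expanded upward through their "straggler
ladders", absorbing sibling branches too small to stand alone that attach
closer to the core than to its join point. The gap criterion is what
distinguishes a genuine branch from the diffuse background: uncorrelated
genes merge at dissimilarities within a few hundredths of the height at
which they join everything else, so a plain static cut at 0.99 would
sweep the entire background into one giant cluster, while the gap rule
leaves it unassigned (the null-mode test requires ≥ 95% of genes
unassigned when nothing is planted). Defaults follow the study
parameters: minimum module size 100, cut height 0.99, deep split on,
merge cut height 0.25.

Eigengenes are the first right singular vector of the per-gene
standardized module submatrix, unit norm, sign-aligned to correlate
non-negatively with the module's mean standardized profile. Modules whose
eigengenes cluster below dissimilarity 1 − cor = 0.25 are merged
iteratively until stable, and labels are reassigned 1..K by decreasing
size with 0 reserved for unassigned genes.

## Linking modules to dependence and across tissues

A module is CIE-related if (1) it contains more DEGs than expected by
chance (one-sided hypergeometric test against the expressed-gene
universe, p < 0.05, computed separately for up- and down-regulated DEGs
to give the module a regulation direction and an intensity tier at
p < 1e-5 / p < 0.05), or (2) its eigengene correlates with group,
consumption or preference (Pearson, t-distribution p on n − 2 df). The
union rule and both branches are tested.

Cross-tissue module overlap uses the intersection of genes measured in
both tissues as the universe — the only set on which joint membership is
defined. In the meta-network, CIE modules are nodes, overlaps with
p < 0.05 between different tissues are edges weighted by −log10 p, and a
blood module whose significant overlaps reach modules from at least two
*distinct* brain regions (region identity, not module count) defines a
blood-brain cluster consisting of that blood node and its brain
neighbours. Restricting the flag to the blood node and its partners —
rather than its whole connected component — prevents unrelated modules
that merely share a component from inheriting the label; the recovery
test plants one three-tissue conserved module and one blood-only module
and requires the former flagged in ≥ 95% of 20 seeds and the latter never.

Generic gene-set over-representation (cell-type markers, alcohol-related
sets, GMT format) uses the same hypergeometric tail restricted to the
expressed universe with Bonferroni correction over all tested
(query, set) pairs.

## Blood-brain correlation analyses

Between-subject mode averages each gene over all samples of a tissue
(irrespective of treatment) and reports one Spearman ρ per tissue pair
over shared genes. Within-subject mode matches samples by subject id and
computes a per-gene Spearman ρ across animals, with average ranks for
ties and the t-approximation for p; Holm-Bonferroni runs over exactly the
genes tested (detected in both tissues). The step-down Holm rule is
implemented directly and cross-checked against statsmodels on random
inputs; NaN p-values propagate and do not count toward m. Sex comparisons
of a correlation use the Fisher z test for independent samples,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); the plain Fisher test
is the only comparison variant implemented (confidence-interval-based
alternatives exist but are out of scope).

## Classification

Three families, chosen for interpretability on small samples: elastic-net
logistic regression (penalty λ[α‖β‖₁ + (1−α)/2‖β‖₂²] in the per-sample
average-loss parameterization; non-convergence at tol 1e-7 within 1e4
iterations is an error, and a non-converging grid point is skipped during
selection), random forest (Gini splits, mtry features per split, score =
fraction of trees voting positive), and PLSDA (PLS regression against the
0/1 label; score = linear predictor; threshold = midpoint of the class
score means). Importances: |coefficient| for the elastic net (with the
zero-coefficient count reported, since the L1 part performs embedded
feature selection), mean decrease in Gini for the forest, and for PLSDA
the weighted sum of absolute per-component regression coefficients with
weights proportional to each component's reduction in response sum of
squares.

Evaluation is outer stratified 5-fold CV repeated 10 times (defaults),
with hyperparameters chosen by an inner CV on each training fold
(selection metric: accuracy; ties break toward smaller penalty /
components / mtry). Normalization is leakage-safe by construction:
log-CPM is strictly per-sample, and gene centering/scaling coefficients
come from the training folds only — a canary test injects an extreme
outlier into the test fold and asserts the training statistics are
byte-identical. Metrics are averaged across the repeated folds
(fold-averaged AUROC; pooled ROC points are exported for plotting), and
importances come from a final all-data fit with hyperparameters selected
by inner CV on the full data. Default grids: α ∈ {0, 0.1, …, 1} × 50
log-spaced λ ∈ [1e-3, 10]; mtry ∈ {√p, p/10, p/4} with 500 trees;
ncomp ∈ {1..5}.

## The synthetic study generator

`synthio` emulates the study at the data level: balanced CIE/Air groups,
configurable sexes, the same subjects across tissues, negative-binomial
counts via a gamma-Poisson mixture (default dispersion 0.1), library
sizes log-uniform in a configurable range (default 0.5-2 million,
exercising CPM), and per-gene baselines drawn once per study (log2-uniform
in [3, 9]) and shared across tissues up to a per-tissue N(0, 1 log2)
deviation — the sharing is what makes between-subject blood-brain mean
expression rank-correlate, as in real tissues.

A planted module ties its genes to a per-subject latent factor (the
future eigengene), reused across all configured tissues (optionally
sign-flipped per tissue to emulate conserved modules with opposite
regulation directions). The factor loading is calibrated so the average
pairwise within-module correlation matches the requested strength s:
with per-gene Gaussian noise τ = 0.35 (log2) and the gamma-Poisson
log-scale variance ≈ dispersion/ln²2, the loading is
a = √(s/(1−s) · (τ² + dispersion/ln²2)). Group effects shift the factor
mean; consumption is rebuilt as a calibrated mixture of the trait-linked
factor and residual noise so the eigengene-trait correlation is
recoverable at the configured value (tests require the mean estimate
within ±0.15 of a planted 0.7). Planted DEGs shift the group mean of
dedicated background genes by the configured log2 fold-change.

One deliberate choice: genes carrying planted signal (module members and
DEGs) are drawn from the lower third of the baseline-abundance range. At
desk scale the planted genes are a large fraction of the transcriptome,
and if they were abundant, their shared shifts would couple every other
gene through the CPM denominator, creating a transcriptome-wide
pseudo-module that no analysis could (or should) undo. Keeping planted
genes at low abundance makes their contribution to per-sample totals
negligible, which reproduces the regime of a real ~12k-gene transcriptome
where any one module is a small fraction of the reads. What the generator
does not emulate: read-level artifacts, batch effects, spike-ins,
tissue-specific dispersion, or correlated gene-gene structure beyond the
planted factors — so passing recovery tests demonstrate correctness of the
pipeline's inference under its own model, not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

- Hypergeometric tails are computed in log space through scipy's survival
  function and match exact enumeration at 1e-12 for universes ≤ 30.
- p-values are clipped into (0, 1] so downstream -log10 and Holm steps
  are always defined.
- Zero-variance genes: similarity 0.5, flagged, never seed modules;
  constant traits are excluded from association with a warning; constant
  genes in classifier folds are scaled by 1 and flagged (an sd below 1e-8
  counts as constant, since log-CPM of identical columns is not
  bit-identical).
- Ties in Spearman use average ranks; ROC thresholds collapse tied scores
  so the AUROC equals the Mann-Whitney concordance with ties counted ½.
- All randomness flows from explicit integer seeds (numpy Generator,
  scikit-learn random_state); identical config + seed reproduces every
  table bit for bit, which the pipeline manifest (SHA-256 per output)
  makes checkable.

## Problem sizes used in the checks

The shipped tests run the recovery and calibration studies at reduced
scale, chosen once as the package's own test conditions: module-recovery
ARI on 650-gene studies (three 150-gene modules at strength 0.8 over five
seeds, mean ARI ≥ 0.9); blood-brain flagging on 1200-gene, three-tissue
studies over 20 seeds; DE null calibration at 2000 genes, n = 16;
classifier null calibration on six 300-gene null studies at 20 subjects
per group; end-to-end determinism on a 500-gene four-tissue study with
single-point classifier grids. Grids and study sizes are inputs, not
constants of the method.

## Known limitations

- The dynamic tree cut implements the tree variant with the distinct-
  branch rule described above, not the hybrid PAM stage; outlying genes
  near a module stay unassigned rather than being attached to the nearest
  eigengene.
- The scale-free fit index depends mildly on the binning (10 log bins);
  candidate β grids should bracket the expected value.
- PLSDA reports no embedded feature selection; all genes keep nonzero
  importance by construction.
- The elastic-net/glmnet λ correspondence is the per-sample average-loss
  convention; coefficients match unpenalized logistic regression only in
  the weak-penalty, well-conditioned limit (tested at 1e-3 tolerance).
- Between/within-subject correlation analyses assume one sample per
  (subject, tissue); technical replicates must be collapsed upstream.
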