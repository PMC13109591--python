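# Methods

This note records the statistical models `dopasig` implements, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Normalization and transformation

Size factors are median-of-ratios: with counts `K_gj`, the reference for
gene g is its geometric mean across samples, and
`s_j = median_g K_gj / geomean_g` over genes whose geometric mean is
positive (any zero count excludes a gene from the reference set). The
median is taken on the natural ratio scale, so with an even reference
count the interpolated midpoint is the arithmetic mean of the two middle
ratios. An error is raised when no gene is positive in every sample.

The variance-stabilizing transform is `log2(K_gj/s_j + 1)`. This is a
deliberate simplification of dispersion-trend-based VSTs: it is monotone,
finite at zero, and adequate for the stages it feeds (PCA, PERMANOVA,
co-expression, batch correction). It is never used for differential
testing, which works on raw counts.

Batch correction fits, per gene, ordinary least squares on the column
space `[intercept | design factors | batch factor]` (treatment coding,
alphabetically first level as reference) and subtracts only the batch
component `X_batch · beta_batch`. Refitting the joint model on corrected
data returns the same design coefficients with zero batch coefficients;
the operation is idempotent. Rank deficiency (batch confounded with
design) raises rather than silently dropping columns. By default
correction runs on VST values; any expression matrix can be passed.

## Exploratory structure

PCA operates on per-gene-centered VST values via SVD with a fixed sign
convention (the largest-magnitude loading of each component is positive).
A fully degenerate matrix (identical samples) yields zero variance
fractions and a warning rather than NaNs.

PERMANOVA uses squared Euclidean distances between sample profiles,
Gower-centered to `G`; for the ordered factor list it builds nested hat
matrices and takes sequential (Type-I) sums of squares
`SS_k = tr(H_{1..k} G) − tr(H_{1..k−1} G)`, so factor R² values plus the
residual sum to one and depend on factor order (document the order you
use). The null permutes sample rows freely; `p = (1 + #{F* ≥ F})/(1 +
n_perm)` with a relative tie tolerance of 1e−9 so permutations that
reproduce the observed grouping count as ties. p-values are BH-adjusted
across factors; the adjustment method is a package choice, as is the
default `n_perm = 999`.

The batch screen is a per-gene two-factor fixed-effects ANOVA
(site × condition, sequential SS, interaction included) on
`log2(raw + 1)`, BH-corrected per term. The second factor defaults to
condition; it is a parameter.

Marker-panel tests fit, per marker gene on `log2(normalized + 1)`, a
Gaussian random-intercept model `y = X beta + b_site + e` by REML with a
one-dimensional profile over `lambda = var_b/var_e` (bounded search on
`log lambda` in ±15, explicitly compared against the OLS boundary
`lambda → 0`). Contrasts against the healthy group use a normal
approximation to the Wald statistic — a simplification relative to
degrees-of-freedom corrections such as Satterthwaite's, slightly liberal
at these sample sizes. The site comparison is a two-sided Wilcoxon
rank-sum on pooled normalized expression; an all-tied gene reports p = 1.

## Differential expression

The model is NB2: `Var = mu + phi mu²`, log link, offset `log s_j`.
Dispersion estimation is a two-step scheme chosen for transparency over
power: (1) per-gene method of moments,
`phi = (v − mean(1/s)·mu)/mu²` with `v` the residual variance of an OLS
fit of normalized counts on the design, floored at 1e−8; (2) 50/50
log-scale shrinkage toward the least-squares trend `phi(mu) = a0 +
a1/mu`. There is no empirical-Bayes posterior, no outlier handling, no
independent filtering, and no fold-change shrinkage; all-zero genes are
excluded and flagged. The GLM is fitted by IRLS vectorized across genes
(shared model matrix; per-gene weights `mu/(1 + phi mu)`), convergence
at max coefficient change < 1e−8 within 50 iterations; non-converged
genes keep their estimate with p = NA. Contrast log2 fold changes are
`c'beta/ln 2` with standard errors from the inverse Fisher information;
two-sided Wald p, BH FDR over tested genes. DEG calls use strict
inequalities (FDR < 0.05 and |log2FC| > 1); a gene sitting exactly on a
boundary is excluded, the symmetric reading of both thresholds.

## Signatures

Differentiation signatures intersect the thresholded DEG lists of all
four day0-versus-week comparisons: up in every comparison → "neurons",
down in every comparison → "progenitors". The six condition signatures
apply fixed rules (PD_up = up in all three versus-healthy contrasts;
LRRK2_up = up in LRRK2-vs-healthy ∩ up in LRRK2-vs-Parkin; Parkin_up =
up in Parkin-vs-healthy ∩ down in LRRK2-vs-Parkin; mirrored for the
down sets), after which any gene admitted by two or more rules is
removed from all signatures. This symmetric removal is order-independent
and guarantees pairwise disjoint outputs without a (necessarily
arbitrary) sequential removal order. Provenance strings record the rule
that admitted each signature.

## Enrichment

Ranking scores are `sign(log2FC) · min(−log10 p, 300)`; ties are broken
by gene identifier so ranked lists are deterministic, and genes without
a p-value (non-converged fits) are dropped. The GSEA enrichment score is
the extreme of the weighted KS running sum with hit increments
`|score|^w / sum_hits |score|^w` (weight 1 by default — the classic
exponent; with weight 0 and all-zero hit scores the increments fall back
to equal steps) and miss decrements `1/(N − |S|)`. The implementation
evaluates the piecewise-linear path only at hit boundaries (O(|S|) per
set) and is tested against a full O(N) recomputation. The null is
gene-set (tag) permutation — random same-size sets, cached per set size
within a call — with sign-matched normalization: `NES = ES / mean |null
ES of the same sign|` and the nominal p from the matching-sign tail with
the +1 convention; BH FDR across sets. Defaults: `n_perm = 1000`,
`min_size = 5`, `max_size = 5000`. ORA uses the upper-tail
hypergeometric p `P(X ≥ k)` and `ER = (k/|hits|)/(|S|/|universe|)`.

## Interaction networks and MCL

Edge lists follow the STRING dialect: integer combined scores 0–1000
(a `unit_scale` flag accepts 0–1 files), self-loops dropped on load,
undirected duplicates resolved to the maximum score. Thresholds 400/700
correspond to the usual mid/high confidence cutoffs. The seeded network
is the induced subgraph of the DEG seeds over qualifying edges; expansion
adds first- then second-order interactors (iterated neighborhoods),
ranking candidates by connections into the current node set, then total
edge score, then name, truncated at `max_added` (default 50) per order
to keep graphs desk-scale.

MCL adds self-loops with each node's maximum incident weight (1 for
isolated nodes), column-normalizes, and alternates expansion (matrix
squaring) with inflation (elementwise power `r = 2.0`, renormalization),
pruning entries below 1e−5, until the matrix changes by less than 1e−6
or 100 iterations (then: warning flag). Clusters are connected
components of the attractor support — rows with surviving diagonal mass
and the columns they feed — which are disjoint and cover all nodes;
a node whose column feeds several attractor systems merges them, so no
separate overlap-resolution step is needed. Edge weights enter the
transition matrix (information-preserving; an unweighted variant is a
one-line change). The partition is deterministic.

## Co-expression

Genes are filtered to the `top_n` (default 5000) by median absolute
deviation; constant genes are dropped with a warning. Adjacency is
signed hybrid: `a_ij = cor_ij^beta` for positive correlations, zero
otherwise (Pearson or Spearman). The soft power is the smallest integer
1–20 whose degree distribution fits a scale-free law with R² ≥ 0.8 on
the binned log–log regression, falling back to 6. TOM is
`(L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with unit diagonal.

Module detection replaces dynamic tree cutting with a deterministic
two-step rule: average-linkage clustering of `1 − TOM`, scanning cut
heights from 0.99 downward in 0.01 steps to the first height with at
least two clusters of size ≥ `min_size`, then an eigengene-membership
clean-up that moves genes with `|cor(gene, module eigengene)| < 0.5`
to the grey set. The loose first cut alone absorbs weakly attached
background genes; the kME filter (standard in eigengene network
practice) restores tight modules while keeping the procedure fully
deterministic. Eigengenes are the unit-norm first principal component
of the module's per-gene z-scored expression, signed to correlate
positively with the module mean profile; a one-gene module's eigengene
is that gene's normalized z-score. Module–trait analysis reports
Pearson and Spearman correlations against one-hot factor indicators
(per-level indicators, a package choice) with BH FDR per method, plus a
per-module `eigengene ~ group` F-test. Co-expression input must carry
the `batch_corrected` provenance tag unless explicitly overridden.

## Pathway activity

Scores come from a long pathway × gene × weight table; non-member genes
get zero weight. `ulm` regresses each sample's across-gene z-scored
expression on the weight vector and reports the slope t-statistic
(invariant to affine rescaling of the sample). `wsum_perm` computes
`sum_g w_g x_gs` and standardizes against `n_perm` gene-label
permutations; at large `n_perm` the z agrees with the closed-form
permutation moments `E = w_+ x̄`, `Var = sigma² (sum w² − (w_+² − sum
w²)/(n−1))`. The association model is per-pathway OLS
`activity ~ mutation + gender + reprogramming + place` with treatment
coding (healthy as the mutation reference), per-coefficient two-sided
t-tests and BH FDR over the pathway × coefficient grid; aliased factor
pairs are detected and named. "GLM" here means Gaussian identity-link
least squares — activity scores are continuous. Module integration takes
PC1 of the module-eigengene matrix and Spearman-correlates it (and each
eigengene) with every pathway's activity, BH-adjusted.

## Synthetic data

The generator emulates the statistical structure of a two-site iPSC
cohort, not its biology. `study_samples()` reproduces the cohort layout:
34 samples — 12 healthy, 6 LRRK2, 16 Parkin — from six lines across two
sites (10/24), one female healthy line, two lentivirus-reprogrammed
Parkin lines, the rest Sendai. Counts are NB with log-uniform baseline
means over [2, 2¹²] and log-normal dispersions (median 0.1, sd of logs
1), spanning typical bulk RNA-seq; library-size factors are log-uniform
within ±0.5 log2. Planted effects multiply the NB mean by `2^lfc` for
samples at the named factor level; the default design plants |log2FC| =
2 mutation effects and an additive ±1 log2 site shift on a random 10% of
genes. Correlated modules arise from per-sample latent log2 factors
shared by a gene block; pathway shifts scale each target by its
normalized weight. The time course covers day 0 and weeks 2/4/6/8 with
marker effects ramping monotonically from half to full size (so even
the earliest neuronal time point clears the |log2FC| > 1 threshold at
the default effect of 3). Interaction graphs are planted partitions
with within-community scores in [600, 1000) and between in [400, 600).

What is *not* emulated: gene–gene correlation beyond the planted
modules, count outliers, GC/length biases, varying sequencing depth
beyond scalar size factors, isoform structure, and any real pathway
weight matrix (the TSV format accepts published footprint weights
unchanged). Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated model, not performance on
real tissue data.

## Problem sizes and defaults

The default pipeline config simulates 1500 genes (600 in the time
course), 999 PERMANOVA and 1000 GSEA/wsum permutations, and completes in
a few seconds; the acceptance experiments use 20 planted cohorts of 800
genes for DE calibration, 20 time courses, 10 planted partitions, and
10 co-expression runs. These sizes were chosen so the full validation
battery runs in about a minute while keeping Monte-Carlo error well
below the tolerances being checked. All stages are pure functions of
(inputs, config, seed); rerunning the pipeline with the same config
yields byte-identical outputs.

## Known limitations

- The log2 VST under-stabilizes low-count genes relative to
  dispersion-aware transforms; low-expression genes carry more weight in
  PCA/PERMANOVA than they would under a full VST.
- Dispersion estimation is moment-based; at very small n it is noisier
  than likelihood-based empirical Bayes and the Wald test can be
  slightly anticonservative for low-count genes.
- The LMM p-values use a normal approximation (no small-sample df
  correction).
- PERMANOVA R² is sequential; reported shares depend on the factor
  order, which must be stated alongside results.
- MCL is dense-matrix: fine for the desk-scale graphs the pipeline
  builds (≤ a few thousand nodes), not for a whole interactome.
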