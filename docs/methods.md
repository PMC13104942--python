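# Methods

## Reference model and query projection

The reference atlas is summarized once and frozen. Fitting proceeds as:
library-size normalization x → ln(1 + s·x/total) with s = 10⁴ (cells with
zero total counts are dropped and reported); selection of `n_hvg` highly
variable genes by standardized dispersion (variance/mean of the
log-normalized values, z-scored within 20 equal-frequency mean-expression
bins; requesting more genes than exist falls back to all genes); optional
per-gene OLS regression on a covariate; z-scaling per gene (genes with zero
standard deviation become all-zero columns) with clamping to ±`clip`; and
PCA of the scaled matrix by SVD. Components are oriented so the
largest-magnitude loading in each column is positive, making loadings
reproducible across BLAS implementations. The model stores the full
reference gene list, the HVG subset, the per-gene post-regression mean and
standard deviation, the loadings, the reference-cell embedding and the
reference state labels.

Queries are mapped into this *fixed* space: reference genes absent from the
query are added as all-zero columns (the alignment report records the
imputed and dropped gene sets), the aligned counts are log-normalized, the
cell-cycle score difference is optionally regressed out (below), and each
HVG is standardized with the **reference** mean and standard deviation —
not the query's — so that the coordinate system cannot drift with the
query's composition. Genes that were degenerate in the reference (sd 0)
contribute exactly zero. A gene the query lacks therefore contributes the
constant clamp(−μ_g/σ_g) to every cell, a fixed offset of the whole query
cloud rather than per-cell noise. Self-projection of the reference matrix
reproduces the stored embedding to machine precision, which the tests
assert at 1e−6.

Scaling the query with reference-frozen statistics (rather than re-scaling
the query) was a genuinely open choice; the frozen variant was chosen
because nearest-neighbour relations between query and reference cells are
only meaningful if both sit in the same affine frame.

## Cell-cycle correction

S and G2M phase scores are module scores (below) over marker gene lists;
the shipped defaults are the canonical Tirosh et al. (2016) lists (43 S,
54 G2M symbols), overridable by any two-set gene-set file — synthetic data
uses its own designated gene blocks. The per-cell difference
`cc_diff = s_score − g2m_score` is regressed out of every gene (OLS slope
on the centered covariate, gene means preserved) before scaling. Regressing
the difference rather than both scores preserves the proliferation axis
that separates cycling states while removing the within-cycle S/G2M
contrast. Phase is called G1 when both scores are ≤ 0 and otherwise the
phase of the larger score (S on an exact tie). A constant covariate
degenerates to plain centering, with a warning.

## Module scores

A signature's score per cell is the mean expression of the signature genes
minus the mean of an expression-matched control pool. Genes are ranked by
average expression (ties get their average rank) and the rank range is cut
into `nbin` = 24 equal-width intervals — identical to equal-frequency
binning when averages are distinct, and deterministic when they are tied.
Each signature gene draws `nctrl` = 100 control genes uniformly *with
replacement* from its own bin using a single seeded generator, so scores
are exactly reproducible. Adding a constant to the whole matrix leaves
scores unchanged (both means shift identically), which is a property test.
Signature genes absent from the matrix are dropped with a warning; an empty
intersection is an error.

## Consensus label transfer and identifiability

For each projected query cell the k = 10 nearest reference cells by
Euclidean distance in the d = 20 embedding vote on its state. Exact
distance ties break by ascending reference-cell index (stable argsort), so
results are platform-independent. A state is assigned only when its vote
count reaches `min_votes` = 5 **and** is uniquely maximal; otherwise the
cell is NA. With min_votes > k/2 qualifying ties are impossible; at
min_votes = k/2 a 5–5 split resolves to NA — the conservative reading of
the unassigned category. Identifiability I(q) = n_match/k is defined only
for assigned cells (requesting it for an NA cell raises
`UndefinedIdentifiabilityError`); it is bounded below by min_votes/k. The
implementation is checked label-for-label against a brute-force
full-distance-matrix vote counter on random instances.

Downstream summaries: per-state distributions of matching vs non-matching
neighbour counts ordered by the median difference (`stability_summary`);
responder fraction per state including NA, over cells from R/NR samples
only (`responder_enrichment`); and `prioritize_states`, which keeps states
in the top quartile of responder fraction whose median identifiability is
at least θ = 0.8 — enrichment alone proposes candidates, identifiability
gates out states whose atlas support is diffuse.

## Response modelling

Per-sample features are cell-count proportions under one of three schemes:
original cohort labels, transferred atlas labels (NA is a real category —
excluding it would break the sum-to-one constraint), or the observed
granular `cohort|atlas` intersections. Rows sum to one exactly, so any
design with an intercept is rank-deficient; columns are dropped by greedy
left-to-right Gram–Schmidt rank detection (tolerance 1e−10) — deterministic,
and on compositional designs it necessarily drops at least one column
(dropping any single proportion column is a reparameterization of the same
model). The logistic model is unpenalized maximum likelihood via IRLS
(at most 100 iterations, convergence 1e−8 on the coefficient change,
linear predictors clipped at ±30 for numerical stability); under complete
separation the iteration cap is reached and the fit is flagged
`converged=False` while probabilities are still returned. The
single-binary-covariate closed form (coefficient = 2×2 log-odds ratio) is a
unit test at 1e−6.

ROC AUC is the rank-sum form, (concordant + 0.5·tied)/(n₁·n₀), verified
against exhaustive pair enumeration. Pair-based cross-validation enumerates
*all* ordered (responder, non-responder) sample pairs; each fold refits on
the remaining samples and scores the held-out pair 1/0.5/0; the reported
value is the mean over folds. This makes the estimate deterministic given
the table — the scheme itself prescribes balanced two-sample test sets, and
enumeration plus per-fold averaging was chosen over random pairing or
pooling for reproducibility at small n. Repeated k-fold CV is stratified
with seeded shuffling and per-fold AUCs are averaged, not pooled; the fold
count is reduced to the smaller class count when necessary. The
feature-subsampling grid draws ⌈p·F⌉ features without replacement at
p ∈ {0.5, …, 0.9} for 10 iterations each, with all randomness derived from
one seed (the grid is bit-identical across runs). Per-PC information gain
centers the features, decomposes by SVD, fits a univariate logistic model
on each of the first min(n−1, F) component scores and reports
(null deviance − model deviance)/2, i.e. the log-likelihood improvement in
nats, alongside explained-variance fractions. "Information gain" had no
stated formula; the univariate log-likelihood improvement was chosen
because it is additive on the deviance scale and comparable across
components.

## Synthetic data

The generator emulates the structure the analyses assume, not gene-level
biology. Each of 8 states (Tn, Tcm, Trm, Teff, t-Teff, Tex, p-Tex, Tisg)
has a sparse Gaussian program (10% of genes, loading sd 0.8) over a shared
Gaussian baseline; state programs avoid the two designated cell-cycle gene
blocks (30 genes each) so the proliferation confound is orthogonal to state
identity. A 15% fraction of cells receives an additive S or G2M program
scaled by `cc_effect`. Per-cell expected counts are
softplus(baseline + program), normalized per cell and scaled by a lognormal
library size (meanlog ln 2000, sdlog 0.35); counts are negative binomial
with Var = μ + φμ², φ = 0.5. Query cohorts share the reference programs but
add a per-gene multiplicative lognormal batch factor (sdlog 0.2), extra
Bernoulli dropout (rate 0.1), and a 10% held-out gene fraction that
exercises zero-imputation. Sample compositions are
Dirichlet(5·1 + Δ·1_{response states}) with Δ = `effect_delta` = 5.2 added
for responders on the designated response state (t-Teff), chosen so the
mean t-Teff proportion shift is ≈ 0.10 ((5+Δ)/(40+Δ) − 1/8 ≈ 0.10). The
default cohort sizes mirror a realistic ICI trial: 20 responders + 20
non-responders at 1,200 CD8 cells per sample. Cohort labels are a
many-to-one coarsening of the true states — by default the six
non-exhausted states (including t-Teff) collapse into "Non-exhausted" and
Tex/p-Tex into "Exhausted", mimicking broad per-study cluster definitions —
plus 5% uniform label noise, with every noised position recorded in the
truth table. One seed drives the whole generation graph through spawned
`SeedSequence` children, so reference and cohort are individually
bit-reproducible.

What passing the in-silico benchmark shows: when per-sample state
compositions genuinely differ by response and the cohort's own labels are
too coarse to see it, atlas mapping plus compositional modelling recovers
the signal (mean pair-CV AUC ≥ 0.8 over seeds) while the coarse labels do
not. What it does not show: performance on real data — the generator has no
continuous differentiation trajectories, no shared programs between states
beyond random overlap, no ambient RNA or doublets, and its batch effect is
a per-gene multiplicative factor rather than a structured platform effect.
Mapping quality on real atlases will be worse near genuinely continuous
state boundaries, which is precisely what the NA category and the
identifiability score are for.

## Problem sizes and runtime

The test suite runs the full default-scale study (4,000 reference cells ×
1,500 genes; 40 samples × 1,200 cells) over 5 seeds for the discrimination
benchmark (~1 minute per seed) and uses smaller configurations (600
reference cells, 300 genes, 12 samples) for the unit and property tests.
The classifier oracle suite uses ≤ 500 reference and ≤ 200 query cells per
instance, where the brute-force comparison is exact and fast.

## Known limitations

* The logistic response model is unpenalized by design; with feature counts
  approaching the sample count it overfits freely (pair-CV AUCs can dip
  below 0.5 in that regime), and under separation coefficients are
  iteration-capped rather than maximum-likelihood.
* HVG selection uses a single dispersion criterion; no batch-aware HVG
  pooling is implemented.
* UMAP visualization, anchor-based transfer and CD4/CD8 compartment
  splitting are out of scope; compartment is an input attribute.
* The identifiability score is defined relative to the transferred label
  only; it does not measure distance-based novelty (a query cell far from
  the whole atlas can still be confidently labelled if its neighbourhood is
  pure).
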