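# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data does and does not emulate.

## Data model and encodings

Genotypes are an individuals × markers matrix over {0, 1, 2, missing},
counting copies of the dataset-minor allele under the additive inheritance
model. The minor allele is determined over the whole cohort (cases and
controls pooled): markers whose counted allele exceeds frequency 0.5 are
flipped `g → 2 − g`; an exact tie keeps the counted allele. Two encodings
feed the classifiers: *additive* (one 0/1/2 column per marker) and
*one-hot* (three indicator columns per marker, requiring imputation
first). One-hot importances are collapsed back to markers by the maximum
over the marker's columns (a strong genotype-specific signal survives the
aggregation; sum is available as an option).

Missing-data policy: the allelic chi-square drops missing calls per marker
(the allele totals shrink accordingly); classifiers require imputation by
the per-marker modal genotype, ties broken toward the smaller code so the
result is deterministic. Cohorts are usually analysed post-QC where
missingness is rare, so a simple deterministic rule is preferred over
dosage imputation.

Coordinates: VCF and GFF3 are 1-based inclusive, BED is 0-based half-open
and converted on read; the internal representation is 1-based inclusive.

## Allelic association test

Each marker contributes a 2×2 table of minor/major allele counts in cases
vs controls (two alleles per individual). The Pearson statistic
Σ(O−E)²/E with df = 1 is used without Yates continuity correction — the
standard choice for GWAS allelic tests at these sample sizes. Monomorphic
markers (a zero column margin) are retained with χ² = 0, p = 1 so that
every downstream ranking and the importance matrix keep the full marker
dimension. Ranking is most-significant-first (ascending p), ties broken by
(chrom, pos, id) for determinism. The Manhattan table flags markers
strictly below the configurable genome-wide threshold (default 1×10⁻⁹);
Bonferroni filtering (p ≤ α/m) is provided as an optional utility.

## Greedy block selection

Markers enter in ranked blocks of 1,000 (configurable). At step *k* a
logistic-regression model uses the top *k* blocks; stratified 5-fold CV
(folds seeded once and shared across steps, so the curve varies in the
number of markers rather than in fold noise) records control-class F1
mean ± SD and accuracy.

The stopping rule makes "the metrics stabilized" operational: from step 2
onward, compare the moving average of mean control-F1 over the last
`stop_window` steps (window truncated at the start of the curve) with the
moving average ending one step earlier; halt when the improvement falls
below `stop_tol` (defaults 3 and 0.005). The reported stop is the step
with the best mean control-F1 seen up to the halt, so the selected set is
never worse than the first block, and the full curve is always emitted so
users can override the chosen size by inspection. Ranking happens once,
globally, before selection — a deliberately simple protocol whose
optimistic bias (selection sees the same data as evaluation) is accepted
and documented rather than hidden behind nested CV.

## Classifiers and importances

All model selection uses exhaustive grid search with seeded stratified
5-fold CV, maximizing mean control-class F1; ties break by lower effective
complexity, then grid order. Reports follow the accuracy / per-class
precision-recall-F1 layout, mean ± SD over folds.

**Logistic regression** — L2-penalized (liblinear; solver and tolerance
overridable), strength `C` on the grid. An unpenalized fit is not
meaningful at m ≫ n, so a penalty is always present; importance is |θⱼ|.

**Gradient-boosted trees** — xgboost with binary logloss, seeded and
single-threaded for reproducibility; trees/depth/learning rate on the
grid. Importance is the backend's gain: the average split-quality
improvement over all splits using the feature, matching the information-
gain view of split quality (H(m) = −Σ pₘₖ log₂ pₘₖ;
IG = H(parent) − weighted child entropies — implemented in closed form in
`entropy_information_gain` and used as the test oracle). Features never
used split score 0. CatBoost's PredictionValueChange is an alternative
importance for the same model family: it measures the average squared
change in the ensemble output when the feature value changes,
PVC(i) = Σ_trees,leaves (v₁−avr)²c₁ + (v₂−avr)²c₂ with avr the
weight-averaged leaf value. It is documented here for completeness but not
used; gain is the operative measure.

**Attentive tabular network** — an original NumPy implementation of the
sparse-attention architecture for tabular data (`paretognome.tabnet`). At
decision step *t* an attentive transformer produces the mask
Mₜ = sparsemax(Pₜ ⊙ Aₜ), where the prior scale Pₜ = Π_{s<t} (γ − Mₛ)
discourages re-selecting features already used (γ = 1.5 allows moderate
re-use). Masked features Mₜ ⊙ x feed a per-step linear+ReLU feature
transformer whose output splits into a decision contribution (summed over
steps into the final logit) and the representation conditioning the next
step's attention. Architectural choices are deliberately compact for
desk-scale genotype design matrices: one linear+ReLU transformer per step
(no GLU stacks or ghost batch norm), width n_d = n_a = 8, T = 3 steps,
attention weights initialized small so masks start near-uniform and
sharpen during training, features standardized internally. Training is
manual backprop with Adam (lr 0.02, batch 256), binary cross-entropy plus
a mask-entropy sparsity penalty (λ = 1e-4), an early-stopping validation
split (10%, patience 5), and one simplification: the prior scale is
treated as a constant during backpropagation (a semi-gradient), which
removes the cross-step gradient chain through the prior at no observed
cost to mask quality. Everything is seeded, single-threaded NumPy, hence
bit-reproducible; the gradient implementation is verified against central
differences in the test suite. Importance is the per-sample step-summed
mask, averaged over samples (so the score is sample-size invariant) and
normalized to sum to 1.

## Pareto consensus

The four importance vectors (chi-square −log₁₀ p; |θ|; gain; cumulative
mask) form a markers × 4 matrix, all dimensions oriented "larger = more
important". Markers excluded by greedy selection receive 0 in the three
model dimensions rather than being dropped, so the chi-square dimension
can still carry them; with ranking by p this means the front is always a
subset of the selected markers unless model scores vanish. The front uses
weak dominance: *j* is dominated iff some marker is ≥ in all four
dimensions and > in at least one; duplicated score vectors are all kept.
The implementation sorts by score sum (a dominator always has a strictly
larger sum) and compares against the accepted front only; it is exactly
equivalent to the O(n²) all-pairs definition and is tested against that
oracle. The front is invariant under positive scaling or shifting of any
dimension — the property that makes it a threshold-free consensus.

Per-method top-K lists (default K = 100; K is a user choice, not a
recoverable constant of any particular study) plus the front give five
lists; their UpSet-style exclusive intersection counts partition the
union.

## Annotation and enrichment

Gene assignment is interval containment (1-based inclusive): inside ≥ 1
interval → genic with all overlapping symbols; otherwise intergenic with
the nearest flanking gene on each side and distances (both flanks when
equidistant; either may be absent at chromosome ends). Transcript-level
consequence terms need transcript models and are out of scope; the
genic/intergenic dichotomy with flanks covers the downstream use (gene
lists). Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with Benjamini–Hochberg FDR across the tested sets (threshold
default 0.05). The universe defaults to all genes in the interval file and
is overridable, because enrichment is universe-sensitive. Symbols compare
case-insensitively after whitespace stripping; alias resolution is the
user's responsibility.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes:
biallelic markers with MAF drawn uniformly from [maf_low, maf_high]
(defaults 0.05–0.5); haplotypes from a latent Gaussian copula thresholded
at the allele-frequency quantile, so marginal MAF is exact and
Hardy–Weinberg holds by construction; optional LD as AR(1) correlation
(ld_rho) of the latent variables within blocks of ld_block_size markers —
chosen because it gives tunable r² with exact marginals; MCAR missingness
at missing_rate. Phenotypes follow the additive logistic model
logit P(case) = β₀ + Σ βⱼ gⱼ over planted causal markers, with β₀ solved
by bisection so the expected case fraction hits the target to 1e-6 —
class imbalance is therefore controlled directly (default case fraction
0.883, matching the ~11.7% control share of heavily case-enriched cohort
designs). Default effect sizes β = 0.5 per allele are simulation
conveniences chosen to make recovery measurable at n = 2,000, not
estimates of real disease loci. Indels are treated as ordinary biallelic
markers.

Not emulated: recombination maps and realistic demography, imputation
uncertainty, covariates (age/sex), population stratification. Passing
recovery tests therefore demonstrates correctness of the machinery under
the assumed model, not robustness to confounding in real cohorts — on
real data, stratification control (PCA/admixture filtering) must happen
upstream.

The standard recovery condition used by the test suite and the acceptance
script is n = 2,000 individuals (balanced classes), m = 5,000 markers, 20
causal at β = 0.5, MAF ∈ [0.1, 0.5], no LD — large enough that the
chi-square arm recovers ≥ 80% of planted markers in the top 1% and the
Pareto front is strongly enriched for them, small enough to run in
seconds to minutes on one CPU.

## Numerical conventions and edge cases

- 0·log 0 := 0 in all entropy computations; entropies in bits (log₂).
- p-values clipped to [tiny, 1] before −log₁₀.
- Chi-square with a zero column margin → (0, 1); a group with no calls at
  a marker → untestable, p = 1.
- Mode imputation ties → smaller genotype code; top-K score ties → whole
  tie group included and flagged; ranking ties → genomic order.
- Sparsemax of an all-equal row → uniform distribution; its
  Jacobian-vector product is computed on the support only.
- The intercept solver brackets β₀ in [−50, 50] and reports an error when
  the target prevalence is unattainable.
- Seeds: every stochastic stage takes an explicit seed; derived seeds stay
  below 2³¹.

## Known limitations

- The attentive network is a compact variant; it is not intended to
  reproduce published benchmark numbers of the full architecture, only its
  interpretability mechanism (sparse per-step masks) at tabular-genotype
  scale.
- Greedy selection inherits the optimistic bias of global pre-ranking (see
  above).
- The Pareto front size is data-dependent and can be small; consumers
  needing fixed-size lists should use the top-K lists alongside it.
- Enrichment p-values are exact but conditional on the chosen universe.
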