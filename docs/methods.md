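# Methods

## Data model and scales

Expression matrices are genes × samples with a platform tag: `microarray`
(log2 intensities), `rnaseq` (RSEM abundances), or `zscore`. All models
consume per-gene z-scores computed across the samples of one dataset
(sample standard deviation, ddof = 1); z-scoring each dataset separately
is what lets a classifier trained on microarray cell-line data be applied
to RNA-seq patient data without retraining. Zero-variance genes map to
all-zero rows with a warning rather than erroring, so degenerate
synthetic fixtures run. Missing values are rejected at read time.

GI₅₀ is on a −log10 molar scale: larger values mean growth inhibition at
lower concentration, i.e. a more sensitive line. A threshold t converts
it to labels: sensitive iff GI₅₀ > t, ties resistant (a deterministic
convention; thresholds are generically between observed values, so ties
are rare). Candidate genes may first be screened against patient
RNA-seq: a gene is dropped when its RSEM value is below 5.0 in strictly
more than half the patients (both numbers configurable).

## MFA candidate selection

Classic MFA: standardize every variable; compute each block's first
singular value s₁ and weight the block by 1/s₁ so no block dominates the
global analysis; run a PCA (SVD) of the weighted concatenation. Variable
loadings are reported as correlations between the original variables and
the global component scores (correlation-circle coordinates, always in
[−1, 1]). Sign indeterminacy is resolved by flipping components so the
response variable's loading on component 1 is non-negative.

A gene is selected as drug-response-related when, in any block carrying
it, two conditions hold on the first n components (default 2):

* **alignment** — |cosine| between its loading vector and the GI₅₀
  variable's exceeds 0.5;
* **representation** — its loading-vector length is at least 0.45, i.e.
  the retained components explain ≥ ~20% of the gene's variance.

The representation gate is standard correlation-circle practice and is
what makes the rule selective: the *direction* of a short noise loading
in a 2-D plane is nearly uniform, so a pure angular cutoff of 0.5 would
pass about two thirds of noise genes regardless of signal. With both
gates, 25 replicate default panels give ≈ 93% recovery of planted genes
at ≈ 7% noise admission (both cutoffs configurable). The sign of the
strongest-block similarity sets the direction: positive → direct
(expression rises with sensitivity), negative → inverse.

When several drugs' GI₅₀ values are analyzed jointly, each drug is its
own one-variable block.

## SVM engine

Soft-margin SVC with RBF kernel parameterized by kernel scale σ
(γ = 1/2σ²) and box constraint C, solved by libsvm via scikit-learn with
the stopping tolerance tightened to 1e−8 so small-panel decision values
are reproducible to high precision (tests verify agreement with an
independent quadratic-programming solve of the dual to 1e−6 on ≤10-sample
instances; at extreme C·σ combinations the dual becomes nearly flat and
any solver's α carries slack, so hyperparameters in tests are scaled to
the data). Decision scores are signed hyperplane distances ("hu");
score ≥ 0 predicts sensitive.

LOOCV computes the Gram matrix once and slices it per fold. Two
objectives:

* **misclassification** — fraction of held-out samples predicted wrong;
* **bounded log-loss** — a sigmoid (Platt) calibration is fitted to the
  pooled held-out scores (Platt's smoothed targets (N⁺+1)/(N⁺+2), slope
  constrained non-positive so the posterior is non-decreasing in score),
  and the objective is the mean of 1 − p̂(true class), which lies in
  [0, 1]. Standard clipped cross-entropy is available as the
  `cross_entropy` objective; it is unbounded above and is not the
  default. The smoothing gives the bounded loss a floor of roughly
  1/(n/2 + 2) even on perfectly separable data.

Hyperparameter grid search is exhaustive over C × σ with ties broken
toward smaller C then smaller σ (prefer the less complex model). Default
grids are C ∈ {10, 10², 10³, 10⁴, 10⁵}, σ ∈ {10, 100, 1000}, matching
the magnitudes at which signatures are typically reported; they are
appropriate for z-scored panels of tens of genes and fully configurable.
Features are z-scored once globally by default — matching the use of one
normalization for both cell-line and patient data — with a
`rescale_per_fold` LOOCV flag that re-standardizes inside each training
fold instead; class imbalance is not reweighted.

## Backwards feature selection

From the candidate set, each round evaluates the LOOCV objective of every
leave-one-gene-out subset and removes the gene whose exclusion yields the
lowest error — i.e. the gene contributing the most error. (The
alternative reading, removing the gene whose exclusion *raises* error
most, would discard the most informative genes and cannot improve
accuracy.) The search runs to exhaustion (down to one gene); the visited
subset with the global minimum wins, and all tied optima are returned —
equally accurate signatures genuinely occur. Removal ties break
lexicographically by gene id, making the search reproducible. Grid search
wraps the whole BFS by default (one search per grid pair); a
`grid_per_step` flag re-optimizes hyperparameters at every subset
instead. An exhaustive-subset oracle (≤ 12 genes) provides the testing
bound: the greedy objective can never beat it, and on the shipped
planted-signal fixtures it attains it.

## Threshold sweep and ensembles

The default threshold grid is the midpoints of consecutive unique GI₅₀
values, keeping only cutoffs that leave ≥ 2 samples per class (the LOOCV
precondition). Each usable cutoff gets its own derived signature(s);
degenerate labelings are skipped with a log entry. Gene frequencies per
threshold interval (fraction of the interval's signatures containing the
gene, optionally grouped by functional category) are emitted as a table
and a grayscale heat map.

An ensemble's decision is the weighted mean of component hyperplane
distances with weights = each component's AUC computed from its LOOCV
*held-out* scores against the training labels — resubstitution scores
would give every strong component weight ≈ 1 and defeat the weighting.
Components whose AUC is undefined (single-class data) are excluded with a
warning. Subset modes restrict to a GI₅₀ threshold interval or to the
top-k AUCs. The composite score is a convex combination, hence bounded
by the component score range, and invariant to duplicating a component
with its weight split.

## Permutation significance and gene importance

Two nulls: random gene sets of the signature's size drawn uniformly from
the full pre-MFA gene universe (testing the biochemical selection
itself), and label permutations preserving class counts (testing the
expression–label association). The Monte-Carlo p-value counts null
iterations *at least as good* as the observed objective:
p = (n_as_good + 1)/(n_iter + 1). With a discrete objective (LOOCV
misclassification takes ~n distinct values) counting only strictly
better nulls is anti-conservative under ties; the tie-inclusive form is
super-uniform under the null (measured P(p ≤ 0.05) ≈ 0.02 over 300 null
replicates of 99 permutations). The strictly-better count is also
reported, as that is the quantity permutation analyses conventionally
print.

Gene importance is the change in LOOCV objective when one signature gene
is excluded (positive = removal worsens). Expression perturbation moves a
misclassified sample's single gene monotonically in both directions over
a grid bounded by `cap_multiplier` (default 3) times the gene's training
extremes, then bisects the first sign flip to 1e−6. For z-scored data
(training min < 0 < max) the bound is literally ±3× the extreme values;
for all-positive scales the bound is widened to contain the training
range so the cap never falls inside it.

## Patient evaluation

Outcome labels at a recurrence horizon T months: resistant iff recurrence
occurred at t ≤ T; sensitive iff disease-free beyond T (including
recurrence after T); disease-free patients censored at or before T are
excluded — counting them sensitive would inflate accuracy with
uninformative follow-up. Metrics are computed over non-excluded patients
only: per-class accuracies (sensitive is the positive class, so
sensitivity = accuracy among true-sensitive patients), overall accuracy
(their prevalence-weighted mean), and AUC by the rank-sum (Mann–Whitney)
formulation over decision scores, with ties mid-ranked; single-class
strata report AUC as missing. Stratification accepts any covariate
column (e.g. smoking history; the recent-quitter boundary defaults to 15
years and is configurable).

Stratified k-fold patient-only CV (k = 5) keeps the signature's genes and
(C, σ) fixed and re-learns only SVM weights per fold on patient
z-scores, pooling held-out predictions into one report.

Combination chemotherapy: given per-drug sensitivity probabilities dᵢ and
independent errors, p(sensitive to the combination) = 1 − Π(1 − dᵢ);
a pooled pair estimate d_ij replaces its two terms when error dependence
between two drugs is suspected.

## Synthetic data

`generate_panel` emulates a breast-cancer cell-line screen: default 40
lines × 30 genes i.i.d. standard normal, 3 informative genes with weights
±1 (one third inverse), GI₅₀ = weighted sum + N(0, 0.2²) affinely mapped
into [4.0, 5.6] to match the printed threshold range of real screens;
optional copy-number block correlated with expression at `cn_coupling`.
With these defaults the population correlation of each planted gene with
GI₅₀ is 1/√(3 + 0.04) ≈ 0.574, and at n = 40 about three quarters of
sample correlations exceed 0.5 — recovery tests are calibrated to that
analytic value, not to an idealized one.

`generate_cohort` draws patients with the same gene universe; the latent
standardized planted-gene score S sets an exponential recurrence hazard
λ = baseline · exp(−βS) (default baseline 0.03/month, β = 1), censoring
is independent exponential (mean 48 months), and binary covariates can
shift S. Expression is emitted on an affine positive RSEM-like scale
(8 + 2z by default, selected genes at 2 + 2z so the low-expression filter
has genuine targets): the affine map means z-scoring recovers the latent
values exactly, keeping the planted linear signal intact. That is a
deliberate simplification — real RSEM is skewed and heteroskedastic, and
real cohorts carry batch effects, platform differences, and
identifier mismatches that these generators do not emulate — so passing
recovery tests demonstrate correctness of the pipeline's machinery, not
expected field performance on real cohorts.

Every generator is a pure function of its spec, seed included.

## Problem sizes and numerical choices

Test and acceptance simulations are sized for a single CPU: permutation
calibration uses 10-sample panels with 99 permutations × 300 (tests) or
150 (script) replicates; exhaustive-subset comparisons cap at 10 genes on
16–20-line panels; recovery experiments use 25 replicate default panels
with reduced grids (C ∈ {10, 10³}, σ ∈ {10, 100}). libsvm runs at
tolerance 1e−8; Platt fitting uses L-BFGS-B on the smoothed-target
cross-entropy; probabilities are clipped to [1e−15, 1 − 1e−15];
perturbation bisection stops at 1e−6.

## Known limitations

* No probe-level microarray preprocessing, identifier mapping, or batch
  correction beyond per-dataset z-scoring.
* Only binary sensitive/resistant classification; no survival modeling of
  the time-to-event outcome beyond thresholding.
* Gaussian kernel only; no isotonic calibration; no forward or floating
  feature selection.
* LOOCV error estimates on small panels are themselves noisy and, under
  label permutation, pessimistically biased at very small n (the held-out
  class is under-represented in its fold) — an O(1/n) effect visible in
  the calibration tests.
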