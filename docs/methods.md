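# Methods

## Model and procedure

`npmatch` treats a batch effect as an additive, feature-wise technical
offset shared by the samples of a (possibly unrecorded) processing group,
superimposed on a normalized log2 expression matrix X ∈ ℝ^{p×n}. The
correction never sees a batch label; it uses the phenotype partition of the
n samples into c ≥ 2 classes, and the premise that biologically comparable
samples should be each other's nearest neighbors in expression space unless
technical offsets push them apart.

The pipeline is: feature selection → centering → distances → per-class
k-nearest-neighbor pairing → paired-matrix expansion → pairing-effect
removal → condensation. Stages and their contracts:

- **Feature selection.** The `n_top_features` (default 2000) features with
  the largest sample variance (ddof = 1) are used for the similarity
  computation only; ties break by first occurrence. The expansion and
  correction always operate on all p features, so no information is
  discarded from the output.
- **Centering.** Each selected feature is 0-centered globally and then
  within each phenotype class. This buffers class mean differences so that
  inter-sample correlation reflects residual (technical + individual)
  structure rather than the class contrast. The centered matrix feeds the
  distance computation only; the corrected output is built from the
  original uncentered values. A single-sample class centers to an all-zero
  profile and triggers a warning (and an error under Pearson distance,
  which is undefined there).
- **Distances.** Pearson correlation r between sample profiles is mapped to
  d = 1 − r ∈ [0, 2] — a one-dimensional scale on which anti-correlated
  samples are maximally distant. The alternative d = 1 − |r|
  (`distance_transform="abs"`), which treats anti-correlation as proximity,
  is provided for sensitivity analysis, as is plain Euclidean distance.
  One global distance matrix is computed and then partitioned by class.
- **Pairing.** For each anchor sample and each class (including the
  anchor's own), the k samples with smallest distance are selected, self
  excluded, ties broken by ascending sample index. k must satisfy
  k ≤ min class size − 1; an explicit error replaces silent clamping so the
  pair count L = n·k·c stays predictable. Every sample is matched; none is
  dropped.
- **Expansion.** The paired matrix has one column per pair, a verbatim copy
  of the neighbor's full-feature profile, labelled with the anchor identity
  (the *pseudo-batch*) and the neighbor's phenotype. By default each
  anchor's own column is added to its block (`include_self_columns=True`,
  L′ = n·(k·c + 1) columns). This default is deliberate: with self excluded
  from the search *and* no self columns, a sample that is nobody's nearest
  neighbor would have no corrected copy, leaving the condensation undefined
  — at n = 60, k = 1 that situation is routine, not exotic. The
  pair-columns-only variant remains available as an audited switch and then
  fails loudly on uncovered samples.
- **Pairing-effect removal.** Per feature, expression over the paired
  columns is regressed on [intercept | phenotype indicators (treatment
  coding) | anchor-block indicators (sum-to-zero coding)] by least squares,
  and only the anchor-block component is subtracted. Including the
  phenotype design protects biological differences from being absorbed into
  the block term; sum-to-zero coding removes deviations from the grand mean
  so no arbitrary reference block re-baselines the data. One shared
  pseudo-inverse serves all features and is numerically equal to
  per-feature OLS (tested to 1e-8). A rank-deficient design (blocks
  confounded with phenotype) is an error that names the confounded factor.
- **Condensation.** For each original sample, the unweighted mean of every
  paired-matrix column whose source is that sample. Output shape and ids
  equal the input's exactly; the whole pipeline is deterministic, so
  identical inputs give bitwise-identical output.

## Evaluation metrics

- **Silhouette width**: mean over samples of (b − a)/max(a, b) with
  Euclidean distance over the full feature space (the conventional default
  for this statistic); singleton clusters contribute 0. Phenotype
  silhouette should rise and batch silhouette fall after a good correction.
- **DEG count**: two-group moderated t (below) with inclusive thresholds
  |log2FC| ≥ 0.5 and BH-FDR ≤ 0.05. For c > 2 classes the reported count
  uses the first-vs-second class contrast (sorted order) unless a contrast
  is given.
- **SNR**: mean |log2FC| over all features divided by the mean per-feature
  SD across samples. The magnitude (not the signed mean) is used — a signed
  mean would cancel for balanced up/down signatures and gut the statistic.
- **PC1 ratio**: SVD of the feature-centered matrix; ρ_j is the absolute
  Pearson correlation of component j's sample scores with the 0/1 phenotype
  encoding (for c > 2, the maximum over one-vs-rest encodings); the ratio
  is ρ₁/Σρ over components with nonzero singular value. Near 1 means the
  phenotype owns the leading axis.
- **Integrated score**: exp of the mean log of the three
  corrected/uncorrected ratios (DEG, silhouette, SNR) — their geometric
  mean. Ratios are formed before logs, so the reference scores exactly 1.
  Guard policy for undefined logs: a DEG count of 0 is floored at 1 and a
  nonpositive silhouette at 1e-3 (`metrics.SS_FLOOR`), each with a loud
  warning; these floors are an implementation decision where no convention
  exists, and scores produced through them should be read only as "much
  worse than reference".
- **Mean rank**: per dataset, methods ranked by descending score (average
  ranks on ties); a method's mean rank across datasets summarizes overall
  performance.
- **Permutation control**: the correction is run under seeded-permuted
  phenotype labels and evaluated against the true labels. Because pairing
  exploits phenotype stratification, the permuted run must not score
  competitively — a guard against the score rewarding overcorrection.

## Moderated t-test

Per feature, the two-group fit gives the log2 fold change (class2 −
class1 mean) and residual variance s²_g on d = n₁ + n₂ − 2 df. Under a
scaled-F model the prior (d₀, s²₀) is estimated by moment matching on
log s²_g: the excess of var(log s²) over trigamma(d/2) equals
trigamma(d₀/2), inverted by Newton iteration; when no excess dispersion
remains, d₀ = ∞ and the common variance is the plain mean of s²_g. The
posterior variance s̃²_g = (d₀s²₀ + ds²_g)/(d₀ + d) yields
t = Δ/(s̃_g√(1/n₁ + 1/n₂)) on d + d₀ df, capped at the pooled residual df
(p·d) so the infinite-prior case is referenced against a t distribution
with the pooled df rather than a normal. p-values are BH-adjusted. Features
flat in both classes get t = 0, p = 1. The implementation is validated to
1e-8 against reference moderated statistics frozen from an established
external implementation on fixed instances of both the finite- and
infinite-prior regimes.

## Preprocessing

Raw-count inputs pass through: duplicate-feature collapsing (per-sample
mean, first-occurrence order), removal of all-zero features, per-sample
CPM followed by log2(CPM + 1), and across-sample quantile normalization
(sorted values replaced by the mean order statistic; ties within a sample
receive the mean of the reference values over their tied positions — the
"average" tie dialect). The chain order follows the narrative order of the
standard pipeline; quantile normalization is idempotent, so re-running the
final step is harmless. Users with already-normalized matrices skip all of
this — the corrector's contract starts at the normalized log matrix.

## Synthetic data

The generator emulates the study conditions the correction targets, on the
log2 scale it consumes: per-gene baselines N(7, 2); Gaussian noise
(SD 0.5); additive phenotype shifts of +1 log2 unit on a random 5% of
genes (one target class per DE gene); additive per-(gene, batch) shifts
N(0, 1) on a random 30% of genes; defaults p = 2000, n = 60, c = 2,
3 batches. Batch assignment mixes a deterministic phenotype→batch map with
uniform assignment at rate 1 − confounding (default 0, i.e. batch ⟂
phenotype); every batch is guaranteed nonempty. Defaults were chosen once
as a realistic mid-sized bulk expression study with batch variance
comparable to the biological effect; named scenarios vary size and balance
(`balanced`, `unbalanced-batches`, `confounded`, `tiny` with n = 8 across
2 batches, `multi-class` with c = 3). A Poisson companion
(counts ~ Poisson(2^x − 1)) exists solely to exercise the preprocessing
chain.

What the simulator does **not** emulate: mean–variance trends and
dispersion structure of real RNA-seq counts, library-size gradients,
correlated gene modules, multiplicative or nonlinear batch distortions,
and missing values. Passing tests therefore demonstrate correctness of the
algorithmics and robust behavior under additive Gaussian batch structure —
not performance on every real-data pathology.

## Numerical choices and degenerate inputs

Variance ties in feature selection and distance ties in pairing break
deterministically (first occurrence / ascending index). Distances are
symmetrized and clipped at 0 to absorb floating-point asymmetry.
Zero-variance samples are an error under Pearson distance. Missing or
non-finite values are rejected at construction — the per-feature
regressions require a complete matrix, so imputation must happen upstream.
Matrix I/O writes 17 significant digits so read∘write is an identity to
≤ 1e-12. The `random_seed` config field exists for audit reproducibility
only; no stage of the correction itself draws random numbers.

## Problem sizes in the test suite

The replicate-based behavioral checks run at the generator defaults
(p = 2000, n = 60): 50 replicates for correction efficacy, 20 for the
permutation control and the null-safety check, and 5 × 2000-feature null
datasets at n = 20 for type-I-error calibration — sizes chosen to estimate
the relevant proportions with comfortable margins while keeping the suite
quick on one CPU. Oracle-equivalence tests run on instances ≤ 50 × 40,
where brute-force references are exact and fast.

## Known limitations

The method outputs a corrected matrix only — no surrogate batch vectors
for downstream covariate modeling. Pairwise correlation and per-sample
neighbor search scale poorly to population-scale cohorts. Phenotype
mislabeling corrupts the stratified pairing. Strong batch–phenotype
confounding is fundamentally unidentifiable for any corrector; the
simulator can generate that regime (`confounded`, or confounding = 1 with
a warning) precisely so the degradation is visible. Single-cell data are
unsupported: there the phenotype (cell type) is typically the unknown and
the batch the known, the inverse of this method's premise.
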