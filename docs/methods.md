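# Methods

## Model

`scper` estimates the cell-type composition of bulk RNA-seq samples by
solving a per-sample linear system in a learned latent space. The premises
are:

- a bulk expression profile is, in linear (counts / CP10K) space, a convex
  combination of single-cell profiles, weighted by each cell's share of the
  total library;
- an encoder trained on single-cell references can place both cells and
  bulk samples into a shared low-dimensional space in which that convex
  structure is preserved;
- nuisance structure (study, platform, tissue of origin) can be removed
  from that space adversarially without destroying cell identity.

The pipeline runs: QC filtering → stratified subsampling → gene-panel
construction (intersection with the bulk gene set, then top highly variable
genes) → graph-diffusion imputation → adversarial autoencoder training →
embedding of cells and bulks → per-type median reference panel →
per-sample regression with clipping and renormalization → optional
phenotype statistics.

## Preprocessing

Cells with fewer than `min_detected_genes` (default 200) detected genes are
removed, as are detected-gene outliers outside the [Q0.01, Q0.99] band of
the per-dataset distribution, then genes seen in fewer than 3 retained
cells. Because a percentile band re-applied to a truncated distribution can
cut again, the filter iterates cell and gene passes to a fixed point, so
its output is stable under re-application.

Library normalization is counts-per-10k followed by log1p. Highly variable
genes are ranked by standardized dispersion — log variance of the
log-normalized expression minus a smooth trend f(log mean) fitted by local
linear regression (lowess, span chosen so at least ~30 genes support each
fit; one robustness iteration). Ties break lexicographically so the panel
is deterministic. The panel is intersected with the bulk gene set *before*
HVG ranking, guaranteeing every panel gene exists on both sides.

Imputation builds a cell–cell kNN graph (default k = 15) on the
log-normalized panel genes with an adaptive Gaussian kernel (bandwidth =
distance to the k-th neighbor), symmetrizes, row-normalizes to a Markov
matrix M and applies M^t (default t = 3). The diffusion averages profiles
in **linear CP10K space**, with the log1p view recomputed afterwards.
Averaging in log space instead would change every gene's linear-space mean
(Jensen's inequality), and since bulk samples *are* linear-space sums of
cells, that choice visibly mis-placed pseudobulk embeddings relative to the
reference (we measured a ~4.7× inflation of latent contrasts before
switching).

## Adversarial autoencoder

Architecture: encoder |panel| → 512 → 256 → 100 (ReLU hidden layers, linear
latent), mirrored decoder, and a linear softmax adversary from the latent
code to the confounder classes. All networks are plain-numpy MLPs with
hand-written backpropagation and Adam (lr 1e-3, batch 128); every weight
draw and shuffle derives from the config seed. Inputs are centered per gene
(not z-scored: dividing by per-gene sd inflates genes that are near-silent
in cells but nonzero in bulk averages, pushing bulk embeddings off-manifold).
Reconstruction error is averaged over genes inside the optimized objective
so the adversarial weight λ means the same thing for any panel size; the
reported `reconstruction_loss` remains the conventional per-row squared
2-norm.

Three further choices matter and were each adopted after the naive
alternative failed reproducibly on synthetic data:

1. **Confusion surrogate.** Gradient *ascent* on the adversary's
   cross-entropy is unbounded: the encoder learns to inflate latent norms so
   the adversary is confidently wrong, reconstruction collapses, and no
   information is removed. The encoder therefore minimizes the
   cross-entropy of the adversary's output against the *uniform*
   distribution — same fixed point (adversary at chance), bounded gradients.
2. **Gradient capping.** With Adam, a dominant adversarial gradient turns
   into indiscriminate parameter drift and collapses the latent space. The
   adversarial latent gradient is rescaled to at most λ × the
   reconstruction-gradient norm (with the first joint round's mean as a
   floor so pressure does not die away as reconstruction converges).
3. **Linear adversary, retrained hard.** A hidden-layer adversary overfits;
   the confusion gradient then points at memorized noise directions and
   erodes cell-type structure before batch structure. A linear adversary
   retrained 5 epochs per round keeps the pressure aimed at genuinely
   batch-predictive directions. The 100→64→K variant remains available via
   `adv_hidden`.

**Mixture consistency.** During both pretraining and joint training, each
minibatch contributes synthetic pseudo-mixtures: 16 uniform averages of 64
batch cells formed in CP10K space, whose latent codes are trained (squared
error, targets held fixed) to equal the same average of their members'
codes. This is the property the deconvolution step assumes — without it the
encoder is only locally linear and per-sample regression on real
pseudobulks degrades badly (per-type r ≈ 0.6 instead of ≈ 0.95 on the
synthetic benchmark).

**Schedule and stopping.** Autoencoder pretraining (default 50 epochs;
80 in the shipped benchmarks, where the extra alignment convergence
measurably tightens recovery), adversary pretraining (20), then alternating
rounds. The minimax oscillates rather than converging monotonically, so the
state of the round on which the adversary's accuracy was lowest is
checkpointed and returned, and training stops early once the adversary has
held within `adv_stop_margin` (0.05) of chance for 3 consecutive rounds (at
least `min_joint_rounds` = 10 rounds, cap `joint_rounds`).

**What deconfounding achieves.** On the two-batch synthetic benchmark the
co-trained adversary's held-out accuracy lands at chance (the acceptance
checks measure it), while a freshly trained cell-type probe on the same
embeddings stays near 1.0. A *freshly trained* batch classifier, however,
can often still decode the batch partially: the batch effect here is
compositional (a fold change on 300 genes shifts the CP10K share of every
other gene), so its complete removal would cost reconstruction across the
whole transcriptome. The embedding is "deconfounded" in the operational
sense of the adversarial game — the co-trained adversary cannot exploit it —
which is also the sense in which the estimator uses it.

## Proportion estimation

The reference panel is the coordinate-wise median latent per cell type
(midpoint convention on even counts); medians resist outlier cells and
doublet-like profiles. Each bulk sample is regressed independently: the 100
latent coordinates are the observations, the K panel rows the predictors.
The default solver is gradient boosting with linear base learners (L2
1e-3, 500 rounds, deterministic coordinate-descent updater), whose summed
weights are the coefficients; negatives are clipped to zero and the rest
renormalized to sum 1. If everything clips to zero the sample gets the
uniform vector and a `degenerate_flag` instead of silent NaNs. NNLS solves
the same system as an independent oracle; on noiseless convex combinations
the two agree to ~1e-4 L1 and NNLS recovers the truth to < 1e-3.

Scoring reports per-type Pearson r across samples, overall r across all
(sample, type) pairs, MSE and mean absolute deviation; undefined
correlations (zero variance) are reported as missing, never as 0.

## Synthetic data

The generator draws negative-binomial counts (gamma–Poisson, shared
dispersion 0.2) with per-gene base means log-uniform on [0.05, 3], 50
disjoint marker genes per type at 4-fold elevation, a batch effect of
4-fold on 300 genes (strong enough that a linear classifier reads batch off
raw data at > 0.9 accuracy), log-normal library-size factors (σ = 0.35) and
random patient labels. Defaults describe a two-batch, four-type, ~3,000-cell,
2,000-gene reference. Pseudobulks either sum all of a patient's cells
(truth = observed count fractions) or draw uniform random proportions,
apportion a 500-cell budget by largest remainder, and sum the sampled cells
(truth = realized fractions).

What it does not emulate: ambient RNA, doublets, dropout beyond NB
sparsity, cell-type abundance imbalance across batches, platform-specific
length biases, or continuous differentiation gradients. Passing tests on
this generator show the machinery is correct and the deconfounding/recovery
logic works under controlled confounding — not that accuracy transfers to
any particular real tissue.

## Accuracy envelope and limitations

On the shipped benchmark (5 types, 50 pseudobulks) the pipeline recovers
compositions with mean per-type r ≈ 0.92–0.98 and mAD ≈ 0.03–0.07 depending
on the generator seed; the residual error is a systematic, seed-dependent
amplification or compression of latent contrasts (the encoder is only
approximately linear over the mixture simplex), not sampling noise.
Estimates are RNA-share compositions: types with systematically larger
libraries are weighted accordingly, as in any expression-fraction
deconvolution. Exact reproducibility holds within one platform/BLAS build;
across platforms, floating-point reduction order may differ.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test (exact null for
small untied groups, tie-corrected normal approximation otherwise;
identical groups are reported as p = 1), with Benjamini–Hochberg adjusted
p-values emitted alongside raw ones. Mutual-information ranking uses the
k-nearest-neighbor estimator (k = 3) averaged over 20 seeded repeats, since
the estimator itself is stochastic. AUROC is the rank-statistic (ties count
half); classifier evaluation uses stratified 5-fold cross-validation
repeated 10×, reporting mean AUROC per feature count and choosing the
smallest count at the maximum.
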