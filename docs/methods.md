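# Methods

## The model

`dlvpm` fits deep latent variable path models: given K sample-aligned data
views X₁…X_K (N samples, p_i features each) and a binary adjacency matrix
C declaring which pairs of views should be associated, each view's
*measurement model* Ȳ_i(X_i, U_i, W_i) — a network body F_i(·, U_i)
followed by a strictly linear, bias-free projection W_i — produces n_dims
deep latent variables (DLVs).  Training maximizes

    Σ_{i≠j} c_ij tr( Ȳ_iᵀ Ȳ_j )   subject to   Ȳ_iᵀ Ȳ_i = I  for all i,

the path-restricted generalization of the CCA trace criterion.  With K=2
and identity bodies this is exactly classical CCA; with the adjacency
mask and shallow linear bodies it is PLS path modelling; with nonlinear
bodies it is a deep, multi-view generalization of both.

Optimization follows the iterative least-squares scheme: per mini-batch,
all views are forward-propagated first, then each view in turn minimizes

    Σ_j c_ij ½ ‖ ŷ_jⁿ − (F_i | Ȳ_i^{n−1}) w_iⁿ ‖²

where ŷ_jⁿ is the connected view's orthonormalized nth DLV treated as a
constant (stop-gradient) and (F_i | Ȳ^{n−1}) denotes the penultimate
features residualized against the view's previous DLVs.  Treating the
other views' outputs as constants matches the per-view update structure
and avoids representation-collapse dynamics; gradients flow through the
view's own body and projection only.

## Orthogonalization

Two schemes enforce the orthogonality constraint batch-wise during
training:

* **Iterative deflation** — DLVs are extracted sequentially; before
  extracting dimension n the features are residualized against the
  previously extracted (orthonormal) DLVs, `F − Ȳ(ȲᵀF)`.  Because the
  deflated regression for each dimension is solved greedily, components
  come out ranked by association strength, like principal components
  ranked by variance.
* **Whitening** — the raw projected block Y = F W is multiplied by the
  inverse square root of its batch Gram matrix, `Y (YᵀY)^{−1/2}`
  (symmetric eigendecomposition route by default; a Cholesky-based
  factorization spanning the same column space is available and faster
  for wide embeddings).

Train and inference behave differently, by design, exactly as in batch
normalization: during training, orthogonalization uses *batch*
statistics (global statistics do not enforce batch-level orthogonality,
so gradient updates would not be orthogonal); at inference, *global*
covariance matrices make the transform a deterministic row-wise map.
Global statistics are estimated online with momentum,

    Σ ← ρ Σ + (1−ρ) (N/b_t) Σ_batch ,   ρ = 0.95 by default,

initialized from the first batch scaled by N/b₀.  The N/b_t factor puts
batch statistics on the full-sample (sum) scale; consumers divide by N
where per-sample moments are needed, and the factor cancels inside every
regression solve.

**Finalization pass.** The momentum estimates blend statistics from
early batches, when the weights still differed; after the last epoch one
deterministic full-training-sample train-mode pass (dropout disabled)
replaces every tracker and moving statistic with its exact value at the
converged weights.  This measurably tightens held-out orthogonality —
with stale trackers the residual off-diagonal correlation between weakly
identified dimensions on fresh data roughly doubles — while leaving the
momentum scheme in place as the training-time mechanism it is.

**Inference scale convention.** Training normalizes each batch DLV to
unit norm; at inference each raw projection is divided by the square
root of its tracked per-sample second moment, so transformed DLVs have
unit variance per sample and the transform is a pure row-wise map
(permuting input rows permutes output rows).

**Rotational alignment (whitening variant).** The whitening objective is
invariant to applying one shared orthogonal rotation to every view's
DLVs, so the fitted coordinates are an arbitrary basis of the
association subspace.  After fitting, a canonical rotation is estimated
on the training data: the highest-degree view diagonalizes its summed
squared cross-correlation with its neighbours (eigendecomposition, which
also orders dimensions by association strength), and the remaining views
are aligned to already-aligned neighbours by orthogonal Procrustes,
breadth-first.  This reproduces, for two views, the SVD rotation that
turns whitened coordinates into canonical ones.  The iterative variant
needs no alignment; its deflation order is the ranking.

**Signs.** DLV signs are unidentifiable.  After fitting, each view's nth
DLV is flipped so that its summed covariance with connected views' nth
DLVs is positive, anchored at the first view.  All tests additionally
use sign-invariant metrics.

## Confound removal

Nuisance covariates C (N × D_c) are removed *inside* the network, in the
penultimate layer: batch-wise the layer computes
`F − C_b (C_bᵀ C_b)^{−1} C_bᵀ F` (the Moore–Penrose projection), making
every downstream linear readout exactly orthogonal to the confounds on
the batch; at inference it applies `F − C_b Σ_CC^{−1} Σ_CF` with the
momentum-tracked global matrices.  Because the final projection is
linear and bias-free, batch-level orthogonality of the features transfers
exactly to the DLVs — which is why no builder is allowed to put an
activation or a bias on the projection layer.  Rank-deficient batch
confounds raise an error naming the offending columns (rank-revealing
pivoted QR).

## Gradient orthogonality of the deflation scheme

For the per-dimension regression losses, the gradients with respect to
distinct projection vectors w^n, w^m satisfy ⟨g_n, g_m⟩ = 0 *given* (a)
batch-wise orthogonality of the view's own DLVs, (b) orthogonality of
the target DLVs, (c) alignment between the two (the target's nth DLV
orthogonal to the view's mth for n ≠ m), and (d) row-whitened batch
features (F Fᵀ ∝ I on the batch).  Conditions (a) and (b) hold by
construction; (c) holds at the aligned fixed point the training seeks;
(d) is a property of the batch.  The package verifies the identity is
exact (relative inner products at machine precision) in that regime and
measures relative inner products of order 10⁻¹ for generic unconverged
random instances — the orthogonality should be understood as a fixed-
point property of the scheme, approached during training, not a
pointwise identity.

## Twins (Siamese) variant

A single measurement model applied to two stochastic distortions of the
same input, trained with the same squared-difference objective (K = 2,
shared parameters).  Unlike the multi-view loop, gradients flow through
*both* branches: the objective is symmetric in the shared weights, so
stop-gradient on one branch would discard half the signal for no
benefit.  The loss has no hyperparameters beyond the embedding size.
Tabular augmentations (additive Gaussian noise, feature dropout, or
their composite) replace image augmentations; the contract is any
stochastic input-preserving map.  Finalization statistics are computed
on clean (un-augmented) inputs, since that is the inference condition.

## Classical baselines

* `cca_oracle` — eigen/SVD CCA: whiten each view by the inverse square
  root of its (jittered) covariance, SVD the cross matrix.  Used as the
  linear-limit oracle in the tests and as a user-facing baseline.
* `plspm_mode_b_fit` — PLS path modelling with within-view covariance
  replaced by identity (weight update `w_i ∝ X_iᵀ Σ_j c_ij y_j`,
  normalized), which stays defined for p > N.  The inner scheme targets
  the sum of connected views' latents, consistent with the
  sum-of-correlations objective; successive dimensions deflate each
  view's features against its accepted latents with the same
  residualization as the deep model, for comparability.  Non-convergence
  after `max_iter` warns and returns the best iterate.

## Downstream statistics

* `rank_inverse_normal` — Φ⁻¹((rank − ½)/N) with average ranks for ties;
  removes marginal skew, preserving order.
* `locus_scores` — per feature, Pearson correlations r_k against every
  connected DLV; score magnitude is the harmonic mean of |r_k| (the
  harmonic mean of signed values is ill-defined under mixed signs, and
  it is the weakest-link summary the multi-view question calls for),
  sign from the arithmetic mean; a single target reduces to r itself.
* `max_stat_permutation` — permutes the sample labels of all targets
  jointly (preserving the inter-locus correlation structure, required
  for strong family-wise control), records the max |score| per
  permutation, and reports p = (1 + #{max ≥ |s|})/(1 + n_perm) plus the
  (1 − α) critical score.
* `mediate` — OLS paths a (m~x), b and c′ (y~x+m), c (y~x) via
  statsmodels; c = c′ + a·b holds exactly on point estimates; percentile
  bootstrap CI and two-sided sign-based p for a·b (closed-form
  vectorized resampling).

## Synthetic data

`generate_multiview` draws one shared Gaussian factor set per connected
component of the path graph; view latents are
√ρ_n · shared + √(1−ρ_n) · independent, so any two connected views'
latents correlate at exactly ρ_n and unconnected views share nothing.
Mixing regimes: `linear` (random Gaussian loadings), `quadratic`
(even-indexed views linear, odd-indexed views exposing only centred
squares and pairwise products of their latents — pure even functions, so
every cross-view covariance visible to a linear method vanishes while a
nonlinear body can recover the shared factor up to the ρ² ceiling of
corr(z₁², z₂²)), and `mlp-random` (random two-layer maps).  Optional
confound channel: Gaussian confounds with unit-norm per-feature loadings
scaled by `confound_effect`, added to every view.  Noise is additive
Gaussian (`noise_sd`, default 1.0 — feature-level signal-to-noise of
one, a deliberately unflattering regime for p ≈ 10 features per view).
Gaussianity throughout matches the standardized / inverse-normal-
transformed inputs the method expects; the generator does not emulate
count overdispersion, missingness patterns, or batch structure of real
omics data, so passing tests certify the algorithmic claims, not
robustness to real-data pathology.

`generate_factor_view` builds the single-view testbed for the twins
variant: three latent factors loading on feature blocks of *unequal*
size (24/16/10 by default) plus pure-noise features.  The unequal sizes
give the factors distinct invariance strengths; with equal strengths any
rotation of the factor space is an equally good solution and
per-dimension recovery would be unidentifiable.

## Numerical choices

* Jitter: every covariance inverse / inverse square root / Cholesky adds
  ε·(mean diagonal)·I — *relative* jitter, ε = 1e-6 by default
  (orthogonalization paths) and 1e-12 for the plain least-squares solves,
  so layer outputs agree with exact normal-equations residuals to well
  below 1e-8 while small-scale Gram matrices stay safely conditioned.
* Column normalization uses ‖y‖ + 1e-8.
* Batch standardization divides by √(var + 1e-8) and raises on exactly
  constant batch columns (moving statistics apply momentum to the mean
  and the standard deviation, initialized from the first batch).
* Batch size must exceed max(n_dims, D_c); smaller batches make the
  orthogonalizations undefined and raise.  Ragged final batches smaller
  than that bound are dropped; epochs reshuffle with a seeded generator.
* All run-level randomness flows from a single seed expanded into named
  substreams (init / shuffle / permutation / bootstrap / augmentation).
* Adam throughout; default learning rate 1e-3.  The study configurations
  in the tests use 1e-2 decaying exponentially to 1e-3 — a point from the
  standard tuning grid (batch ∈ {32, 64, 128, 256}, lr ∈ {1e-2, 1e-3,
  1e-4}, exponential decay to a tenth) that `tune_grid` searches by
  validation mean cross-view correlation.

## Problem sizes and training budgets in the test suite

The linear-limit studies use N = 500 training samples, p = 10 features
per view, spectrum (0.8, 0.5, 0.2), batch 64, 100 epochs for the
iterative variant and 200 for the whitening variant (whose Gram-coupled
update converges more slowly on the weakest dimension); the
quadratic study N = 600/400 train/test, p = 12, one shared factor at
ρ = 0.95, 200 epochs; the twins study N = 600/400 with the 24/16/10
block design, 150 epochs.  Budgets were chosen as the smallest that
reach the classical oracle in the linear limit; on the quadratic data,
training much longer measurably *hurts* held-out correlation (the MLP
starts fitting sample noise), so the budget doubles as implicit
regularization and the package deliberately does not push past it.

## Known limitations

* Held-out orthogonality of weakly identified dimensions is bounded by
  the in-sample-orthogonalization limit shared with classical CCA: for
  spectrum entries near the detection floor (ρ ≈ 0.2 at N = 500,
  p = 10), trained directions orthogonalized on the training sample
  retain population off-diagonal correlations of roughly 0.05–0.15 —
  for the exact eigen CCA oracle as much as for this implementation.
* The measurement-model zoo is deliberately small (identity, two-layer
  MLP, embedding + single-head self-attention with residual merge);
  convolutional image branches are out of scope.
* Missing views are not imputed: every sample must carry all views.
* The attention pseudo-sequence uses length = embedding width with one
  channel and one head (key dimension = embedding width by default,
  configurable); other splits are possible and unexplored here.
* Training is single-threaded numpy; it is sized for desk-scale data
  (thousands of samples, hundreds of features per view), not for
  GPU-scale corpora.
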