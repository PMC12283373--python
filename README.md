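# dlvpm — deep latent variable path modelling

`dlvpm` integrates multiple sample-aligned data views — for example
RNA-seq, methylation, miRNA-seq, mutation profiles and image-derived
features from the same tumours — by learning, for each view, a small set
of orthogonal **deep latent variables** (DLVs) that are maximally
correlated with the DLVs of the views it is connected to in a
user-specified **path model** (a binary adjacency matrix over views).
It is a deep, multi-view generalization of canonical correlation
analysis and PLS path modelling: each view's *measurement model* is a
neural network ending in a strictly linear projection, trained under the
criterion

```
max  Σ_{i≠j} c_ij tr( Ȳ_i(X_i, U_i, W_i)ᵀ Ȳ_j(X_j, U_j, W_j) )
s.t. Ȳ_iᵀ Ȳ_i = I   for all views i
```

where `c_ij ∈ {0,1}` is the adjacency, `U_i` the network body and `W_i`
the final projection.  Orthogonality is enforced batch-wise during
training — by **iterative deflation** (which ranks DLVs by association
strength) or by **whitening** — and reproduced deterministically at
inference through momentum-tracked global covariance matrices.  Nuisance
covariates can be projected out *inside* the network (Moore–Penrose
confound layer), making the outputs exactly orthogonal to the confounds.

The package is written for analysts of multi-omics and multi-modal
cohort data who want path-structured latent variables with honest
train/test separation, plus the downstream statistics that turn latent
variables into biology: per-locus association scores (harmonic-mean
statistic with max-statistic permutation FWER control) and bootstrap
mediation analysis.  It also includes:

* **DLVPM-Twins** — the single-view Siamese variant: one shared-weight
  model applied to two stochastic distortions of the same input, giving
  augmentation-invariant representations with no loss hyperparameters
  beyond the embedding size;
* classical baselines/oracles — eigendecomposition **CCA** and **mode-B
  PLS path modelling**;
* a **synthetic multi-view generator** with known latent structure
  (correlation spectrum propagated along the path graph; linear,
  quadratic or random-MLP mixing; optional confound channel), so every
  claim is testable without any external data.

Everything is pure numpy/scipy (networks train on a small built-in
reverse-mode autodiff engine), sized for desk-scale data.

## Worked example

```python
import numpy as np
from dlvpm import (SimSpec, generate_multiview, split_views, DLVPM,
                   TrainConfig, validate_path_spec)

# two views sharing three latent factors at correlations 0.8 / 0.5 / 0.2
spec = SimSpec(K=2, N=700, p=[10, 10], n_latents=3,
               spectrum=(0.8, 0.5, 0.2), seed=7)
views, _, truth = generate_multiview(spec)
(train, _), (test, _) = split_views(views, 500)

path = validate_path_spec([[0, 1], [1, 0]])
model = DLVPM(train, path, variant="iterative", n_dims=3)
results = model.fit(TrainConfig(batch_size=64, epochs=100,
                                lr_initial=1e-2, lr_decay="exponential",
                                seed=0))
print(results.summary())

r_test = results.cross_view_correlations(test)
print("held-out correlations:", np.round(r_test, 3))
report = results.association_report(test, n_perm=999, seed=0)
print("dimension-1 r =", round(report.correlations[0][0, 1], 3),
      " FWER p =", round(report.p_values[0][0, 1], 4))
```

prints

```
Deep latent variable path model
==============================================
views: view0, view1
variant: iterative   n_dims: 3   N: 500   edges: 1
confounds: 0
----------------------------------------------
mean cross-view correlation per DLV (training data):
  DLV 1: +0.573
  DLV 2: +0.433
  DLV 3: +0.150
final epoch mean batch correlation: 0.382

held-out correlations: [0.468 0.301 0.13 ]
dimension-1 r = 0.468  FWER p = 0.001
```

The three DLV pairs come out ranked (the iterative variant extracts
dimensions in order of association strength), the held-out correlations
track the planted spectrum after noise attenuation — at these sample
sizes they agree with the exact CCA solution to within a few hundredths
— and the permutation test, which adjusts for all view pairs by the
max-statistic, confirms the leading association at p ≈ 0.001.

`DLVPMResults.transform` maps new samples to DLVs deterministically;
`save_checkpoint` / `load_checkpoint` round-trip the fitted model.  For
confounded data, pass a `ConfoundBlock` to `DLVPM(...)`; for a single
view use `DLVPMTwins` with an `AugmentationSpec`; for the shallow
baseline use `plspm_mode_b_fit`.

There is also a command line (`dlvpm simulate / fit / transform /
associate / loci / mediate`) driven by a YAML config; every run writes a
manifest with the package version, seed and config hash.

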