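"""Siamese (twins) training: one shared-weight measurement model applied to
two stochastic distortions of the same input.

The network is trained so that representations of paired augmentations
correlate maximally while remaining orthogonal within each branch, which
drives it toward features invariant to the augmentation.  The loss has no
hyperparameters beyond the embedding size: it is the same squared-difference
association objective as the multi-view model with two branches and shared
parameters, and — unlike the multi-view loop — gradients flow through both
branches simultaneously (the objective is symmetric in the shared weights).

Image augmentations are out of scope here; the contract is any stochastic
input-preserving map, and two tabular distortions are provided: additive
Gaussian noise and feature dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, constant
from .covariance import InvalidArgumentError, NumericDegeneracyError, DEFAULT_RHO
from .data import ViewData
from .layers import DLVBlock, NORM_EPS
from .measurement import MeasurementModel, MeasurementModelSpec
from .model import TrainConfig

__all__ = ["AugmentationSpec", "augment_pair", "DLVPMTwins", "TwinsResults",
           "fit_twins"]


@dataclass
class AugmentationSpec:
    """A stochastic input-preserving distortion."""

    kind: str = "additive_gaussian"   # additive_gaussian | feature_dropout | composite
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("additive_gaussian", "feature_dropout",
                             "composite"):
            raise InvalidArgumentError(f"unknown augmentation {self.kind!r}")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise sd must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidArgumentError("dropout rate must be in [0, 1)")


def _distort(X: np.ndarray, spec: AugmentationSpec,
             rng: np.random.Generator) -> np.ndarray:
    out = X
    if spec.kind in ("additive_gaussian", "composite") and spec.noise_sd > 0:
        out = out + spec.noise_sd * rng.standard_normal(X.shape)
    if spec.kind in ("feature_dropout", "composite") and spec.dropout_rate > 0:
        mask = rng.random(X.shape) >= spec.dropout_rate
        out = out * mask
    return out if out is not X else X.copy()


def augment_pair(X, spec: AugmentationSpec,
                 rng: np.random.Generator | None = None):
    """Two independent stochastic distortions of ``X``; deterministic for a
    given ``spec.seed`` (or caller-supplied generator)."""
    X = np.asarray(X, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _distort(X, spec, rng), _distort(X, spec, rng)


class DLVPMTwins:
    """Single-view twins model with a shared measurement network."""

    def __init__(self, view: ViewData, augmentation: AugmentationSpec,
                 measurement_spec: MeasurementModelSpec | None = None,
                 variant: str = "iterative", n_dims: int = 5,
                 rho: float = DEFAULT_RHO,
                 whiten_method: str = "inverse_sqrt"):
        if variant not in ("iterative", "whiten"):
            raise InvalidArgumentError(f"unknown variant {variant!r}")
        self.augmentation = augmentation
        self.variant = variant
        self.n_dims = int(n_dims)
        self.rho = float(rho)
        self.whiten_method = whiten_method
        if measurement_spec is None:
            measurement_spec = MeasurementModelSpec(
                kind="linear", input_dim=view.n_features, n_dims=self.n_dims)
        if measurement_spec.n_dims != self.n_dims:
            raise InvalidArgumentError("measurement spec n_dims mismatch")
        self.measurement_spec = measurement_spec
        mu = np.nanmean(view.matrix, axis=0)
        sd = np.nanstd(view.matrix, axis=0)
        if np.any(sd == 0):
            raise InvalidArgumentError("constant features in twins input")
        self._mu, self._sd = mu, sd
        X = np.nan_to_num((view.matrix - mu) / sd, nan=0.0)
        self.view = ViewData(X, view.sample_ids, view.feature_names,
                             view.view_name, standardized=True)
        self.measurement_model: MeasurementModel | None = None

    @property
    def N(self) -> int:
        return self.view.n_samples

    def fit(self, config: TrainConfig | None = None) -> "TwinsResults":
        config = config or TrainConfig()
        k = self.n_dims
        if config.batch_size <= k:
            raise InvalidArgumentError(
                f"batch_size {config.batch_size} must exceed n_dims {k}")
        ss = np.random.SeedSequence(config.seed)
        rng_init, rng_shuffle, rng_aug, rng_drop = [
            np.random.default_rng(s) for s in ss.spawn(4)]
        mm = MeasurementModel(self.measurement_spec, self.rho, rng_init,
                              self.view.view_name)
        self.measurement_model = mm
        N = self.N
        n_batches = max(1, N // config.batch_size)
        lr_final = (config.lr_initial / 10
                    if config.lr_decay == "exponential" else None)
        opt = Adam(mm.params(), lr=config.lr_initial, lr_final=lr_final,
                   decay_steps=config.epochs * n_batches)
        X = self.view.matrix
        history = []
        for epoch in range(config.epochs):
            perm = rng_shuffle.permutation(N)
            ep_corr, ep_loss, seen = 0.0, 0.0, 0
            for start in range(0, N, config.batch_size):
                idx = perm[start:start + config.batch_size]
                if len(idx) < k + 1:
                    continue
                XA, XB = augment_pair(X[idx], self.augmentation, rng_aug)
                branches = []
                for Xb in (XA, XB):
                    F = mm.features_train(Xb, None, N, rng_drop)
                    if self.variant == "iterative":
                        branches.append(mm.iterative_forward_train(F, N))
                    else:
                        branches.append(mm.whiten_forward_train(
                            F, N, self.whiten_method))
                (rawA, tgtA), (rawB, tgtB) = branches
                loss_t = None
                if self.variant == "iterative":
                    for n in range(k):
                        dA = constant(tgtB[:, n:n + 1]) - rawA[n]
                        dB = constant(tgtA[:, n:n + 1]) - rawB[n]
                        term = 0.5 * ((dA * dA).sum() + (dB * dB).sum())
                        loss_t = term if loss_t is None else loss_t + term
                else:
                    dA = constant(tgtB) - rawA
                    dB = constant(tgtA) - rawB
                    loss_t = 0.5 * ((dA * dA).sum() + (dB * dB).sum())
                pen = mm.penalty()
                if pen is not None:
                    loss_t = loss_t + pen
                if not np.isfinite(loss_t.data):
                    raise NumericDegeneracyError(
                        f"non-finite twins loss at epoch {epoch}")
                opt.zero_grad()
                loss_t.backward()
                opt.step()
                a = tgtA - tgtA.mean(0)
                bb = tgtB - tgtB.mean(0)
                a /= np.linalg.norm(a, axis=0) + NORM_EPS
                bb /= np.linalg.norm(bb, axis=0) + NORM_EPS
                ep_corr += float(np.abs((a * bb).sum(0)).mean()) * len(idx)
                ep_loss += float(loss_t.data)
                seen += len(idx)
            history.append({"epoch": epoch,
                            "pair_corr": ep_corr / max(seen, 1),
                            "loss": ep_loss / max(seen, 1)})
        # exact full-sample finalization of moving stats and trackers at
        # the converged weights, on clean (un-augmented) inputs
        mm.reset_statistics()
        F = mm.features_train(X, None, N, rng_drop, stochastic=False)
        if self.variant == "iterative":
            mm.iterative_forward_train(F, N)
        else:
            mm.whiten_forward_train(F, N, self.whiten_method)
        return TwinsResults(self, pd.DataFrame(history))

    def _standardize_new(self, X) -> np.ndarray:
        X = X.matrix if isinstance(X, ViewData) else np.asarray(X, float)
        return np.nan_to_num((X - self._mu) / self._sd, nan=0.0)


class TwinsResults:
    """Fitted twins model: representations and invariance diagnostics."""

    def __init__(self, model: DLVPMTwins, history: pd.DataFrame):
        self.model = model
        self.history = history

    def _transform_std(self, Xs: np.ndarray) -> np.ndarray:
        mm = self.model.measurement_model
        if mm is None:
            raise InvalidArgumentError("twins model is not fitted")
        F = mm.features_infer(Xs, None)
        if self.model.variant == "iterative":
            return mm.iterative_forward_infer(F)
        return mm.whiten_forward_infer(F, self.model.whiten_method)

    def transform(self, X=None) -> DLVBlock:
        """Deterministic representation of (new) samples."""
        if X is None:
            if self.model.view is None:
                raise InvalidArgumentError(
                    "restored model has no training data; pass X")
            Xs = self.model.view.matrix
        else:
            Xs = self.model._standardize_new(X)
        name = self.model.view.view_name if self.model.view is not None else ""
        return DLVBlock(self._transform_std(Xs), name)

    def pair_correlations(self, X=None, seed: int = 0) -> np.ndarray:
        """Per-dimension correlation between representations of two fresh
        augmentations of the same samples (augmentation applied on the
        standardized feature scale)."""
        if X is None and self.model.view is None:
            raise InvalidArgumentError(
                "restored model has no training data; pass X")
        Xs = (self.model.view.matrix if X is None
              else self.model._standardize_new(X))
        rng = np.random.default_rng(seed)
        XA, XB = augment_pair(Xs, self.model.augmentation, rng)
        YA = self._transform_std(XA)
        YB = self._transform_std(XB)
        return np.array([np.corrcoef(YA[:, n], YB[:, n])[0, 1]
                         for n in range(YA.shape[1])])

    def summary(self) -> str:
        r = self.pair_correlations()
        lines = ["Twins (Siamese) representation model",
                 "=" * 42,
                 f"variant: {self.model.variant}   "
                 f"n_dims: {self.model.n_dims}   N: {self.model.N}",
                 f"augmentation: {self.model.augmentation.kind} "
                 f"(sd={self.model.augmentation.noise_sd}, "
                 f"dropout={self.model.augmentation.dropout_rate})",
                 "augmented-pair correlation per dimension:"]
        lines += [f"  dim {n + 1}: {v:+.3f}" for n, v in enumerate(r)]
        return "\n".join(lines)


def fit_twins(view: ViewData, augmentation: AugmentationSpec,
              config: TrainConfig | None = None,
              measurement_spec: MeasurementModelSpec | None = None,
              variant: str = "iterative", n_dims: int = 5) -> TwinsResults:
    """Convenience wrapper: build and fit a :class:`DLVPMTwins` model."""
    model = DLVPMTwins(view, augmentation, measurement_spec, variant, n_dims)
    return model.fit(config)
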