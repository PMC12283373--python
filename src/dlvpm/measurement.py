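"""Per-view measurement models: networks mapping raw features to DLVs.

Every measurement model is a *body* (identity, small MLP, or the
attention-based omics architecture) followed by a standard head:
batch standardization -> dropout -> optional confound-removal layer ->
a strictly linear, bias-free projection onto ``n_dims`` latent variables.
The linear final projection is a hard architectural constraint: it is what
makes confound removal in the penultimate layer exact for the outputs.

The omics body reduces the input to an embedding of width ceil(sqrt(p)),
reshapes it into a pseudo-sequence, applies a single self-attention block,
and merges the result with the embedding through a residual connection, so
the projection sees both the (linear) main effects and learned interaction
effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, constant, parameter
from .covariance import (
    CovarianceTracker,
    InvalidArgumentError,
    init_tracker,
)
from .layers import (
    BatchStandardizeLayer,
    ConfoundLayer,
    DropoutLayer,
    deflate_t,
    inv_sqrt_sym,
    whiten,
    JITTER,
    NORM_EPS,
)

__all__ = [
    "MeasurementModelSpec",
    "MeasurementModel",
    "build_linear",
    "build_mlp",
    "build_omics",
]


@dataclass
class MeasurementModelSpec:
    """Architecture hyperparameters for one view's network."""

    kind: str = "linear"  # linear | mlp | omics_attention
    input_dim: int = 0
    n_dims: int = 5
    embed_dim: int | None = None   # omics default: ceil(sqrt(p))
    hidden: int = 32               # mlp hidden width
    dropout: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    use_confound_layer: bool = False
    attention_heads: int = 1
    key_dim: int | None = None     # default: embed_dim

    def __post_init__(self):
        if self.kind not in ("linear", "mlp", "omics_attention"):
            raise InvalidArgumentError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidArgumentError("dropout must be in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise InvalidArgumentError("penalties must be >= 0")
        if self.kind == "omics_attention":
            if self.input_dim < 4:
                raise InvalidArgumentError("omics model needs p >= 4")
            if self.embed_dim is None:
                self.embed_dim = math.ceil(math.sqrt(self.input_dim))
            if self.embed_dim < self.n_dims:
                raise InvalidArgumentError(
                    f"embed_dim {self.embed_dim} < n_dims {self.n_dims}")
            if self.key_dim is None:
                self.key_dim = self.embed_dim
        if self.kind == "linear" and self.input_dim < self.n_dims:
            raise InvalidArgumentError(
                f"linear model needs p >= n_dims "
                f"({self.input_dim} < {self.n_dims})")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _LinearBody:
    """Identity body: the projection layer sees the raw (standardized)
    features, reducing the model to the classical linear objective."""

    out_dim: int

    def __init__(self, spec: MeasurementModelSpec, rng):
        self.out_dim = spec.input_dim

    def params(self):
        return []

    def weight_params(self):
        return []

    def forward(self, X: Tensor, train: bool, rng) -> Tensor:
        return X


class _MLPBody:
    """Two tanh hidden layers of equal width."""

    def __init__(self, spec: MeasurementModelSpec, rng):
        p, h = spec.input_dim, spec.hidden
        self.W1 = parameter(_glorot(rng, p, h))
        self.b1 = parameter(np.zeros((1, h)))
        self.W2 = parameter(_glorot(rng, h, h))
        self.b2 = parameter(np.zeros((1, h)))
        self.out_dim = h

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def weight_params(self):
        return [self.W1, self.W2]

    def forward(self, X: Tensor, train: bool, rng) -> Tensor:
        h = (X @ self.W1 + self.b1).tanh()
        return (h @ self.W2 + self.b2).tanh()


class _OmicsAttentionBody:
    """Square-root embedding -> pseudo-sequence self-attention -> residual.

    The embedding output of width ``e`` is treated as a length-``e``
    sequence with one channel; a single-head scaled-dot-product attention
    block captures interaction effects, and its output is added back onto
    the embedding (residual merge).
    """

    def __init__(self, spec: MeasurementModelSpec, rng):
        p, e, dk = spec.input_dim, spec.embed_dim, spec.key_dim
        self.embed_W = parameter(_glorot(rng, p, e))
        self.embed_b = parameter(np.zeros((1, e)))
        self.Wq = parameter(_glorot(rng, 1, dk))
        self.Wk = parameter(_glorot(rng, 1, dk))
        self.Wv = parameter(_glorot(rng, 1, 1))
        self.key_dim = dk
        self.out_dim = e

    def params(self):
        return [self.embed_W, self.embed_b, self.Wq, self.Wk, self.Wv]

    def weight_params(self):
        return [self.embed_W, self.Wq, self.Wk, self.Wv]

    def forward(self, X: Tensor, train: bool, rng) -> Tensor:
        emb = X @ self.embed_W + self.embed_b          # (b, e)
        b, e = emb.shape
        seq = emb.reshape(b, e, 1)                     # pseudo-sequence
        q = seq @ self.Wq                              # (b, e, dk)
        k = seq @ self.Wk
        v = seq @ self.Wv                              # (b, e, 1)
        scores = (q @ k.T) * (1.0 / math.sqrt(self.key_dim))
        att = scores.softmax(axis=-1) @ v              # (b, e, 1)
        return att.reshape(b, e) + emb                 # residual merge


_BODIES = {"linear": _LinearBody, "mlp": _MLPBody,
           "omics_attention": _OmicsAttentionBody}


class MeasurementModel:
    """One view's network with its head state (moving stats, trackers).

    The final projection ``W`` (out_dim x n_dims) carries no bias and no
    activation.  Per-view covariance trackers estimate, at full-sample
    (sum) scale, the statistics needed to reproduce the batch-wise
    orthogonalization deterministically at inference:

    - iterative variant: ``sigma_yf`` (DLV-feature cross-covariance, in the
      unit-variance DLV basis), ``sigma_yy`` (DLV Gram), and the raw
      projection scale per dimension;
    - whitening variant: ``sigma_yy`` of the raw projected block.
    """

    def __init__(self, spec: MeasurementModelSpec, rho: float,
                 rng: np.random.Generator, view_name: str = ""):
        self.spec = spec
        self.view_name = view_name
        self.rho = rho
        self.body = _BODIES[spec.kind](spec, rng)
        self.bn = BatchStandardizeLayer(rho)
        self.dropout = DropoutLayer(spec.dropout)
        self.conf = ConfoundLayer(rho) if spec.use_confound_layer else None
        d = self.body.out_dim
        if d < spec.n_dims:
            raise InvalidArgumentError(
                f"body output dim {d} < n_dims {spec.n_dims}")
        self.W = parameter(_glorot(rng, d, spec.n_dims))
        self.sigma_yf: CovarianceTracker | None = None
        self.sigma_yy: CovarianceTracker | None = None
        self.scale: CovarianceTracker | None = None

    # ------------------------------------------------------------------
    @property
    def n_dims(self) -> int:
        return self.spec.n_dims

    @property
    def trained(self) -> bool:
        return self.bn.stats.initialized

    def params(self):
        return self.body.params() + [self.W]

    def penalty(self) -> Tensor | None:
        """L1/L2 penalty over weight-bearing layers (biases excluded)."""
        if self.spec.l1 == 0 and self.spec.l2 == 0:
            return None
        total = None
        for p in self.body.weight_params() + [self.W]:
            term = self.spec.l1 * p.abs().sum() + self.spec.l2 * (p * p).sum()
            total = term if total is None else total + term
        return total

    # ------------------------------------------------------------------
    def reset_statistics(self) -> None:
        """Clear moving statistics and covariance trackers (used by the
        exact full-sample finalization pass after training)."""
        self.bn = BatchStandardizeLayer(self.rho)
        if self.conf is not None:
            self.conf = ConfoundLayer(self.rho)
        self.sigma_yf = None
        self.sigma_yy = None
        self.scale = None

    def features_train(self, Xb: np.ndarray, Cb: np.ndarray | None,
                       n_total: int, rng: np.random.Generator,
                       conf_names=None, stochastic: bool = True) -> Tensor:
        """Body -> batch standardization -> dropout -> confound removal."""
        F = self.body.forward(constant(Xb), True, rng)
        F = self.bn.forward_train(F)
        if stochastic:
            F = self.dropout.forward_train(F, rng)
        if self.conf is not None:
            if Cb is None:
                raise InvalidArgumentError(
                    f"view {self.view_name!r} has a confound layer but no "
                    "confounds were supplied")
            F = self.conf.forward_train(F, Cb, n_total, conf_names)
        return F

    def features_infer(self, X: np.ndarray,
                       Cb: np.ndarray | None) -> np.ndarray:
        F = self.body.forward(constant(X), False, None).data
        F = self.bn.forward_infer(F)
        if self.conf is not None:
            if Cb is None:
                raise InvalidArgumentError(
                    f"view {self.view_name!r} needs confounds at inference")
            F = self.conf.forward_infer(F, Cb)
        return F

    # -- iterative orthogonalization -----------------------------------
    def iterative_forward_train(self, F: Tensor, n_total: int):
        """Per-dimension deflated projections on one training batch.

        Returns the list of raw projection columns (graph nodes, used in
        the regression loss) and the batch-orthonormal DLV block (numpy,
        used as other views' targets and for deflation).  Trackers are
        updated with per-sample-unit-variance DLV statistics.
        """
        b, d = F.shape
        k = self.n_dims
        if b <= k:
            raise InvalidArgumentError(
                f"batch size {b} must exceed n_dims {k} for "
                "orthonormalization")
        ys_raw = []
        Yhat = np.zeros((b, 0))
        raw_sq = np.zeros(k)
        for n in range(k):
            Fn = deflate_t(F, Yhat)
            y_t = Fn @ self.W[:, n:n + 1]
            ys_raw.append(y_t)
            y = y_t.data[:, 0]
            raw_sq[n] = y @ y
            Yhat = np.column_stack([Yhat, y / (np.linalg.norm(y) + NORM_EPS)])
        # per-sample-unit-variance DLV basis for the trackers
        Yps = Yhat * math.sqrt(b)
        stat_yf = Yps.T @ F.data
        stat_yy = Yps.T @ Yps
        if self.sigma_yf is None:
            self.sigma_yf = init_tracker(stat_yf, n_total, b, self.rho)
            self.sigma_yy = init_tracker(stat_yy, n_total, b, self.rho)
            self.scale = init_tracker(raw_sq, n_total, b, self.rho)
        else:
            self.sigma_yf.update(stat_yf, b)
            self.sigma_yy.update(stat_yy, b)
            self.scale.update(raw_sq, b)
        return ys_raw, Yhat

    def iterative_forward_infer(self, F: np.ndarray) -> np.ndarray:
        """Deterministic DLVs using global trackers; unit per-sample
        variance columns."""
        if self.sigma_yf is None:
            raise InvalidArgumentError("model not trained (no trackers)")
        k = self.n_dims
        N = self.sigma_yf.n_total
        scale_ps = self.scale.value / N       # E[y_raw^2] per dimension
        Y = np.zeros((F.shape[0], 0))
        for n in range(k):
            if n == 0:
                Fn = F
            else:
                Syy = self.sigma_yy.value[:n, :n]
                B = np.linalg.solve(
                    Syy + JITTER * (np.trace(Syy) / n) * np.eye(n),
                    self.sigma_yf.value[:n, :])
                Fn = F - Y @ B
            y = Fn @ self.W.data[:, n]
            y = y / math.sqrt(max(scale_ps[n], NORM_EPS**2))
            Y = np.column_stack([Y, y])
        return Y

    # -- whitening ------------------------------------------------------
    def whiten_forward_train(self, F: Tensor, n_total: int,
                             method: str = "inverse_sqrt"):
        """Raw projected block (graph) plus its batch-whitened version
        (numpy; orthonormal columns), updating the Gram tracker."""
        b = F.shape[0]
        k = self.n_dims
        if b <= k:
            raise InvalidArgumentError(
                f"batch size {b} must exceed n_dims {k} for whitening")
        Y_t = F @ self.W
        Yd = Y_t.data
        Yw = whiten(Yd, mode="train", method=method)
        stat_yy = Yd.T @ Yd
        if self.sigma_yy is None:
            self.sigma_yy = init_tracker(stat_yy, n_total, b, self.rho)
        else:
            self.sigma_yy.update(stat_yy, b)
        return Y_t, Yw

    def whiten_forward_infer(self, F: np.ndarray,
                             method: str = "inverse_sqrt") -> np.ndarray:
        if self.sigma_yy is None:
            raise InvalidArgumentError("model not trained (no trackers)")
        Y = F @ self.W.data
        sigma_ps = self.sigma_yy.value / self.sigma_yy.n_total
        return whiten(Y, sigma_yy=sigma_ps, mode="infer", method=method)


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------

def build_linear(p: int, n_dims: int, rho: float = 0.95,
                 rng: np.random.Generator | None = None,
                 view_name: str = "",
                 use_confound_layer: bool = False) -> MeasurementModel:
    """Identity body with a trainable final projection only: the deep
    model reduces exactly to the classical linear objective."""
    spec = MeasurementModelSpec(kind="linear", input_dim=p, n_dims=n_dims,
                                use_confound_layer=use_confound_layer)
    rng = rng if rng is not None else np.random.default_rng(0)
    return MeasurementModel(spec, rho, rng, view_name)


def build_mlp(p: int, n_dims: int, hidden: int = 32, rho: float = 0.95,
              rng: np.random.Generator | None = None, view_name: str = "",
              use_confound_layer: bool = False,
              dropout: float = 0.0) -> MeasurementModel:
    spec = MeasurementModelSpec(kind="mlp", input_dim=p, n_dims=n_dims,
                                hidden=hidden, dropout=dropout,
                                use_confound_layer=use_confound_layer)
    rng = rng if rng is not None else np.random.default_rng(0)
    return MeasurementModel(spec, rho, rng, view_name)


def build_omics(p: int, n_dims: int,
                spec: MeasurementModelSpec | None = None,
                rho: float = 0.95,
                rng: np.random.Generator | None = None,
                view_name: str = "") -> MeasurementModel:
    """The omics architecture: sqrt-width embedding, self-attention with a
    residual merge, dropout 0.5 and L1 = L2 = 0.01 penalties by default."""
    if spec is None:
        spec = MeasurementModelSpec(kind="omics_attention", input_dim=p,
                                    n_dims=n_dims, dropout=0.5,
                                    l1=0.01, l2=0.01)
    rng = rng if rng is not None else np.random.default_rng(0)
    return MeasurementModel(spec, rho, rng, view_name)
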