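"""Orthogonalizing building blocks for deep latent variable path models.

Four operations, each with distinct train/inference behaviour:

``batch_standardize``
    Feature standardization using batch statistics during training (with
    momentum-tracked moving mean/std for inference), as in batch
    normalization without the learned affine map.

``deflate``
    Residualization of penultimate-layer features against previously
    extracted latent variables.  Because extracted DLVs are orthonormal on
    the batch, the least-squares projection collapses to
    ``F - Y_prev (Y_prev^T F)``.  At inference the projection coefficients
    come from momentum-tracked covariance matrices instead.

``whiten``
    Joint orthonormalization of a DLV block by the inverse square root of
    its Gram matrix (symmetric eigendecomposition route by default, with a
    faster Cholesky alternative spanning the same column space).

``remove_confounds``
    Least-squares projection of features out of the span of nuisance
    covariates (Moore-Penrose pseudo-inverse).  Because every layer after
    this one is linear, downstream outputs are exactly orthogonal to the
    confounds on the training batch.

Functional numpy forms are the public surface; the ``*Layer`` classes wrap
the same math around the autodiff engine for use inside training loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._autodiff import Tensor, constant
from .covariance import (
    CovarianceTracker,
    InvalidArgumentError,
    MovingStats,
    NumericDegeneracyError,
    init_tracker,
)

JITTER = 1e-6
BN_EPS = 1e-8
NORM_EPS = 1e-8

__all__ = [
    "DLVBlock",
    "ConfoundBlock",
    "batch_standardize",
    "deflate",
    "whiten",
    "remove_confounds",
    "inv_sqrt_sym",
    "dlv_gradient_cross_products",
]


@dataclass
class DLVBlock:
    """An N x n_dims matrix of deep latent variables for one view.

    Columns are ordered by extraction index; for the iterative variant the
    order is meaningful (components are ranked by association strength).
    """

    values: np.ndarray
    view_name: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] < 1:
            raise InvalidArgumentError("DLVBlock needs at least one column")

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfoundBlock:
    """An N x D_c matrix of nuisance covariates with column names."""

    values: np.ndarray
    names: list

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise InvalidArgumentError("confound names do not match columns")
        if self.values.shape[1] < 1:
            raise InvalidArgumentError("need at least one confound column")
        dead = [n for n, c in zip(self.names, self.values.T)
                if np.allclose(c, 0.0)]
        if dead:
            raise InvalidArgumentError(
                f"constant-zero confound columns: {dead}")


# ----------------------------------------------------------------------
# linear algebra helpers
# ----------------------------------------------------------------------

def _jitter_eye(S: np.ndarray, eps: float) -> np.ndarray:
    """Scale-relative jitter: eps times the mean diagonal magnitude."""
    scale = float(np.trace(S)) / S.shape[0]
    if not np.isfinite(scale) or scale <= 0.0:
        raise NumericDegeneracyError(
            "matrix not positive definite after jitter")
    return eps * scale * np.eye(S.shape[0])


def inv_sqrt_sym(S: np.ndarray, eps: float = JITTER) -> np.ndarray:
    """Symmetric inverse square root of an SPD matrix, with relative
    jitter."""
    S = np.asarray(S, dtype=float)
    S = 0.5 * (S + S.T) + _jitter_eye(S, eps)
    w, V = np.linalg.eigh(S)
    if w.min() <= 0:
        raise NumericDegeneracyError(
            "matrix not positive definite after jitter")
    return (V * (1.0 / np.sqrt(w))) @ V.T


def _solve_spd(S: np.ndarray, B: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    S = 0.5 * (S + S.T) + _jitter_eye(S, eps)
    try:
        return scipy.linalg.solve(S, B, assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise NumericDegeneracyError(str(err)) from err


# ----------------------------------------------------------------------
# functional operations
# ----------------------------------------------------------------------

def batch_standardize(F: np.ndarray, stats: MovingStats,
                      mode: str = "train") -> np.ndarray:
    """Standardize features by batch statistics (train) or moving stats
    (infer).  Train mode updates ``stats`` with momentum."""
    F = np.asarray(F, dtype=float)
    if mode == "train":
        if F.shape[0] < 2:
            raise InvalidArgumentError("train-mode standardization needs b >= 2")
        mu = F.mean(axis=0)
        var = F.var(axis=0)
        if np.any(var == 0):
            bad = np.flatnonzero(var == 0)
            raise NumericDegeneracyError(
                f"zero batch variance in columns {bad.tolist()}")
        stats.update(mu, var)
        return (F - mu) / np.sqrt(var + BN_EPS)
    if not stats.initialized:
        raise InvalidArgumentError("moving stats not initialized for inference")
    return (F - stats.mean) / stats.std


def deflate(F: np.ndarray, Y_prev: np.ndarray,
            sigma_yf: np.ndarray | None = None,
            mode: str = "train") -> np.ndarray:
    """Residualize features against previously extracted DLVs.

    Train mode assumes ``Y_prev`` has orthonormal columns on the batch and
    uses the simplified projection ``F - Y_prev (Y_prev^T F)``.  Inference
    mode applies externally supplied regression coefficients ``sigma_yf``
    (rows: previous dimensions), as estimated by a covariance tracker.
    With no previous dimensions the features pass through unchanged.
    """
    F = np.asarray(F, dtype=float)
    Y_prev = np.asarray(Y_prev, dtype=float)
    if Y_prev.ndim == 1:
        Y_prev = Y_prev[:, None]
    if Y_prev.shape[1] == 0:
        return F
    if mode == "train":
        return F - Y_prev @ (Y_prev.T @ F)
    if sigma_yf is None:
        raise InvalidArgumentError("inference deflation requires sigma_yf")
    return F - Y_prev @ np.asarray(sigma_yf, dtype=float)


def whiten(Y: np.ndarray, sigma_yy: np.ndarray | None = None,
           mode: str = "train", method: str = "inverse_sqrt",
           eps: float = JITTER) -> np.ndarray:
    """Orthonormalize the columns of a DLV block.

    Train mode whitens with the batch Gram matrix ``Y^T Y`` so that
    ``out^T out = I``; inference mode uses the supplied (tracker-estimated)
    covariance ``sigma_yy`` so the transform is deterministic.  The
    ``cholesky`` method is an equivalent faster factorization spanning the
    same column space.
    """
    Y = np.asarray(Y, dtype=float)
    b, k = Y.shape
    if mode == "train":
        if b <= k:
            raise InvalidArgumentError(
                f"whitening needs batch size > n_dims ({b} <= {k})")
        S = Y.T @ Y
    else:
        if sigma_yy is None:
            raise InvalidArgumentError("inference whitening requires sigma_yy")
        S = np.asarray(sigma_yy, dtype=float)
    if method == "inverse_sqrt":
        return Y @ inv_sqrt_sym(S, eps)
    if method == "cholesky":
        S = 0.5 * (S + S.T) + _jitter_eye(S, eps)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as err:
            raise NumericDegeneracyError(
                "matrix not positive definite after jitter") from err
        return scipy.linalg.solve_triangular(L, Y.T, lower=True).T
    raise InvalidArgumentError(f"unknown whitening method {method!r}")


def remove_confounds(F: np.ndarray, Cb: np.ndarray,
                     cc: CovarianceTracker | None = None,
                     cf: CovarianceTracker | None = None,
                     mode: str = "train",
                     names: list | None = None) -> np.ndarray:
    """Project features out of the span of the confound columns.

    Train mode solves the batch least-squares problem
    ``F - Cb (Cb^T Cb)^{-1} Cb^T F`` (and the caller updates trackers);
    inference mode uses global tracker values ``F - Cb Scc^{-1} Scf``.
    """
    F = np.asarray(F, dtype=float)
    Cb = np.atleast_2d(np.asarray(Cb, dtype=float))
    if mode == "train":
        b, dc = Cb.shape
        if b <= dc:
            raise InvalidArgumentError(
                f"confound removal needs batch size > D_c ({b} <= {dc})")
        _check_confound_rank(Cb, names)
        beta = _solve_spd(Cb.T @ Cb, Cb.T @ F)
        return F - Cb @ beta
    if cc is None or cf is None:
        raise InvalidArgumentError(
            "inference confound removal requires initialized trackers")
    beta = _solve_spd(cc.value, cf.value)
    return F - Cb @ beta


def _check_confound_rank(Cb: np.ndarray, names: list | None = None) -> None:
    """Raise with the offending column names if the batch confounds are
    rank deficient."""
    _, R, piv = scipy.linalg.qr(Cb, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Cb.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > max(tol, 1e-10)).sum())
    if rank < Cb.shape[1]:
        bad = sorted(piv[rank:].tolist())
        labels = [names[j] if names else j for j in bad]
        raise NumericDegeneracyError(
            f"rank-deficient batch confounds; offending columns: {labels}")


def dlv_gradient_cross_products(F: np.ndarray, W: np.ndarray,
                                targets: np.ndarray) -> np.ndarray:
    """Pairwise inner products of per-dimension loss gradients.

    For the iterative variant the loss for dimension ``n`` regresses the
    deflated projection ``(F | Y^{n-1}) w^n`` onto the connected view's
    ``n``-th DLV; its gradient with respect to ``w^n`` is
    ``-(F | Y^{n-1})^T r^n`` with ``r^n`` the regression residual.  Returns
    the matrix of inner products ``<g_n, g_m>`` (diagonal: squared norms).
    Under batch-wise deflation these are exactly zero off the diagonal when
    the batch features are row-whitened and the target DLVs are aligned
    with the view's own.
    """
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    targets = np.asarray(targets, dtype=float)
    k = W.shape[1]
    grads = []
    Yhat = np.zeros((F.shape[0], 0))
    for n in range(k):
        Fn = deflate(F, Yhat, mode="train")
        y = Fn @ W[:, n]
        r = targets[:, n] - y
        grads.append(-Fn.T @ r)
        Yhat = np.column_stack([Yhat, y / (np.linalg.norm(y) + NORM_EPS)])
    G = np.array(grads)
    return G @ G.T


# ----------------------------------------------------------------------
# stateful layers over the autodiff engine
# ----------------------------------------------------------------------

class BatchStandardizeLayer:
    """Batch standardization with moving statistics (no learned affine)."""

    def __init__(self, rho: float):
        self.stats = MovingStats(rho=rho)

    def forward_train(self, F: Tensor) -> Tensor:
        var_np = F.data.var(axis=0)
        if np.any(var_np == 0):
            bad = np.flatnonzero(var_np == 0)
            raise NumericDegeneracyError(
                f"zero batch variance in columns {bad.tolist()}")
        self.stats.update(F.data.mean(axis=0), var_np)
        mu = F.mean(axis=0, keepdims=True)
        centred = F - mu
        var = (centred * centred).mean(axis=0, keepdims=True)
        return centred / (var + BN_EPS).sqrt()

    def forward_infer(self, F: np.ndarray) -> np.ndarray:
        return batch_standardize(F, self.stats, mode="infer")


class ConfoundLayer:
    """Batch-wise confound projection with momentum-tracked global
    covariances for inference."""

    def __init__(self, rho: float):
        self.rho = rho
        self.cc: CovarianceTracker | None = None
        self.cf: CovarianceTracker | None = None

    @property
    def initialized(self) -> bool:
        return self.cc is not None and self.cf is not None

    def forward_train(self, F: Tensor, Cb: np.ndarray, n_total: int,
                      names: list | None = None) -> Tensor:
        Cb = np.atleast_2d(np.asarray(Cb, dtype=float))
        b = Cb.shape[0]
        if b <= Cb.shape[1]:
            raise InvalidArgumentError(
                f"confound removal needs batch size > D_c "
                f"({b} <= {Cb.shape[1]})")
        _check_confound_rank(Cb, names)
        # projection is linear in F: out = (I - Cb (Cb^T Cb)^-1 Cb^T) F
        pinv = _solve_spd(Cb.T @ Cb, Cb.T)
        proj = np.eye(b) - Cb @ pinv
        out = constant(proj) @ F
        stat_cc = Cb.T @ Cb
        stat_cf = Cb.T @ F.data
        if not self.initialized:
            self.cc = init_tracker(stat_cc, n_total, b, self.rho)
            self.cf = init_tracker(stat_cf, n_total, b, self.rho)
        else:
            self.cc.update(stat_cc, b)
            self.cf.update(stat_cf, b)
        return out

    def forward_infer(self, F: np.ndarray, Cb: np.ndarray) -> np.ndarray:
        if not self.initialized:
            raise InvalidArgumentError("confound trackers not initialized")
        return remove_confounds(F, Cb, cc=self.cc, cf=self.cf, mode="infer")


class DropoutLayer:
    """Inverted dropout: active in training only."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise InvalidArgumentError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward_train(self, F: Tensor, rng: np.random.Generator) -> Tensor:
        if self.rate == 0.0:
            return F
        mask = (rng.random(F.shape) >= self.rate) / (1.0 - self.rate)
        return F * constant(mask)


def deflate_t(F: Tensor, Y_prev: np.ndarray) -> Tensor:
    """Graph-mode deflation against detached orthonormal previous DLVs."""
    if Y_prev.shape[1] == 0:
        return F
    return F - constant(Y_prev) @ (constant(Y_prev.T) @ F)
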