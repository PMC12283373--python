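"""Classical linear references: eigen-based CCA and mode-B PLS path
modelling.

Both serve as user-facing baselines and as oracles for the deep model's
linear limit.  The CCA solver follows the standard eigendecomposition
route (regularized with a small jitter); the PLS path model uses the
identity-metric ("mode B") weight update that replaces within-view
covariance matrices with identity, so it remains defined when features
outnumber samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .covariance import InvalidArgumentError, NumericDegeneracyError
from .data import ViewData
from .layers import JITTER, NORM_EPS, inv_sqrt_sym
from .path import PathSpec

logger = logging.getLogger(__name__)

__all__ = ["LinearPathFit", "cca_oracle", "plspm_mode_b_fit"]


@dataclass
class LinearPathFit:
    """Weights, latent scores and per-dimension correlations of a linear
    two-or-more-view fit."""

    weights: list                       # per view, p_i x n_dims, unit columns
    scores: list                        # per view, N x n_dims, unit columns
    correlations: np.ndarray            # per dimension (mean over edges)
    mu: list = field(default_factory=list)
    sd: list = field(default_factory=list)
    deflation: list = field(default_factory=list)   # PLS-PM replay state
    weight_scales: list = field(default_factory=list)
    converged: bool = True

    def transform(self, Xs: list) -> list:
        """Apply the fitted weights to new data (standardized with the
        training statistics), replaying per-dimension deflation when the
        fit used it."""
        Xs = [np.asarray(X, dtype=float) for X in Xs]
        Zs = [(X - m) / s for X, m, s in zip(Xs, self.mu, self.sd)]
        if not self.deflation:
            return [Z @ W for Z, W in zip(Zs, self.weights)]
        out = [np.zeros((Z.shape[0], self.weights[i].shape[1]))
               for i, Z in enumerate(Zs)]
        R = [Z.copy() for Z in Zs]
        for d in range(self.weights[0].shape[1]):
            for i in range(len(R)):
                # rescale to the training latent's unit-norm scale so the
                # deflation coefficients replay consistently
                y = R[i] @ self.weights[i][:, d] / self.weight_scales[i][d]
                out[i][:, d] = y
                beta = self.deflation[i][d]        # row: y -> features
                R[i] = R[i] - np.outer(y, beta)
        return out


def _standardize(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise NumericDegeneracyError("constant feature column")
    return (X - mu) / sd, mu, sd


def cca_oracle(X1, X2, n_dims: int, reg: float = JITTER) -> LinearPathFit:
    """Canonical correlation analysis via symmetric eigendecomposition.

    Maximizes ``tr((X1 W1)^T X2 W2)`` subject to each view's variates
    being orthonormal; returns canonical correlations in non-increasing
    order.  Within-view covariance inverses are regularized with ``reg``
    jitter.
    """
    Z1, mu1, sd1 = _standardize(X1)
    Z2, mu2, sd2 = _standardize(X2)
    N, p1 = Z1.shape
    p2 = Z2.shape[1]
    if N <= max(p1, p2):
        raise InvalidArgumentError(
            f"CCA needs N > max(p1, p2); got N={N}, p=({p1}, {p2})")
    if n_dims > min(p1, p2):
        raise InvalidArgumentError(
            f"n_dims {n_dims} exceeds min(p1, p2) = {min(p1, p2)}")
    S11 = Z1.T @ Z1 / N
    S22 = Z2.T @ Z2 / N
    S12 = Z1.T @ Z2 / N
    R1 = inv_sqrt_sym(S11, reg)
    R2 = inv_sqrt_sym(S22, reg)
    U, svals, Vt = np.linalg.svd(R1 @ S12 @ R2)
    W1 = R1 @ U[:, :n_dims]
    W2 = R2 @ Vt.T[:, :n_dims]
    scores = []
    for Z, W in ((Z1, W1), (Z2, W2)):
        Y = Z @ W
        Y = Y / (np.linalg.norm(Y, axis=0, keepdims=True) + NORM_EPS)
        scores.append(Y)
    return LinearPathFit(weights=[W1, W2], scores=scores,
                         correlations=svals[:n_dims],
                         mu=[mu1, mu2], sd=[sd1, sd2])


def plspm_mode_b_fit(views, path: PathSpec, n_dims: int = 1,
                     max_iter: int = 500, tol: float = 1e-8) -> LinearPathFit:
    """Mode-B PLS path modelling by alternating weight updates.

    Per dimension: each view's weight vector is re-estimated against the
    sum of connected views' current unit-norm latents with the within-view
    covariance replaced by identity (``w_i <- X_i^T t_i``, normalized),
    iterated to convergence.  Successive dimensions deflate each view's
    features against its accepted latents, mirroring the deflation used by
    the deep model's iterative variant.
    """
    Xs = [v.matrix if isinstance(v, ViewData) else np.asarray(v, float)
          for v in views]
    Zs, mus, sds = [], [], []
    for X in Xs:
        Z, mu, sd = _standardize(X)
        Zs.append(Z)
        mus.append(mu)
        sds.append(sd)
    K = len(Zs)
    if K != path.K:
        raise InvalidArgumentError(f"{K} views for a {path.K}-view path")
    N = Zs[0].shape[0]
    R = [Z.copy() for Z in Zs]
    weights = [np.zeros((Z.shape[1], n_dims)) for Z in Zs]
    scores = [np.zeros((N, n_dims)) for _ in Zs]
    deflation = [[] for _ in Zs]
    weight_scales = [np.zeros(n_dims) for _ in Zs]
    corrs = np.zeros(n_dims)
    converged = True
    edges = path.edges()
    for d in range(n_dims):
        ws = [np.ones(Z.shape[1]) / np.sqrt(Z.shape[1]) for Z in R]
        ys = [R[i] @ ws[i] for i in range(K)]
        ys = [y / (np.linalg.norm(y) + NORM_EPS) for y in ys]
        ok = False
        for it in range(max_iter):
            delta = 0.0
            for i in range(K):
                nbrs = path.neighbours(i)
                t = np.sum([ys[j] for j in nbrs], axis=0)
                w_new = R[i].T @ t
                nrm = np.linalg.norm(w_new)
                if nrm < NORM_EPS:
                    raise NumericDegeneracyError(
                        f"degenerate weight update in view {i}")
                w_new = w_new / nrm
                y_new = R[i] @ w_new
                y_new = y_new / (np.linalg.norm(y_new) + NORM_EPS)
                delta = max(delta, float(np.abs(y_new - ys[i]).max()))
                ys[i], ws[i] = y_new, w_new
            if delta < tol:
                ok = True
                break
        if not ok:
            converged = False
            logger.warning("PLS-PM dimension %d: no convergence after %d "
                           "iterations (last delta %.2e); using best "
                           "iterate", d + 1, max_iter, delta)
        for i in range(K):
            weights[i][:, d] = ws[i]
            weight_scales[i][d] = np.linalg.norm(R[i] @ ws[i]) + NORM_EPS
            scores[i][:, d] = ys[i]
            beta = ys[i] @ R[i]              # unit-norm y regression row
            deflation[i].append(beta)
            R[i] = R[i] - np.outer(ys[i], beta)
        corrs[d] = np.mean([ys[i] @ ys[j] for (i, j) in edges])
    return LinearPathFit(weights=weights, scores=scores, correlations=corrs,
                         mu=mus, sd=sds, deflation=deflation,
                         weight_scales=weight_scales, converged=converged)
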