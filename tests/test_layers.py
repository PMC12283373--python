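"""The orthogonalizing layers: standardization, deflation, whitening and
confound removal, each against explicit least-squares/eigen oracles."""

import numpy as np
import pytest

from dlvpm import (InvalidArgumentError, MovingStats, NumericDegeneracyError,
                   batch_standardize, deflate, dlv_gradient_cross_products,
                   remove_confounds, whiten)
from dlvpm.covariance import CovarianceTracker, init_tracker
from dlvpm.layers import ConfoundBlock, inv_sqrt_sym

RNG = np.random.default_rng(0)


def lstsq_residual(F, D):
    """Explicit normal-equations oracle: residual of each F column after
    regression on the design D."""
    beta, *_ = np.linalg.lstsq(D, F, rcond=None)
    return F - D @ beta


# ---------------------------------------------------------------- standardize
def test_batch_standardize_train_centres_and_scales():
    F = RNG.standard_normal((64, 3)) * 2.0 + 5.0
    st = MovingStats(rho=0.95)
    out = batch_standardize(F, st, mode="train")
    assert np.allclose(out.mean(0), 0, atol=1e-12)
    assert np.allclose(out.std(0), 1, atol=1e-3)
    assert st.initialized


def test_batch_standardize_infer_identity_with_unit_stats():
    st = MovingStats(rho=0.95)
    st.mean, st.std, st.initialized = np.zeros(3), np.ones(3), True
    F = RNG.standard_normal((10, 3))
    assert np.allclose(batch_standardize(F, st, mode="infer"), F)


def test_batch_standardize_two_batches_momentum():
    st = MovingStats(rho=0.95)
    F1 = np.array([[1.0, 2.0], [3.0, 6.0]])
    F2 = np.array([[5.0, 0.0], [9.0, 2.0]])
    batch_standardize(F1, st, mode="train")
    batch_standardize(F2, st, mode="train")
    m1, m2 = F1.mean(0), F2.mean(0)
    assert np.allclose(st.mean, 0.95 * m1 + 0.05 * m2)


def test_batch_standardize_constant_column_errors():
    F = np.column_stack([np.ones(8), RNG.standard_normal(8)])
    with pytest.raises(NumericDegeneracyError):
        batch_standardize(F, MovingStats(rho=0.95), mode="train")


# ------------------------------------------------------------------- deflate
def test_deflate_empty_previous_block_passes_through():
    F = RNG.standard_normal((8, 4))
    assert np.array_equal(deflate(F, np.zeros((8, 0)), mode="train"), F)


def test_deflate_orthogonal_features_unchanged():
    y = np.zeros(8); y[0] = 1.0
    F = np.zeros((8, 3)); F[1:, :] = RNG.standard_normal((7, 3))
    out = deflate(F, y[:, None], mode="train")
    assert np.allclose(out, F)


@pytest.mark.parametrize("seed", range(20))
def test_deflate_matches_least_squares_oracle(seed):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((8, 3))
    Y = np.linalg.qr(rng.standard_normal((8, 1)))[0]
    out = deflate(F, Y, mode="train")
    assert np.allclose(out, lstsq_residual(F, Y), atol=1e-10)
    assert np.abs(Y.T @ out).max() < 1e-6 * 8


def test_deflate_infer_uses_supplied_coefficients():
    F = RNG.standard_normal((6, 3))
    Y = RNG.standard_normal((6, 2))
    B = RNG.standard_normal((2, 3))
    assert np.allclose(deflate(F, Y, sigma_yf=B, mode="infer"), F - Y @ B)


# -------------------------------------------------------------------- whiten
def test_whiten_orthonormal_input_is_identity():
    Y = np.linalg.qr(RNG.standard_normal((32, 4)))[0]
    assert np.allclose(whiten(Y, mode="train"), Y, atol=1e-4)
    assert np.allclose(whiten(2.0 * Y, mode="train"), Y, atol=1e-4)


@pytest.mark.parametrize("method", ["inverse_sqrt", "cholesky"])
def test_whiten_output_orthonormal(method):
    Y = RNG.standard_normal((64, 4))
    out = whiten(Y, mode="train", method=method, eps=1e-12)
    assert np.abs(out.T @ out - np.eye(4)).max() < 1e-6


def test_whiten_methods_span_identical_column_space():
    Y = RNG.standard_normal((64, 4))
    A = whiten(Y, mode="train", method="inverse_sqrt", eps=1e-12)
    B = whiten(Y, mode="train", method="cholesky", eps=1e-12)
    # projection distance between the two column spaces
    PA, PB = A @ A.T, B @ B.T
    assert np.abs(PA - PB).max() < 1e-6


def test_whiten_against_eigendecomposition_oracle():
    Y = RNG.standard_normal((64, 4))
    S = Y.T @ Y
    w, V = np.linalg.eigh(S)
    oracle = Y @ (V * (1 / np.sqrt(w))) @ V.T
    assert np.allclose(whiten(Y, mode="train", eps=0.0), oracle, atol=1e-8)


def test_whiten_rejects_small_batch_and_singular():
    with pytest.raises(InvalidArgumentError):
        whiten(RNG.standard_normal((3, 4)), mode="train")
    Y = np.zeros((16, 3))
    with pytest.raises(NumericDegeneracyError):
        whiten(Y, sigma_yy=np.zeros((3, 3)), mode="infer", eps=0.0)


def test_inv_sqrt_sym_inverts_square():
    S = RNG.standard_normal((4, 4))
    S = S @ S.T + 4 * np.eye(4)
    R = inv_sqrt_sym(S, eps=0.0)
    assert np.allclose(R @ S @ R, np.eye(4), atol=1e-10)


# ---------------------------------------------------------- confound removal
def test_remove_confounds_intercept_only_demeans():
    F = RNG.standard_normal((16, 4)) + 3.0
    Cb = np.ones((16, 1))
    out = remove_confounds(F, Cb, mode="train")
    assert np.allclose(out, F - F.mean(0), atol=1e-10)


def test_remove_confounds_orthogonal_confound_is_noop():
    Cb = np.zeros((8, 1)); Cb[0] = 1.0
    F = np.zeros((8, 3)); F[1:] = RNG.standard_normal((7, 3))
    assert np.allclose(remove_confounds(F, Cb, mode="train"), F)


@pytest.mark.parametrize("seed", range(20))
def test_remove_confounds_matches_least_squares_oracle(seed):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((32, 5))
    Cb = rng.standard_normal((32, 2))
    out = remove_confounds(F, Cb, mode="train")
    assert np.allclose(out, lstsq_residual(F, Cb), atol=1e-8)
    assert np.abs(Cb.T @ out).max() < 1e-6 * 32


def test_remove_confounds_rank_deficiency_names_columns():
    c = RNG.standard_normal(16)
    Cb = np.column_stack([c, 2 * c, RNG.standard_normal(16)])
    with pytest.raises(NumericDegeneracyError, match="offending"):
        remove_confounds(F=RNG.standard_normal((16, 3)), Cb=Cb, mode="train",
                         names=["a", "a_x2", "b"])


def test_remove_confounds_infer_uses_trackers():
    rng = np.random.default_rng(5)
    F = rng.standard_normal((200, 4))
    Cb = rng.standard_normal((200, 2))
    cc = init_tracker(Cb.T @ Cb, 200, 200, rho=0.95)
    cf = init_tracker(Cb.T @ F, 200, 200, rho=0.95)
    out = remove_confounds(F, Cb, cc=cc, cf=cf, mode="infer")
    assert np.abs(Cb.T @ out).max() < 1e-6 * 200


def test_confound_block_validation():
    with pytest.raises(InvalidArgumentError):
        ConfoundBlock(np.zeros((5, 1)), ["dead"])
    with pytest.raises(InvalidArgumentError):
        ConfoundBlock(np.ones((5, 2)), ["only_one_name"])


# ------------------------------------------------- gradient orthogonality
def test_gradient_orthogonality_in_whitened_aligned_regime():
    """Per-dimension loss gradients under batch-wise deflation are exactly
    orthogonal when the batch features are row-whitened and the target
    DLVs coincide with the view's own (the regime in which both displayed
    orthogonality conditions of the scheme hold)."""
    rng = np.random.default_rng(11)
    b, d, k = 16, 40, 3
    F = np.linalg.qr(rng.standard_normal((d, b)))[0].T   # orthonormal rows
    W = rng.standard_normal((d, k))
    # targets: the view's own orthonormalized DLVs (aligned two-view limit)
    Yhat = np.zeros((b, 0))
    for n in range(k):
        Fn = F - Yhat @ (Yhat.T @ F)
        y = Fn @ W[:, n]
        Yhat = np.column_stack([Yhat, y / np.linalg.norm(y)])
    G = dlv_gradient_cross_products(F, W, Yhat)
    norms = np.sqrt(np.diag(G))
    for n in range(k):
        for m in range(n + 1, k):
            assert abs(G[n, m]) < 1e-6 * norms[n] * norms[m]


def test_gradient_orthogonality_fails_without_whitening():
    """With generic (non-whitened) batch features the same inner products
    are far from zero, confirming the condition is load-bearing."""
    rng = np.random.default_rng(12)
    b, d, k = 32, 10, 3
    F = rng.standard_normal((b, d))
    F = (F - F.mean(0)) / F.std(0)
    W = rng.standard_normal((d, k))
    T = np.linalg.qr(rng.standard_normal((b, k)))[0]
    G = dlv_gradient_cross_products(F, W, T)
    norms = np.sqrt(np.diag(G))
    rel = max(abs(G[n, m]) / (norms[n] * norms[m])
              for n in range(k) for m in range(n + 1, k))
    assert rel > 1e-3
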