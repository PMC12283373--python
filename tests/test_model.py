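"""The path model: loss, fitting, transform, association matrices."""

import numpy as np
import pytest

from dlvpm import (DLVPM, InvalidArgumentError, NumericDegeneracyError,
                   SimSpec, TrainConfig, ViewData, association_matrices,
                   dlvpm_loss_view, generate_multiview, split_views,
                   validate_path_spec)
from tests.conftest import LINEAR_CONFIG

RNG = np.random.default_rng(0)


# ---------------------------------------------------------------- loss
def test_loss_zero_for_identical_blocks():
    Y = RNG.standard_normal((20, 3))
    assert dlvpm_loss_view(Y, [Y], [1.0]) == pytest.approx(0.0)


def test_loss_zero_with_no_edges():
    Y = RNG.standard_normal((20, 3))
    Z = RNG.standard_normal((20, 3))
    assert dlvpm_loss_view(Y, [Z], [0.0]) == pytest.approx(0.0)


def test_loss_equals_one_minus_correlation_for_unit_columns():
    """Half squared distance of centred unit-norm columns is 1 - r; with
    r = 0 the single-dimension loss is exactly 1."""
    a = np.zeros(4); a[0], a[1] = 1, -1
    b = np.zeros(4); b[2], b[3] = 1, -1
    a /= np.linalg.norm(a); b /= np.linalg.norm(b)
    assert dlvpm_loss_view(a[:, None], [b[:, None]], [1.0]) == pytest.approx(1.0)
    # general identity on random centred data
    Y = RNG.standard_normal((50, 2)); Y -= Y.mean(0)
    Z = RNG.standard_normal((50, 2)); Z -= Z.mean(0)
    r = [np.corrcoef(Y[:, n], Z[:, n])[0, 1] for n in range(2)]
    assert dlvpm_loss_view(Y, [Z], [1.0]) == pytest.approx(2 - sum(r), abs=1e-6)


def test_loss_edge_length_mismatch():
    Y = RNG.standard_normal((10, 2))
    with pytest.raises(InvalidArgumentError):
        dlvpm_loss_view(Y, [Y], [1.0, 1.0])


# ---------------------------------------------------------------- fitting
def test_fit_rejects_misaligned_samples():
    v1 = ViewData(RNG.standard_normal((10, 3)), [f"S{i}" for i in range(10)],
                  list("abc"), "v1")
    v2 = ViewData(RNG.standard_normal((10, 3)), [f"T{i}" for i in range(10)],
                  list("abc"), "v2")
    with pytest.raises(InvalidArgumentError, match="offending"):
        DLVPM([v1, v2], [[0, 1], [1, 0]])


def test_fit_rejects_small_batch():
    spec = SimSpec(K=2, N=60, p=[6, 6], n_latents=2, spectrum=(0.9, 0.5),
                   seed=0)
    views, _, _ = generate_multiview(spec)
    model = DLVPM(views, [[0, 1], [1, 0]], n_dims=4)
    with pytest.raises(InvalidArgumentError):
        model.fit(TrainConfig(batch_size=4, epochs=1))


def test_null_data_gives_no_spurious_correlation():
    """With zero cross-view signal the held-out mean correlation is small."""
    spec = SimSpec(K=2, N=900, p=[8, 8], n_latents=2, spectrum=(0.0, 0.0),
                   seed=3)
    views, _, _ = generate_multiview(spec)
    (tr, _), (te, _) = split_views(views, 600)
    model = DLVPM(tr, [[0, 1], [1, 0]], n_dims=2)
    res = model.fit(TrainConfig(batch_size=64, epochs=60, lr_initial=1e-2,
                                lr_decay="exponential", seed=0))
    assert np.abs(res.cross_view_correlations(te)).mean() < 0.1


def test_iterative_ranking_on_stated_spectrum():
    """The iterative variant ranks DLVs by association strength."""
    spec = SimSpec(K=2, N=600, p=[10, 10], n_latents=3,
                   spectrum=(0.9, 0.6, 0.3), seed=5)
    views, _, _ = generate_multiview(spec)
    model = DLVPM(views, [[0, 1], [1, 0]], variant="iterative", n_dims=3)
    res = model.fit(TrainConfig(**LINEAR_CONFIG))
    r = res.cross_view_correlations()
    assert np.all(np.diff(r) <= 1e-6)
    from dlvpm import cca_oracle
    cca = cca_oracle(views[0].matrix, views[1].matrix, 3)
    assert abs(r[0] - cca.correlations[0]) < 0.05


def test_transform_is_deterministic_and_rowwise(fitted_linear, two_view_linear):
    res = fitted_linear["iterative"]
    te = two_view_linear["test"]
    b1 = res.transform(te)
    b2 = res.transform(te)
    for a, b in zip(b1, b2):
        assert np.array_equal(a.values, b.values)
    # permuted sample order in -> permuted rows out
    perm = np.random.default_rng(0).permutation(te[0].n_samples)
    bp = res.transform([v.take(perm) for v in te])
    for a, b in zip(b1, bp):
        assert np.allclose(a.values[perm], b.values, atol=1e-10)


def test_transform_matches_training_representation(fitted_linear):
    """Inference on the training data reproduces the orthogonalized
    training DLVs (global vs batch statistics)."""
    res = fitted_linear["iterative"]
    blocks = res.transform()
    model = res.model
    # compare with a fresh full-batch train-mode forward at final weights
    import copy
    for i, blk in enumerate(blocks):
        mm = copy.deepcopy(model.measurement_models[i])
        F = mm.features_train(model.views[i].matrix, None, model.N,
                              np.random.default_rng(0), stochastic=False)
        _, Yhat = mm.iterative_forward_train(F, model.N)
        for n in range(model.n_dims):
            r = abs(np.corrcoef(Yhat[:, n], blk.values[:, n])[0, 1])
            assert r > 0.95


def test_variants_agree_on_subspace(fitted_linear, two_view_linear):
    """Iterative and whitening variants span the same held-out DLV
    subspace (principal-angle cosines > 0.9)."""
    te = two_view_linear["test"]
    A = fitted_linear["iterative"].transform(te)
    B = fitted_linear["whiten"].transform(te)
    for a, b in zip(A, B):
        Qa = np.linalg.qr(a.values - a.values.mean(0))[0]
        Qb = np.linalg.qr(b.values - b.values.mean(0))[0]
        cosines = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
        assert cosines.min() > 0.9


def test_history_records_progress(fitted_linear):
    h = fitted_linear["iterative"].history
    assert {"epoch", "mean_cross_corr", "loss"} <= set(h.columns)
    assert h["mean_cross_corr"].iloc[-1] > h["mean_cross_corr"].iloc[0]


def test_summary_mentions_views_and_dimensions(fitted_linear):
    s = fitted_linear["iterative"].summary()
    assert "DLV 1" in s and "view0" in s and "iterative" in s


# ------------------------------------------------------- association report
def test_association_identical_blocks():
    Y = RNG.standard_normal((60, 2))
    path = validate_path_spec([[0, 1], [1, 0]])
    rep = association_matrices([Y, Y.copy()], path, n_perm=199, seed=0)
    for n in range(2):
        assert rep.correlations[n][0, 1] == pytest.approx(1.0)
        assert rep.p_values[n][0, 1] == pytest.approx(1 / 200)
        assert np.allclose(rep.correlations[n], rep.correlations[n].T)


def test_association_null_calibration():
    """Independent Gaussian blocks: each dimension's adjusted p stays
    above 0.05 in at least 90% of tests."""
    path = validate_path_spec([[0, 1], [1, 0]])
    ok = total = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        rep = association_matrices(
            [rng.standard_normal((200, 2)), rng.standard_normal((200, 2))],
            path, n_perm=199, seed=seed)
        for n in range(2):
            ok += int(rep.p_values[n][0, 1] > 0.05)
            total += 1
    assert ok / total >= 0.9


def test_association_constant_column_error():
    Y = RNG.standard_normal((50, 2))
    Z = Y.copy(); Z[:, 1] = 3.0
    path = validate_path_spec([[0, 1], [1, 0]])
    with pytest.raises(NumericDegeneracyError):
        association_matrices([Y, Z], path, n_perm=199, seed=0)
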