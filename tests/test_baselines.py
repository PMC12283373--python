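"""Classical CCA and mode-B PLS path modelling."""

import numpy as np
import pytest

from dlvpm import (InvalidArgumentError, SimSpec, ViewData, cca_oracle,
                   generate_multiview, plspm_mode_b_fit, validate_path_spec)

RNG = np.random.default_rng(0)


def test_cca_identical_views_perfect_correlation():
    X = RNG.standard_normal((200, 5))
    fit = cca_oracle(X, X.copy(), n_dims=3)
    assert np.allclose(fit.correlations, 1.0, atol=1e-6)


def test_cca_independent_views_near_zero():
    rng = np.random.default_rng(1)
    fit = cca_oracle(rng.standard_normal((2000, 5)),
                     rng.standard_normal((2000, 5)), n_dims=5)
    assert fit.correlations.max() < 0.15


def test_cca_correlations_non_increasing_and_scores_orthonormal():
    spec = SimSpec(K=2, N=400, p=[6, 6], n_latents=2, spectrum=(0.8, 0.4),
                   seed=2)
    views, _, _ = generate_multiview(spec)
    fit = cca_oracle(views[0].matrix, views[1].matrix, n_dims=3)
    assert np.all(np.diff(fit.correlations) <= 1e-10)
    for Y in fit.scores:
        assert np.abs(Y.T @ Y - np.eye(3)).max() < 1e-6


def test_cca_one_dimension_matches_grid_search_oracle():
    """p=2: exhaustive search over unit weight vectors reproduces the
    leading canonical correlation."""
    rng = np.random.default_rng(3)
    z = rng.standard_normal(300)
    X1 = np.column_stack([z + rng.standard_normal(300),
                          rng.standard_normal(300)])
    X2 = np.column_stack([rng.standard_normal(300),
                          z + rng.standard_normal(300)])
    fit = cca_oracle(X1, X2, n_dims=1, reg=1e-10)
    theta = np.linspace(0, np.pi, 720, endpoint=False)
    W = np.column_stack([np.cos(theta), np.sin(theta)])   # unit vectors

    def scores(X):
        Z = (X - X.mean(0)) / X.std(0)
        S = Z @ W.T
        return (S - S.mean(0)) / S.std(0)

    S1, S2 = scores(X1), scores(X2)
    grid_best = np.abs(S1.T @ S2 / 300).max()
    assert fit.correlations[0] == pytest.approx(grid_best, abs=1e-3)


def test_cca_invariant_to_invertible_reparameterization():
    spec = SimSpec(K=2, N=500, p=[5, 5], n_latents=2, spectrum=(0.7, 0.3),
                   seed=4)
    views, _, _ = generate_multiview(spec)
    X1, X2 = views[0].matrix, views[1].matrix
    A = RNG.standard_normal((5, 5)) + 3 * np.eye(5)     # invertible
    f1 = cca_oracle(X1, X2, n_dims=2, reg=1e-10)
    f2 = cca_oracle(X1 @ A, X2, n_dims=2, reg=1e-10)
    assert np.allclose(f1.correlations, f2.correlations, atol=1e-6)


def test_cca_preconditions():
    with pytest.raises(InvalidArgumentError):
        cca_oracle(RNG.standard_normal((5, 6)), RNG.standard_normal((5, 3)), 2)
    with pytest.raises(InvalidArgumentError):
        cca_oracle(RNG.standard_normal((50, 3)), RNG.standard_normal((50, 3)), 4)


# -------------------------------------------------------------------- PLS-PM
def _as_views(mats):
    ids = [f"S{i}" for i in range(mats[0].shape[0])]
    return [ViewData(M, ids, [f"f{j}" for j in range(M.shape[1])], f"v{k}")
            for k, M in enumerate(mats)]


def test_plspm_single_feature_views_recover_feature():
    rng = np.random.default_rng(5)
    z = rng.standard_normal(100)
    views = _as_views([np.column_stack([z + 0.1 * rng.standard_normal(100)]),
                       np.column_stack([z + 0.1 * rng.standard_normal(100)])])
    path = validate_path_spec([[0, 1], [1, 0]])
    fit = plspm_mode_b_fit(views, path, n_dims=1)
    for i in range(2):
        assert abs(abs(fit.weights[i][0, 0]) - 1.0) < 1e-9
        r = np.corrcoef(fit.scores[i][:, 0], views[i].matrix[:, 0])[0, 1]
        assert abs(r) > 0.999999


def test_plspm_agrees_with_cca_on_linear_data():
    """Cross-method consistency: dimension-1 correlation within 0.05 of
    the eigen oracle on linear synthetic data."""
    spec = SimSpec(K=2, N=500, p=[8, 8], n_latents=2, spectrum=(0.8, 0.4),
                   seed=6)
    views, _, _ = generate_multiview(spec)
    path = validate_path_spec([[0, 1], [1, 0]])
    pls = plspm_mode_b_fit(views, path, n_dims=1)
    cca = cca_oracle(views[0].matrix, views[1].matrix, n_dims=1)
    assert abs(pls.correlations[0] - cca.correlations[0]) < 0.05


def test_plspm_three_view_chain_runs():
    spec = SimSpec(K=3, N=400, p=[6, 6, 6], n_latents=2, spectrum=(0.8, 0.3),
                   adjacency=[[0, 1, 0], [1, 0, 1], [0, 1, 0]], seed=7)
    views, _, _ = generate_multiview(spec)
    fit = plspm_mode_b_fit(views, spec.adjacency, n_dims=2)
    assert fit.correlations[0] > 0.5
    assert fit.converged


def test_plspm_transform_consistent_with_training_scores():
    spec = SimSpec(K=2, N=400, p=[6, 6], n_latents=2, spectrum=(0.8, 0.4),
                   seed=8)
    views, _, _ = generate_multiview(spec)
    path = validate_path_spec([[0, 1], [1, 0]])
    fit = plspm_mode_b_fit(views, path, n_dims=2)
    replay = fit.transform([v.matrix for v in views])
    for i in range(2):
        for d in range(2):
            r = np.corrcoef(replay[i][:, d], fit.scores[i][:, d])[0, 1]
            assert r > 0.999999
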