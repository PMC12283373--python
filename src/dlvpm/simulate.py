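"""Synthetic multi-view data with known latent structure.

The generator emulates the statistical structure a latent variable path
model assumes: a set of shared Gaussian factors propagated along the
adjacency graph.  For each latent dimension ``n`` with target cross-view
correlation ``rho_n``, every view in a connected component of the graph
receives ``z_i = sqrt(rho_n) * g + sqrt(1 - rho_n) * e_i`` where ``g`` is
the component-wide shared factor and ``e_i`` view-specific noise, so any
two connected views' latents correlate at ``rho_n``.  Views in different
components share nothing.

Latents are mixed into observed features linearly, quadratically, or
through a random two-layer map, plus additive Gaussian noise and optional
additive confound effects.  In the quadratic regime, even-indexed views mix
linearly while odd-indexed views expose only centred squares and pairwise
products of their latents: the cross-view dependence is then invisible to
any linear projection (odd moments vanish) but recoverable by a nonlinear
measurement model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import InvalidArgumentError
from .data import ViewData
from .layers import ConfoundBlock
from .path import PathSpec, validate_path_spec

__all__ = ["SimSpec", "SyntheticTruth", "generate_multiview", "split_views",
           "generate_factor_view"]


def generate_factor_view(seed: int = 0, N: int = 1000,
                         groups: tuple = (24, 16, 10),
                         feat_noise: float = 0.5,
                         noise_features: int = 15,
                         view_name: str = "omics"):
    """Single-view data with block latent-factor structure.

    Each latent factor loads on its own block of features (``groups``
    gives the block sizes; unequal sizes give the factors distinct
    strengths, which makes ranked components identifiable); a final block
    of pure-noise features carries no signal.  Used as the testbed for the
    single-view (twins) representation model.  Returns ``(view, latents)``.
    """
    rng = np.random.default_rng(seed)
    k = len(groups)
    z = rng.standard_normal((N, k))
    cols = [z[:, [j]] + feat_noise * rng.standard_normal((N, g))
            for j, g in enumerate(groups)]
    cols.append(rng.standard_normal((N, noise_features)))
    X = np.hstack(cols)
    ids = [f"S{i:05d}" for i in range(N)]
    view = ViewData(X, ids, [f"f{j}" for j in range(X.shape[1])], view_name)
    return view, z


@dataclass
class SimSpec:
    """Configuration of one synthetic multi-view dataset."""

    K: int = 2
    N: int = 500
    p: list = field(default_factory=lambda: [10, 10])
    adjacency: object = None          # default: fully connected
    n_latents: int = 3
    spectrum: tuple = (0.8, 0.5, 0.2)
    mixing: str = "linear"            # linear | quadratic | mlp-random
    noise_sd: float = 1.0
    confound_dim: int = 0
    confound_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.p) != self.K:
            raise InvalidArgumentError(
                f"{len(self.p)} feature counts for K={self.K} views")
        if self.mixing not in ("linear", "quadratic", "mlp-random"):
            raise InvalidArgumentError(f"unknown mixing {self.mixing!r}")
        spectrum = tuple(float(s) for s in self.spectrum)
        if len(spectrum) > self.n_latents:
            raise InvalidArgumentError(
                f"spectrum of length {len(spectrum)} for "
                f"{self.n_latents} latents")
        if len(spectrum) < self.n_latents:
            spectrum = spectrum + (0.0,) * (self.n_latents - len(spectrum))
        if any(not 0.0 <= s <= 1.0 for s in spectrum):
            raise InvalidArgumentError("spectrum entries must be in [0, 1]")
        if any(a < b for a, b in zip(spectrum, spectrum[1:])):
            raise InvalidArgumentError("spectrum must be non-increasing")
        self.spectrum = spectrum
        for pi in self.p:
            if pi <= self.n_latents:
                raise InvalidArgumentError(
                    "each view needs more features than latents")
        if self.adjacency is None:
            A = 1 - np.eye(self.K, dtype=int)
            self.adjacency = validate_path_spec(
                A, [f"view{i}" for i in range(self.K)])
        elif not isinstance(self.adjacency, PathSpec):
            self.adjacency = validate_path_spec(self.adjacency)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the observed views."""

    latents: list                # per view, N x n_latents
    shared: np.ndarray           # N x n_latents component-shared factors
    mixing_maps: list            # per view, mixing parameters
    confounds: np.ndarray | None
    confound_loadings: list | None
    components: list             # view index -> component label


def _components(path: PathSpec) -> list:
    """Connected-component label per view."""
    K = path.K
    labels = [-1] * K
    cur = 0
    for start in range(K):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = cur
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(path.adjacency[u]):
                if labels[v] == -1:
                    labels[v] = cur
                    stack.append(int(v))
        cur += 1
    return labels


def _quad_features(Z: np.ndarray) -> np.ndarray:
    """Centred pure-even functions of the latents: squares and pairwise
    products.  E[z] * these = 0 for Gaussian z, so no linear projection of
    them correlates with a linear function of the latents."""
    cols = [Z[:, a] * Z[:, b] - (1.0 if a == b else 0.0)
            for a in range(Z.shape[1]) for b in range(a, Z.shape[1])]
    return np.column_stack(cols)


def generate_multiview(spec: SimSpec):
    """Draw one dataset; returns ``(views, confounds_or_None, truth)``.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    path = spec.adjacency
    comp = _components(path)
    n_comp = max(comp) + 1
    L = spec.n_latents
    # one shared factor set per connected component
    shared_by_comp = [rng.standard_normal((spec.N, L)) for _ in range(n_comp)]
    sq = np.sqrt(np.asarray(spec.spectrum))
    cq = np.sqrt(1.0 - np.asarray(spec.spectrum))
    latents = []
    for i in range(spec.K):
        e = rng.standard_normal((spec.N, L))
        latents.append(shared_by_comp[comp[i]] * sq + e * cq)

    confounds = None
    loadings = None
    if spec.confound_dim > 0:
        U = rng.standard_normal((spec.N, spec.confound_dim))
        confounds = ConfoundBlock(
            U, [f"conf{j}" for j in range(spec.confound_dim)])
        loadings = []

    views, maps = [], []
    sample_ids = [f"S{i:05d}" for i in range(spec.N)]
    for i in range(spec.K):
        Z = latents[i]
        if spec.mixing == "linear" or (spec.mixing == "quadratic" and i % 2 == 0):
            A = rng.standard_normal((L, spec.p[i]))
            signal = Z @ A
            maps.append({"kind": "linear", "A": A})
        elif spec.mixing == "quadratic":
            Q = _quad_features(Z)
            A = rng.standard_normal((Q.shape[1], spec.p[i]))
            signal = Q @ A
            maps.append({"kind": "quadratic", "A": A})
        else:  # mlp-random
            h = max(2 * L, 8)
            W1 = rng.standard_normal((L, h))
            W2 = rng.standard_normal((h, spec.p[i]))
            signal = np.tanh(Z @ W1) @ W2
            maps.append({"kind": "mlp", "W1": W1, "W2": W2})
        signal = signal / signal.std(axis=0)
        X = signal + spec.noise_sd * rng.standard_normal((spec.N, spec.p[i]))
        if confounds is not None and spec.confound_effect > 0:
            Li = rng.standard_normal((spec.confound_dim, spec.p[i]))
            Li /= np.linalg.norm(Li, axis=0, keepdims=True)
            X = X + spec.confound_effect * confounds.values @ Li
            loadings.append(Li)
        views.append(ViewData(
            X, sample_ids, [f"f{i}_{j}" for j in range(spec.p[i])],
            path.view_names[i]))

    truth = SyntheticTruth(latents=latents,
                           shared=np.column_stack(
                               [shared_by_comp[comp[0]]])[:, :L],
                           mixing_maps=maps,
                           confounds=confounds.values if confounds else None,
                           confound_loadings=loadings,
                           components=comp)
    return views, confounds, truth


def split_views(views, n_train: int, confounds: ConfoundBlock | None = None,
                truth: SyntheticTruth | None = None):
    """Deterministic head/tail train-test split of aligned views."""
    N = views[0].n_samples
    if not 0 < n_train < N:
        raise InvalidArgumentError(f"n_train must be in (0, {N})")
    tr = np.arange(n_train)
    te = np.arange(n_train, N)
    train = [v.take(tr) for v in views]
    test = [v.take(te) for v in views]
    ctr = cte = None
    if confounds is not None:
        ctr = ConfoundBlock(confounds.values[tr], confounds.names)
        cte = ConfoundBlock(confounds.values[te], confounds.names)
    if truth is None:
        return (train, ctr), (test, cte)
    ttr = SyntheticTruth([z[tr] for z in truth.latents], truth.shared[tr],
                         truth.mixing_maps,
                         truth.confounds[tr] if truth.confounds is not None else None,
                         truth.confound_loadings, truth.components)
    tte = SyntheticTruth([z[te] for z in truth.latents], truth.shared[te],
                         truth.mixing_maps,
                         truth.confounds[te] if truth.confounds is not None else None,
                         truth.confound_loadings, truth.components)
    return (train, ctr, ttr), (test, cte, tte)
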