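"""Deep latent variable path modelling: model and results objects.

A :class:`DLVPM` model couples K data views through a user-specified binary
adjacency matrix (the structural model).  Each view's measurement model
produces ``n_dims`` deep latent variables (DLVs) that are trained to
correlate maximally with the DLVs of connected views while remaining
mutually orthogonal within each view.

Training follows an iterative least-squares scheme: per mini-batch, all
views are forward-propagated first; then each view in turn regresses its
raw (deflated or pre-whitened) projections onto the connected views'
orthonormalized DLVs, treated as constants, and takes one optimizer step.
Orthogonalization is enforced batch-wise during training (deflation or
whitening), while momentum-tracked global covariance matrices reproduce the
transform deterministically at inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, constant
from .covariance import InvalidArgumentError, NumericDegeneracyError, DEFAULT_RHO
from .data import ConfoundBlock, ViewData
from .layers import DLVBlock, NORM_EPS
from .measurement import MeasurementModel, MeasurementModelSpec
from .path import PathSpec, validate_path_spec

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "DLVPM",
    "DLVPMResults",
    "AssociationReport",
    "dlvpm_loss_view",
    "association_matrices",
    "tune_grid",
]


@dataclass
class TrainConfig:
    """Optimization settings for one training run."""

    batch_size: int = 64
    epochs: int = 100
    lr_initial: float = 1e-3
    lr_decay: str = "none"          # none | exponential (to lr_initial/10)
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.lr_initial <= 0:
            raise InvalidArgumentError("lr_initial must be positive")
        if self.lr_decay not in ("none", "exponential"):
            raise InvalidArgumentError(f"unknown lr_decay {self.lr_decay!r}")
        if self.optimizer != "adam":
            raise InvalidArgumentError("only the adam optimizer is supported")


def dlvpm_loss_view(y_self, targets, edges) -> float:
    """Squared-difference association loss for one view.

    ``sum_j c_ij * 0.5 * || norm(Y_self) - norm(Y_j) ||_F^2`` with each
    column scaled to unit norm; for centred columns this equals
    ``sum_j c_ij * sum_n (1 - corr(y_self^n, y_j^n))``.
    """
    ys = y_self.values if isinstance(y_self, DLVBlock) else np.asarray(y_self)
    edges = np.asarray(edges, dtype=float)
    if len(edges) != len(targets):
        raise InvalidArgumentError(
            f"{len(edges)} edge weights for {len(targets)} target blocks")

    def _norm(Y):
        Y = Y.values if isinstance(Y, DLVBlock) else np.asarray(Y, dtype=float)
        return Y / (np.linalg.norm(Y, axis=0, keepdims=True) + NORM_EPS)

    a = _norm(ys)
    total = 0.0
    for c, tgt in zip(edges, targets):
        if c == 0:
            continue
        total += c * 0.5 * np.sum((a - _norm(tgt)) ** 2)
    return float(total)


class DLVPM:
    """Deep latent variable path model over K aligned data views.

    Parameters
    ----------
    views : list of ViewData
        Sample-aligned feature matrices (identical sample_ids in identical
        order; misalignment raises with the offending ids).  Features are
        standardized internally using statistics of these data; NaNs are
        imputed to zero (the mean) after standardization.
    path : PathSpec or array
        Binary adjacency matrix declaring which view pairs correlate.
    measurement_specs : list of MeasurementModelSpec, optional
        Per-view architecture; default is a linear model per view.
    variant : {"iterative", "whiten"}
        Orthogonalization scheme.  The iterative variant ranks DLVs by
        association strength; whitening orthonormalizes jointly.
    confounds : ConfoundBlock, optional
        Nuisance covariates removed inside every view that enables
        ``use_confound_layer`` (enabled for all views when confounds are
        supplied and specs do not say otherwise).
    """

    def __init__(self, views, path, measurement_specs=None,
                 variant: str = "iterative", n_dims: int = 5,
                 confounds: ConfoundBlock | None = None,
                 rho: float = DEFAULT_RHO,
                 whiten_method: str = "inverse_sqrt"):
        if variant not in ("iterative", "whiten"):
            raise InvalidArgumentError(f"unknown variant {variant!r}")
        if not isinstance(path, PathSpec):
            path = validate_path_spec(path)
        if len(views) != path.K:
            raise InvalidArgumentError(
                f"{len(views)} views for a {path.K}-view path model")
        ref_ids = views[0].sample_ids
        for v in views[1:]:
            if v.sample_ids != ref_ids:
                bad = sorted(set(v.sample_ids) ^ set(ref_ids))[:10]
                raise InvalidArgumentError(
                    f"views are not sample-aligned; offending ids include "
                    f"{bad} (use align_views first)")
        if confounds is not None and confounds.values.shape[0] != len(ref_ids):
            raise InvalidArgumentError("confound rows do not match samples")
        self.path = path
        self.variant = variant
        self.n_dims = int(n_dims)
        self.rho = float(rho)
        self.whiten_method = whiten_method
        self.confounds = confounds
        self.sample_ids = list(ref_ids)
        if measurement_specs is None:
            measurement_specs = [
                MeasurementModelSpec(
                    kind="linear", input_dim=v.n_features, n_dims=self.n_dims,
                    use_confound_layer=confounds is not None)
                for v in views]
        for spec in measurement_specs:
            if spec.n_dims != self.n_dims:
                raise InvalidArgumentError(
                    "all views must share n_dims with the model")
        self.measurement_specs = measurement_specs
        # per-view feature standardization parameters (train statistics)
        self._mu, self._sd = [], []
        self.views = []
        for v in views:
            mu = np.nanmean(v.matrix, axis=0)
            sd = np.nanstd(v.matrix, axis=0)
            if np.any(sd == 0) or np.any(~np.isfinite(sd)):
                bad = [v.feature_names[j] for j in
                       np.flatnonzero((sd == 0) | ~np.isfinite(sd))][:5]
                raise InvalidArgumentError(
                    f"constant features in view {v.view_name!r}: {bad}")
            self._mu.append(mu)
            self._sd.append(sd)
            X = np.nan_to_num((v.matrix - mu) / sd, nan=0.0)
            n_nan = int(np.isnan(v.matrix).sum())
            if n_nan:
                logger.info("view %s: %d NaNs imputed to 0 after "
                            "standardization", v.view_name, n_nan)
            self.views.append(ViewData(X, v.sample_ids, v.feature_names,
                                       v.view_name, standardized=True))
        self.measurement_models: list[MeasurementModel] | None = None

    # ------------------------------------------------------------------
    @property
    def K(self) -> int:
        return self.path.K

    @property
    def N(self) -> int:
        return len(self.sample_ids)

    def _standardize_new(self, views) -> list[np.ndarray]:
        out = []
        for i, v in enumerate(views):
            X = v.matrix if isinstance(v, ViewData) else np.asarray(v, float)
            if X.shape[1] != self._mu[i].shape[0]:
                raise InvalidArgumentError(
                    f"view {i} has {X.shape[1]} features, model expects "
                    f"{self._mu[i].shape[0]}")
            out.append(np.nan_to_num((X - self._mu[i]) / self._sd[i], nan=0.0))
        return out

    # ------------------------------------------------------------------
    def fit(self, config: TrainConfig | None = None) -> "DLVPMResults":
        """Train all measurement models; returns a results object."""
        config = config or TrainConfig()
        K, N, k = self.K, self.N, self.n_dims
        dc = self.confounds.values.shape[1] if self.confounds is not None else 0
        min_batch = max(k + 1, dc + 1)
        if config.batch_size <= max(k, dc):
            raise InvalidArgumentError(
                f"batch_size {config.batch_size} must exceed "
                f"max(n_dims, D_c) = {max(k, dc)}")
        ss = np.random.SeedSequence(config.seed)
        rng_init, rng_shuffle, rng_drop = [
            np.random.default_rng(s) for s in ss.spawn(3)]
        self.measurement_models = [
            MeasurementModel(spec, self.rho, rng_init, v.view_name)
            for spec, v in zip(self.measurement_specs, self.views)]
        n_batches = max(1, N // config.batch_size)
        total_steps = config.epochs * n_batches
        opts = []
        for mm in self.measurement_models:
            lr_final = (config.lr_initial / 10
                        if config.lr_decay == "exponential" else None)
            opts.append(Adam(mm.params(), lr=config.lr_initial,
                             lr_final=lr_final, decay_steps=total_steps))
        Xs = [v.matrix for v in self.views]
        Cfull = self.confounds.values if self.confounds is not None else None
        cnames = self.confounds.names if self.confounds is not None else None
        history = []
        for epoch in range(config.epochs):
            perm = rng_shuffle.permutation(N)
            epoch_corr, epoch_loss, n_seen = 0.0, 0.0, 0
            for start in range(0, N, config.batch_size):
                idx = perm[start:start + config.batch_size]
                if len(idx) < min_batch:
                    continue  # ragged final batch dropped
                b = len(idx)
                Cb = Cfull[idx] if Cfull is not None else None
                raw, targets = [], []
                for i, mm in enumerate(self.measurement_models):
                    F = mm.features_train(Xs[i][idx], Cb, N, rng_drop, cnames)
                    if self.variant == "iterative":
                        ys_raw, Yhat = mm.iterative_forward_train(F, N)
                        raw.append(ys_raw)
                        targets.append(Yhat)
                    else:
                        Y_t, Yw = mm.whiten_forward_train(
                            F, N, self.whiten_method)
                        raw.append(Y_t)
                        targets.append(Yw)
                for i, mm in enumerate(self.measurement_models):
                    nbrs = self.path.neighbours(i)
                    loss_t = None
                    for j in nbrs:
                        if self.variant == "iterative":
                            for n in range(k):
                                diff = constant(
                                    targets[j][:, n:n + 1]) - raw[i][n]
                                term = 0.5 * (diff * diff).sum()
                                loss_t = term if loss_t is None else loss_t + term
                        else:
                            diff = constant(targets[j]) - raw[i]
                            term = 0.5 * (diff * diff).sum()
                            loss_t = term if loss_t is None else loss_t + term
                    if loss_t is None:
                        continue  # isolated view: nothing to optimize
                    pen = mm.penalty()
                    if pen is not None:
                        loss_t = loss_t + pen
                    if not np.isfinite(loss_t.data):
                        raise NumericDegeneracyError(
                            f"non-finite loss in view {mm.view_name!r} at "
                            f"epoch {epoch}; lower the learning rate or "
                            "check the inputs")
                    opts[i].zero_grad()
                    loss_t.backward()
                    opts[i].step()
                    epoch_loss += float(loss_t.data)
                # batch mean cross-view correlation over edges and dims
                cc = []
                for (i, j) in self.path.edges():
                    ti, tj = targets[i], targets[j]
                    ti = ti - ti.mean(0)
                    tj = tj - tj.mean(0)
                    ti /= np.linalg.norm(ti, axis=0) + NORM_EPS
                    tj /= np.linalg.norm(tj, axis=0) + NORM_EPS
                    cc.append(np.abs((ti * tj).sum(0)).mean())
                epoch_corr += float(np.mean(cc)) * b
                n_seen += b
            history.append({
                "epoch": epoch,
                "mean_cross_corr": epoch_corr / max(n_seen, 1),
                "loss": epoch_loss / max(n_seen, 1)})
        self._finalize_statistics(Xs, Cfull, cnames, rng_drop)
        hist = pd.DataFrame(history)
        results = DLVPMResults(self, hist)
        results._finalize()
        return results

    def _finalize_statistics(self, Xs, Cfull, cnames, rng) -> None:
        """Replace the momentum-tracked statistics with their exact
        full-training-sample values at the converged weights.

        The momentum trackers blend statistics from earlier batches, when
        the weights still differed; one deterministic full-sample
        train-mode pass (dropout disabled) gives the quantities they
        estimate without that staleness, so inference-time
        orthogonalization and confound removal use the best available
        global estimates.
        """
        N = self.N
        for i, mm in enumerate(self.measurement_models):
            mm.reset_statistics()
            F = mm.features_train(Xs[i], Cfull, N, rng, cnames,
                                  stochastic=False)
            if self.variant == "iterative":
                mm.iterative_forward_train(F, N)
            else:
                mm.whiten_forward_train(F, N, self.whiten_method)

    # ------------------------------------------------------------------
    def _transform_arrays(self, Xs_std: list[np.ndarray],
                          Cb: np.ndarray | None) -> list[np.ndarray]:
        out = []
        for i, mm in enumerate(self.measurement_models):
            F = mm.features_infer(Xs_std[i], Cb)
            if self.variant == "iterative":
                Y = mm.iterative_forward_infer(F)
            else:
                Y = mm.whiten_forward_infer(F, self.whiten_method)
            out.append(Y)
        return out


@dataclass
class AssociationReport:
    """Per-dimension pairwise DLV correlations with permutation
    significance (FWER-adjusted by the max statistic across tested
    pairs)."""

    correlations: list          # n_dims matrices, K x K, unit diagonal
    p_values: list              # n_dims matrices, K x K, diagonal 1.0
    view_names: list
    n_perm: int
    seed: int

    def to_frames(self):
        frames = []
        for n, (r, p) in enumerate(zip(self.correlations, self.p_values)):
            frames.append((
                pd.DataFrame(r, index=self.view_names, columns=self.view_names),
                pd.DataFrame(p, index=self.view_names, columns=self.view_names)))
        return frames


def association_matrices(dlvs, path: PathSpec, n_perm: int = 1000,
                         seed: int = 0) -> AssociationReport:
    """Pairwise Pearson correlations between views' nth DLVs with a
    max-statistic permutation FWER adjustment.

    The null permutes the sample rows of the first block of each pair
    (one shared permutation per draw, preserving within-view structure);
    the per-dimension adjustment takes the max |r| over all tested pairs.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    blocks = [d.values if isinstance(d, DLVBlock) else np.asarray(d, float)
              for d in dlvs]
    K = len(blocks)
    Nn = blocks[0].shape[0]
    k = blocks[0].shape[1]
    for bkk in blocks:
        if bkk.shape != (Nn, k):
            raise InvalidArgumentError("DLV blocks are not aligned")
        if np.any(bkk.std(axis=0) == 0):
            raise NumericDegeneracyError(
                "constant DLV column: correlation undefined")
    Z = [(bk - bk.mean(0)) / bk.std(0) for bk in blocks]
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    rng = np.random.default_rng(seed)
    corrs = [np.eye(K) for _ in range(k)]
    pvals = [np.ones((K, K)) for _ in range(k)]
    r_obs = np.zeros((len(pairs), k))
    for e, (i, j) in enumerate(pairs):
        r = (Z[i] * Z[j]).mean(0)
        r_obs[e] = r
        for n in range(k):
            corrs[n][i, j] = corrs[n][j, i] = r[n]
    # permutation null: shared row permutation applied to the first block
    max_null = np.zeros((n_perm, k))
    for b in range(n_perm):
        pi = rng.permutation(Nn)
        m = np.zeros(k)
        for (i, j) in pairs:
            m = np.maximum(m, np.abs((Z[i][pi] * Z[j]).mean(0)))
        max_null[b] = m
    for e, (i, j) in enumerate(pairs):
        for n in range(k):
            p = (1.0 + np.sum(max_null[:, n] >= abs(r_obs[e, n]))) / (1.0 + n_perm)
            pvals[n][i, j] = pvals[n][j, i] = p
    return AssociationReport(corrs, pvals, list(path.view_names),
                             n_perm, seed)


class DLVPMResults:
    """Fitted DLVPM model: latent variables, diagnostics, reports."""

    def __init__(self, model: DLVPM, history: pd.DataFrame):
        self.model = model
        self.history = history
        self._signs = [np.ones(model.n_dims) for _ in range(model.K)]
        self._rotations = [np.eye(model.n_dims) for _ in range(model.K)]

    # ------------------------------------------------------------------
    def _finalize(self):
        """Resolve the orthogonal indeterminacies left by training.

        Whitening variant: the objective is invariant to applying one
        shared orthogonal rotation to every view's DLVs, so the fitted
        coordinates are an arbitrary basis of the association subspace.
        An alternating Procrustes pass estimates per-view rotations that
        diagonalize the cross-view correlation structure on the training
        data, and dimensions are then ordered by decreasing mean
        cross-view correlation (the analogue of the iterative variant's
        built-in ranking).  Signs: each view's nth DLV is flipped so its
        summed covariance with connected views' nth DLVs is positive
        (the first view anchors the convention).
        """
        model = self.model
        raw = model._transform_arrays(
            [v.matrix for v in model.views],
            model.confounds.values if model.confounds is not None else None)
        K, k = model.K, model.n_dims
        Nn = raw[0].shape[0]
        if model.variant == "whiten" and k > 1:
            Z = [(Y - Y.mean(0)) / (Y.std(0) + NORM_EPS) for Y in raw]
            C = {}
            for i in range(K):
                for j in model.path.neighbours(i):
                    C[(i, j)] = Z[i].T @ Z[j] / Nn
            # reference view: diagonalize the summed squared cross-
            # correlation (its eigenvector order ranks the dimensions)
            degrees = model.path.adjacency.sum(axis=1)
            ref = int(np.argmax(degrees))
            M = sum(C[(ref, j)] @ C[(ref, j)].T
                    for j in model.path.neighbours(ref))
            w, V = np.linalg.eigh(M)
            R = [np.eye(k) for _ in range(K)]
            R[ref] = V[:, np.argsort(-w)]
            # align remaining views to already-aligned neighbours (BFS)
            aligned = {ref}
            frontier = [ref]
            while frontier:
                nxt = []
                for i in frontier:
                    for j in model.path.neighbours(i):
                        j = int(j)
                        if j in aligned:
                            continue
                        M = sum(C[(j, u)] @ R[u]
                                for u in model.path.neighbours(j)
                                if int(u) in aligned)
                        U, _, Vt = np.linalg.svd(M)
                        R[j] = U @ Vt
                        aligned.add(j)
                        nxt.append(j)
                frontier = nxt
            self._rotations = R
            raw = [Y @ Ri for Y, Ri in zip(raw, self._rotations)]
        signs = [np.ones(k) for _ in range(K)]
        for i in range(1, K):
            nbrs = [j for j in model.path.neighbours(i)]
            if not nbrs:
                continue
            for n in range(k):
                s = sum(np.cov(raw[i][:, n] * signs[i][n],
                               raw[j][:, n] * signs[j][n])[0, 1]
                        for j in nbrs)
                if s < 0:
                    signs[i][n] = -1.0
        self._signs = signs

    # ------------------------------------------------------------------
    def transform(self, views=None, confounds=None) -> list[DLVBlock]:
        """Deterministic DLVs using global moving statistics and trackers.

        With no arguments, transforms the training views.  Output columns
        have unit per-sample variance (up to tracker estimation error).
        """
        model = self.model
        if model.measurement_models is None:
            raise InvalidArgumentError("model is not fitted")
        if views is None:
            Xs = [v.matrix for v in model.views]
            names = [v.view_name for v in model.views]
        else:
            Xs = model._standardize_new(views)
            names = [getattr(v, "view_name", f"view{i}")
                     for i, v in enumerate(views)]
        if confounds is None and views is None:
            Cb = (model.confounds.values
                  if model.confounds is not None else None)
        else:
            Cb = confounds.values if confounds is not None else None
        ys = model._transform_arrays(Xs, Cb)
        return [DLVBlock((y @ R) * s, name)
                for y, R, s, name in zip(ys, self._rotations, self._signs,
                                         names)]

    def association_report(self, views=None, confounds=None,
                           n_perm: int = 1000, seed: int = 0) -> AssociationReport:
        dlvs = self.transform(views, confounds)
        return association_matrices(dlvs, self.model.path, n_perm, seed)

    def cross_view_correlations(self, views=None, confounds=None) -> np.ndarray:
        """Mean Pearson r per dimension over path-connected view pairs."""
        dlvs = self.transform(views, confounds)
        k = self.model.n_dims
        out = np.zeros(k)
        edges = self.model.path.edges()
        for n in range(k):
            rs = [np.corrcoef(dlvs[i].values[:, n], dlvs[j].values[:, n])[0, 1]
                  for (i, j) in edges]
            out[n] = np.mean(rs)
        return out

    def summary(self) -> str:
        model = self.model
        lines = [
            "Deep latent variable path model",
            "=" * 46,
            f"views: {', '.join(v.view_name or f'view{i}' for i, v in enumerate(model.views))}",
            f"variant: {model.variant}   n_dims: {model.n_dims}   "
            f"N: {model.N}   edges: {model.path.n_edges}",
            f"confounds: "
            f"{model.confounds.values.shape[1] if model.confounds is not None else 0}",
            "-" * 46,
        ]
        r = self.cross_view_correlations()
        lines.append("mean cross-view correlation per DLV (training data):")
        for n, v in enumerate(r):
            lines.append(f"  DLV {n + 1}: {v:+.3f}")
        if len(self.history):
            lines.append(f"final epoch mean batch correlation: "
                         f"{self.history['mean_cross_corr'].iloc[-1]:.3f}")
        return "\n".join(lines)


def tune_grid(views, path, measurement_specs=None, variant="iterative",
              n_dims: int = 5, confounds: ConfoundBlock | None = None,
              epochs: int = 50, batch_sizes=(32, 64, 128, 256),
              lrs=(1e-2, 1e-3, 1e-4), val_frac: float = 0.2,
              seed: int = 0):
    """Grid search over batch size and initial learning rate (each run
    decays exponentially to a tenth of the initial rate), selecting the
    combination with the highest validation mean cross-view correlation.

    Returns ``(best_config, records)`` where records is a DataFrame with
    one row per grid point.
    """
    rng = np.random.default_rng(seed)
    N = views[0].n_samples
    perm = rng.permutation(N)
    n_val = max(1, int(round(val_frac * N)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    records = []
    for bs in batch_sizes:
        for lr in lrs:
            cfg = TrainConfig(batch_size=bs, epochs=epochs, lr_initial=lr,
                              lr_decay="exponential", seed=seed)
            model = DLVPM([v.take(train_idx) for v in views], path,
                          measurement_specs=measurement_specs,
                          variant=variant, n_dims=n_dims,
                          confounds=(ConfoundBlock(
                              confounds.values[train_idx], confounds.names)
                              if confounds is not None else None))
            try:
                res = model.fit(cfg)
                val_conf = (ConfoundBlock(confounds.values[val_idx],
                                          confounds.names)
                            if confounds is not None else None)
                score = float(res.cross_view_correlations(
                    [v.take(val_idx) for v in views], val_conf).mean())
            except (InvalidArgumentError, NumericDegeneracyError) as err:
                logger.warning("grid point (bs=%d, lr=%g) failed: %s",
                               bs, lr, err)
                score = -np.inf
            records.append({"batch_size": bs, "lr_initial": lr,
                            "val_mean_corr": score})
    records = pd.DataFrame(records)
    best = records.loc[records["val_mean_corr"].idxmax()]
    best_cfg = TrainConfig(batch_size=int(best["batch_size"]), epochs=epochs,
                           lr_initial=float(best["lr_initial"]),
                           lr_decay="exponential", seed=seed)
    return best_cfg, records
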