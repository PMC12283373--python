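"""Momentum-tracked global covariance estimates from batch statistics.

Mini-batch training only ever sees a subset of the sample, but the
orthogonalization and confound-removal layers need *full-sample* covariance
matrices at inference time.  These are estimated online: the first batch
provides an initial estimate scaled up to the full-sample size, and each
subsequent batch is blended in with momentum ``rho``::

    Sigma <- rho * Sigma + (1 - rho) * (N / b_t) * Sigma_batch

where ``Sigma_batch`` is the raw (sum-scale) batch statistic, ``N`` the full
sample size and ``b_t`` the current batch size.  The default momentum of
0.95 trades stability of the running estimate against responsiveness to
parameter drift during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RHO = 0.95

__all__ = [
    "CovarianceTracker",
    "MovingStats",
    "init_tracker",
    "update_tracker",
    "InvalidArgumentError",
    "NumericDegeneracyError",
]


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


class NumericDegeneracyError(ArithmeticError):
    """Raised when an input is numerically degenerate (constant columns,
    singular matrices beyond jitter, ...)."""


@dataclass
class CovarianceTracker:
    """Running full-sample-scale estimate of a covariance matrix."""

    value: np.ndarray
    rho: float
    n_total: int
    initialized: bool = True

    def update(self, batch_stat: np.ndarray, b_t: int) -> "CovarianceTracker":
        update_tracker(self, batch_stat, b_t)
        return self

    def state(self) -> dict:
        return {"value": self.value, "rho": self.rho, "n_total": self.n_total}


def init_tracker(batch_stat: np.ndarray, n_total: int, b0: int,
                 rho: float = DEFAULT_RHO) -> CovarianceTracker:
    """Initialize a tracker from the first batch's statistic.

    The statistic is scaled by ``n_total / b0`` so that ``value`` estimates
    the statistic computed over the full sample.
    """
    if b0 < 1 or n_total < b0:
        raise InvalidArgumentError(
            f"need 1 <= b0 <= n_total, got b0={b0}, n_total={n_total}")
    if not (0.0 < rho <= 1.0):
        raise InvalidArgumentError(f"rho must be in (0, 1], got {rho}")
    batch_stat = np.asarray(batch_stat, dtype=float)
    value = (n_total / b0) * batch_stat
    return CovarianceTracker(value=value, rho=float(rho), n_total=int(n_total))


def update_tracker(t: CovarianceTracker, batch_stat: np.ndarray,
                   b_t: int) -> CovarianceTracker:
    """Momentum update ``value <- rho*value + (1-rho)*(N/b_t)*batch_stat``."""
    if not t.initialized:
        raise InvalidArgumentError("tracker is not initialized")
    batch_stat = np.asarray(batch_stat, dtype=float)
    if batch_stat.shape != t.value.shape:
        raise InvalidArgumentError(
            f"batch statistic shape {batch_stat.shape} does not match "
            f"tracker shape {t.value.shape}")
    if b_t < 1:
        raise InvalidArgumentError(f"batch size must be positive, got {b_t}")
    t.value = t.rho * t.value + (1.0 - t.rho) * (t.n_total / b_t) * batch_stat
    return t


@dataclass
class MovingStats:
    """Moving mean and standard deviation of penultimate-layer features.

    Initialized from the first training batch; later batches are blended in
    with momentum ``rho`` applied to the mean and to the standard deviation
    (not the variance), matching the update scheme of the training
    algorithm.
    """

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    rho: float = DEFAULT_RHO
    initialized: bool = field(default=False)

    @property
    def variance(self) -> np.ndarray:
        if self.std is None:
            raise InvalidArgumentError("moving stats are not initialized")
        return self.std**2

    def update(self, batch_mean: np.ndarray, batch_var: np.ndarray) -> None:
        batch_mean = np.asarray(batch_mean, dtype=float)
        batch_var = np.asarray(batch_var, dtype=float)
        if np.any(batch_var <= 0):
            raise NumericDegeneracyError(
                "zero batch variance: constant feature in training batch")
        batch_std = np.sqrt(batch_var)
        if not self.initialized:
            self.mean = batch_mean.copy()
            self.std = batch_std
            self.initialized = True
        else:
            self.mean = self.rho * self.mean + (1 - self.rho) * batch_mean
            self.std = self.rho * self.std + (1 - self.rho) * batch_std

    def state(self) -> dict:
        return {"mean": self.mean, "std": self.std, "rho": self.rho}
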