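"""The structural (path) model: a binary adjacency matrix over data views.

An entry ``c_ij = 1`` declares that the latent variables of views ``i`` and
``j`` are optimized to correlate; ``c_ij = 0`` leaves the pair unlinked.
Edges are association edges (undirected): asymmetric input is symmetrized
with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .covariance import InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = ["PathSpec", "validate_path_spec"]


@dataclass
class PathSpec:
    """K x K binary adjacency matrix plus view names."""

    adjacency: np.ndarray
    view_names: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    def neighbours(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


def validate_path_spec(adjacency, names: list | None = None) -> PathSpec:
    """Validate and normalize an adjacency matrix into a :class:`PathSpec`.

    Entries must be 0/1; the diagonal is zeroed and the matrix symmetrized
    (with warnings); isolated views are warned about.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidArgumentError(f"adjacency must be square, got {A.shape}")
    K = A.shape[0]
    if K < 2:
        raise InvalidArgumentError("path model needs at least two views")
    if names is None:
        names = [f"view{i}" for i in range(K)]
    if len(names) != K:
        raise InvalidArgumentError(
            f"{len(names)} view names for {K}x{K} adjacency")
    if len(set(names)) != K:
        raise InvalidArgumentError("view names must be unique")
    if not np.isin(A, (0.0, 1.0)).all():
        raise InvalidArgumentError("adjacency entries must be binary (0/1)")
    if np.any(np.diag(A) != 0):
        logger.warning("zeroing %d nonzero diagonal entries in adjacency",
                       int(np.count_nonzero(np.diag(A))))
        np.fill_diagonal(A, 0.0)
    if not np.array_equal(A, A.T):
        logger.warning("asymmetric adjacency symmetrized (edges are "
                       "association edges)")
        A = np.maximum(A, A.T)
    if A.sum() == 0:
        raise InvalidArgumentError("adjacency has no edges")
    isolated = [names[i] for i in range(K) if A[i].sum() == 0]
    if isolated:
        logger.warning("views with no edges in the path model: %s", isolated)
    return PathSpec(adjacency=A.astype(int), view_names=list(names))
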