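"""Data containers and I/O for sample-by-feature view matrices.

Views are TSV/CSV files with a sample-ID first column and a feature-name
header row.  Missing values (``NA``/``NaN`` tokens) are carried as NaN and
imputed to zero *after* standardization, i.e. to the feature mean, which is
the standard convention in multimodal integration pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import InvalidArgumentError
from .layers import ConfoundBlock

logger = logging.getLogger(__name__)

__all__ = [
    "ViewData",
    "ConfoundBlock",
    "load_view_matrix",
    "load_confounds",
    "align_views",
    "standardize_view",
    "variance_filter",
    "write_dlv_table",
    "read_dlv_table",
]


@dataclass
class ViewData:
    """An N x p_i matrix of features for one data view."""

    matrix: np.ndarray
    sample_ids: list
    feature_names: list
    view_name: str = ""
    standardized: bool = field(default=False)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, p = self.matrix.shape
        if len(self.sample_ids) != n:
            raise InvalidArgumentError(
                f"{len(self.sample_ids)} sample ids for {n} rows "
                f"in view {self.view_name!r}")
        if len(self.feature_names) != p:
            raise InvalidArgumentError(
                f"{len(self.feature_names)} feature names for {p} columns "
                f"in view {self.view_name!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def take(self, rows: np.ndarray) -> "ViewData":
        return ViewData(self.matrix[rows],
                        [self.sample_ids[i] for i in rows],
                        self.feature_names, self.view_name,
                        standardized=self.standardized)


def load_view_matrix(path, name: str = "") -> ViewData:
    """Read a TSV/CSV view matrix (sample-ID first column, feature header)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0,
                     na_values=["NA", "NaN", "nan", ""])
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise InvalidArgumentError(
            f"duplicate sample ids in {path}: {dupes}")
    bad = df.columns[~df.dtypes.map(
        lambda t: np.issubdtype(t, np.number))].tolist()
    if bad:
        for col in bad:
            raw = df[col]
            row = raw.index[[not _is_numeric_token(v) for v in raw]][:1].tolist()
            raise InvalidArgumentError(
                f"non-numeric cell in {path}, column {col!r}, row {row}")
    return ViewData(df.to_numpy(dtype=float), df.index.tolist(),
                    df.columns.tolist(), name or str(path))


def _is_numeric_token(v) -> bool:
    if isinstance(v, float) or isinstance(v, int):
        return True
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def load_confounds(path) -> tuple[ConfoundBlock, list]:
    """Read a confound TSV; returns the block and its sample ids."""
    vd = load_view_matrix(path, name="confounds")
    return ConfoundBlock(vd.matrix, vd.feature_names), vd.sample_ids


def align_views(views: list[ViewData],
                confounds: ConfoundBlock | None = None,
                confound_ids: list | None = None):
    """Intersect sample IDs across views (and confounds) and reorder all
    matrices identically.  Order follows the first view's file order."""
    if len(views) < 2:
        raise InvalidArgumentError("alignment needs at least two views")
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if confounds is not None:
        if confound_ids is None:
            raise InvalidArgumentError("confound sample ids required")
        common &= set(confound_ids)
    if not common:
        raise InvalidArgumentError("no common sample ids across views")
    order = [sid for sid in views[0].sample_ids if sid in common]
    aligned = []
    for v in views:
        dropped = v.n_samples - len(order)
        if dropped:
            logger.info("view %s: dropped %d samples during alignment",
                        v.view_name, dropped)
        pos = {sid: i for i, sid in enumerate(v.sample_ids)}
        aligned.append(v.take(np.array([pos[sid] for sid in order])))
    if confounds is None:
        return aligned, None
    cpos = {sid: i for i, sid in enumerate(confound_ids)}
    rows = np.array([cpos[sid] for sid in order])
    cb = ConfoundBlock(confounds.values[rows], confounds.names)
    return aligned, cb


def standardize_view(view: ViewData) -> ViewData:
    """Column-standardize a view; NaNs become 0 (the mean) afterwards."""
    X = view.matrix.copy()
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = [view.feature_names[j] for j in
               np.flatnonzero((sd == 0) | ~np.isfinite(sd))]
        raise InvalidArgumentError(
            f"constant or all-missing features in view "
            f"{view.view_name!r}: {bad[:5]}")
    X = (X - mu) / sd
    n_nan = int(np.isnan(X).sum())
    if n_nan:
        logger.info("view %s: imputed %d missing values to 0 after "
                    "standardization", view.view_name, n_nan)
        X = np.nan_to_num(X, nan=0.0)
    return ViewData(X, view.sample_ids, view.feature_names, view.view_name,
                    standardized=True)


def variance_filter(view: ViewData, top_frac: float = 0.10) -> ViewData:
    """Keep the top fraction of features by variance (preprocessing helper
    for high-dimensional omics matrices)."""
    if not 0 < top_frac <= 1:
        raise InvalidArgumentError(f"top_frac must be in (0,1], got {top_frac}")
    var = np.nanvar(view.matrix, axis=0)
    keep = max(1, int(round(top_frac * view.n_features)))
    idx = np.sort(np.argsort(var)[::-1][:keep])
    return ViewData(view.matrix[:, idx], view.sample_ids,
                    [view.feature_names[j] for j in idx], view.view_name,
                    standardized=view.standardized)


def write_dlv_table(path, sample_ids, dlvs: np.ndarray) -> None:
    df = pd.DataFrame(dlvs, index=pd.Index(sample_ids, name="sample_id"),
                      columns=[f"DLV_{n+1}" for n in range(dlvs.shape[1])])
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_dlv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
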