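"""Post-hoc statistics: rank-based inverse normal transform, harmonic-mean
locus scoring with max-statistic permutation FWER control, and bootstrap
mediation analysis.

The locus score summarizes how strongly one feature (a genetic locus, a
methylation probe, ...) associates with *all* latent variables connected to
its data view: the magnitude is the harmonic mean of the absolute Pearson
correlations (sensitive to the weakest link), the sign the sign of their
arithmetic mean.  Family-wise error across loci is controlled in the
strong sense by permuting the sample labels of the target variables
jointly and recording the maximum score per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .covariance import InvalidArgumentError, NumericDegeneracyError

__all__ = [
    "rank_inverse_normal",
    "LocusScoreTable",
    "locus_scores",
    "max_stat_permutation",
    "MediationResult",
    "mediate",
]


def rank_inverse_normal(x) -> np.ndarray:
    """Rank-based inverse Gaussian transform, ``Phi^-1((rank - 0.5)/N)``.

    Removes skew while preserving order; ties receive average ranks and
    map to tied outputs.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if np.all(x == x[0]):
        raise InvalidArgumentError("constant input has no rank transform")
    ranks = scipy.stats.rankdata(x, method="average")
    return scipy.stats.norm.ppf((ranks - 0.5) / n)


@dataclass
class LocusScoreTable:
    """Signed harmonic-mean association scores per locus, with optional
    max-statistic permutation significance."""

    scores: np.ndarray                 # signed, L
    raw_correlations: np.ndarray       # L x T (targets)
    constant_flags: np.ndarray         # L bool: constant locus, score 0
    locus_names: list = field(default_factory=list)
    p_values: np.ndarray | None = None   # FWER-adjusted
    critical_score: float | None = None  # (1 - alpha) quantile of max null
    n_perm: int = 0
    seed: int | None = None
    alpha: float = 0.05


def _corr_matrix(Zl: np.ndarray, Zt: np.ndarray) -> np.ndarray:
    return Zl.T @ Zt / Zl.shape[0]


def _standardize_cols(M: np.ndarray):
    sd = M.std(axis=0)
    const = sd == 0
    Z = np.zeros_like(M, dtype=float)
    ok = ~const
    Z[:, ok] = (M[:, ok] - M[:, ok].mean(0)) / sd[ok]
    return Z, const


def _signed_scores(R: np.ndarray) -> np.ndarray:
    """Harmonic-mean magnitude with arithmetic-mean sign, rowwise.

    A single target reduces to the Pearson correlation itself; any zero
    correlation zeroes the harmonic mean.
    """
    A = np.abs(R)
    T = R.shape[1]
    if T == 1:
        return R[:, 0].copy()
    zero = np.any(A == 0, axis=1)
    mag = np.zeros(R.shape[0])
    nz = ~zero
    mag[nz] = T / np.sum(1.0 / A[nz], axis=1)
    return mag * np.sign(R.mean(axis=1))


def locus_scores(loci, targets, locus_names=None) -> LocusScoreTable:
    """Signed harmonic-mean scores of each locus against the target DLVs.

    ``targets`` is a list of N-vectors (one per connected view's DLV for
    the dimension under analysis); a single target yields the plain
    Pearson correlation.  Constant loci are flagged and scored 0.
    """
    loci = np.atleast_2d(np.asarray(loci, dtype=float))
    tgt = np.column_stack([np.asarray(t, dtype=float).ravel()
                           for t in (targets if isinstance(targets, (list, tuple))
                                     else [targets])])
    if tgt.shape[1] < 1:
        raise InvalidArgumentError("need at least one target")
    if tgt.shape[0] != loci.shape[0]:
        raise InvalidArgumentError("loci and targets are not sample-aligned")
    if np.any(tgt.std(axis=0) == 0):
        raise InvalidArgumentError("constant target DLV")
    Zl, const = _standardize_cols(loci)
    Zt = (tgt - tgt.mean(0)) / tgt.std(0)
    R = _corr_matrix(Zl, Zt)
    scores = _signed_scores(R)
    scores[const] = 0.0
    return LocusScoreTable(scores=scores, raw_correlations=R,
                           constant_flags=const,
                           locus_names=list(locus_names or
                                            range(loci.shape[1])))


def max_stat_permutation(loci, targets, n_perm: int = 1000, seed: int = 0,
                         alpha: float = 0.05,
                         locus_names=None) -> LocusScoreTable:
    """Locus scores with FWER-adjusted permutation p-values.

    The sample labels of all targets are permuted *jointly* per draw
    (preserving the correlation structure among loci, as strong FWER
    control requires); the null statistic is the maximum |score| across
    loci.  Adjusted ``p = (1 + #{max_perm >= |score|}) / (1 + n_perm)``;
    ``critical_score`` is the (1 - alpha) quantile of the max null.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    table = locus_scores(loci, targets, locus_names)
    loci = np.atleast_2d(np.asarray(loci, dtype=float))
    tgt = np.column_stack([np.asarray(t, dtype=float).ravel()
                           for t in (targets if isinstance(targets, (list, tuple))
                                     else [targets])])
    Zl, const = _standardize_cols(loci)
    Zt = (tgt - tgt.mean(0)) / tgt.std(0)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        pi = rng.permutation(Zt.shape[0])
        Rb = _corr_matrix(Zl, Zt[pi])
        sb = np.abs(_signed_scores(Rb))
        sb[const] = 0.0
        max_null[b] = sb.max()
    absS = np.abs(table.scores)
    pvals = (1.0 + (max_null[:, None] >= absS[None, :]).sum(0)) / (1.0 + n_perm)
    table.p_values = pvals
    table.critical_score = float(np.quantile(max_null, 1.0 - alpha))
    table.n_perm = n_perm
    table.seed = seed
    table.alpha = alpha
    return table


@dataclass
class MediationResult:
    """Linear mediation decomposition with bootstrap inference on the
    indirect (A x B) effect."""

    path_a: float
    path_b: float
    direct: float        # c'
    total: float         # c = c' + a*b
    indirect: float      # a*b
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    alpha: float = 0.05

    def summary(self) -> str:
        sig = "" if self.ci_low <= 0 <= self.ci_high else " *"
        return ("Mediation (OLS, percentile bootstrap)\n"
                f"  path A (x -> m):        {self.path_a:+.4f}\n"
                f"  path B (m -> y | x):    {self.path_b:+.4f}\n"
                f"  direct  c' (x -> y | m): {self.direct:+.4f}\n"
                f"  indirect a*b:           {self.indirect:+.4f} "
                f"[{self.ci_low:+.4f}, {self.ci_high:+.4f}]{sig}\n"
                f"  total   c:              {self.total:+.4f}\n"
                f"  bootstrap p:            {self.p_value:.4g} "
                f"({self.n_boot} resamples)")


def _boot_indirect(x, m, y, idx):
    """Closed-form OLS paths a and b on resampled indices (vectorized
    over bootstrap draws)."""
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(1)
    a = (xc * mc).sum(1) / sxx
    # y ~ x + m: 2x2 normal equations per draw
    smm = (mc * mc).sum(1)
    sxm = (xc * mc).sum(1)
    sxy = (xc * yc).sum(1)
    smy = (mc * yc).sum(1)
    det = sxx * smm - sxm**2
    b = (sxx * smy - sxm * sxy) / det
    return a * b


def mediate(x, m, y, n_boot: int = 1000, seed: int = 0,
            alpha: float = 0.05) -> MediationResult:
    """Bootstrap mediation analysis of ``x -> m -> y``.

    Fits ``m ~ x`` (path A), ``y ~ x + m`` (paths C' and B) and ``y ~ x``
    (total C) by OLS; the indirect effect ``a*b`` gets a percentile
    bootstrap confidence interval and a two-sided sign-based p-value.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise InvalidArgumentError("mediation needs at least 10 samples")
    if n_boot < 200:
        raise InvalidArgumentError("n_boot must be >= 200")
    if m.size != n or y.size != n:
        raise InvalidArgumentError("x, m, y must be sample-aligned")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise NumericDegeneracyError(
            f"mediator nearly collinear with x (|r| = {abs(r_xm):.4f})")
    Xa = sm.add_constant(x)
    a = sm.OLS(m, Xa).fit().params[1]
    fit_b = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
    c_prime, b = fit_b.params[1], fit_b.params[2]
    c_total = sm.OLS(y, Xa).fit().params[1]
    indirect = a * b
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = _boot_indirect(x, m, y, idx)
    ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    n_le = int(np.sum(boots <= 0))
    n_ge = int(np.sum(boots >= 0))
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    return MediationResult(path_a=float(a), path_b=float(b),
                           direct=float(c_prime), total=float(c_total),
                           indirect=float(indirect),
                           ci_low=float(ci_low), ci_high=float(ci_high),
                           p_value=float(p), n_boot=n_boot, seed=seed,
                           alpha=alpha)
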