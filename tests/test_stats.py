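"""Downstream statistics: inverse-normal transform, locus scores with
max-statistic FWER control, and bootstrap mediation."""

import numpy as np
import pytest
import scipy.stats

from dlvpm import (InvalidArgumentError, NumericDegeneracyError,
                   locus_scores, max_stat_permutation, mediate,
                   rank_inverse_normal)

RNG = np.random.default_rng(0)


# ------------------------------------------------------- inverse normal
def test_rint_sorted_distinct_is_symmetric_increasing():
    out = rank_inverse_normal(np.arange(9.0))
    assert np.all(np.diff(out) > 0)
    assert np.allclose(out, -out[::-1], atol=1e-12)


def test_rint_removes_skew_of_exponential_sample():
    x = np.random.default_rng(1).exponential(size=1000)
    out = rank_inverse_normal(x)
    assert abs(scipy.stats.skew(out)) < 0.1


def test_rint_ties_get_tied_outputs():
    out = rank_inverse_normal(np.array([1.0, 2.0, 2.0, 5.0]))
    assert out[1] == out[2]


def test_rint_invariant_to_monotone_transform():
    x = RNG.standard_normal(50)
    assert np.allclose(rank_inverse_normal(x),
                       rank_inverse_normal(np.exp(x)), atol=1e-12)


def test_rint_rejects_constant_and_tiny_input():
    with pytest.raises(InvalidArgumentError):
        rank_inverse_normal(np.ones(10))
    with pytest.raises(InvalidArgumentError):
        rank_inverse_normal(np.array([1.0, 2.0]))


# --------------------------------------------------------- locus scores
def test_locus_scores_perfectly_associated_locus():
    rng = np.random.default_rng(2)
    t = rng.standard_normal(3000)
    table = locus_scores(t[:, None], [t, t.copy()])
    assert table.scores[0] == pytest.approx(1.0)


def test_locus_scores_harmonic_mean_magnitude_arithmetic_sign():
    """r = (0.2, 0.8) -> +0.32; r = (-0.5, -0.5) -> -0.5; the magnitude is
    the harmonic mean of |r|, the sign follows the arithmetic mean."""
    from dlvpm.stats import _signed_scores
    assert _signed_scores(np.array([[0.5, 0.5]]))[0] == pytest.approx(0.5)
    assert _signed_scores(np.array([[0.2, 0.8]]))[0] == pytest.approx(0.32)
    assert _signed_scores(np.array([[-0.5, -0.5]]))[0] == pytest.approx(-0.5)
    # any zero correlation zeroes the harmonic mean
    assert _signed_scores(np.array([[0.0, 0.8]]))[0] == pytest.approx(0.0)


def test_locus_scores_single_target_reduces_to_pearson():
    rng = np.random.default_rng(3)
    loci = rng.standard_normal((500, 4))
    t = loci[:, 0] * 0.6 + rng.standard_normal(500)
    table = locus_scores(loci, [t])
    expected = [np.corrcoef(loci[:, j], t)[0, 1] for j in range(4)]
    assert np.allclose(table.scores, expected, atol=1e-12)


def test_locus_scores_constant_locus_flagged_zero():
    loci = np.column_stack([np.ones(50), RNG.standard_normal(50)])
    table = locus_scores(loci, [RNG.standard_normal(50)])
    assert table.constant_flags[0] and table.scores[0] == 0.0


# --------------------------------------------------- max-stat permutation
def test_max_stat_self_target_minimal_p():
    rng = np.random.default_rng(4)
    t = rng.standard_normal(200)
    loci = np.column_stack([t, rng.standard_normal((200, 9)).T.reshape(200, 9)])
    table = max_stat_permutation(loci, [t], n_perm=199, seed=0)
    assert table.p_values[0] == pytest.approx(1 / 200)


def test_max_stat_p_monotone_in_score():
    rng = np.random.default_rng(5)
    t = rng.standard_normal(300)
    loci = np.column_stack([t * w + rng.standard_normal(300)
                            for w in (0.0, 0.3, 0.6, 1.0)])
    table = max_stat_permutation(loci, [t], n_perm=299, seed=1)
    order = np.argsort(-np.abs(table.scores))
    assert np.all(np.diff(table.p_values[order]) >= 0)


def test_max_stat_adjusted_p_at_least_single_locus_p():
    rng = np.random.default_rng(6)
    t = rng.standard_normal(250)
    loci = rng.standard_normal((250, 20))
    loci[:, 3] += 0.4 * t
    full = max_stat_permutation(loci, [t], n_perm=499, seed=2)
    single = max_stat_permutation(loci[:, [3]], [t], n_perm=499, seed=2)
    assert full.p_values[3] >= single.p_values[0] - 1e-12


def test_max_stat_critical_score_is_null_quantile():
    rng = np.random.default_rng(7)
    table = max_stat_permutation(rng.standard_normal((150, 10)),
                                 [rng.standard_normal(150)],
                                 n_perm=199, seed=3, alpha=0.1)
    assert 0 < table.critical_score < 1


# -------------------------------------------------------------- mediation
def test_mediation_null_mediator_covers_zero():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(400)
    m = rng.standard_normal(400)
    y = rng.standard_normal(400)
    res = mediate(x, m, y, n_boot=500, seed=0)
    assert res.ci_low <= 0 <= res.ci_high
    assert abs(res.indirect) < 0.1


def test_mediation_direct_only_effect():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(400)
    y = x.copy()
    m = rng.standard_normal(400)
    res = mediate(x, m, y, n_boot=500, seed=0)
    assert res.total == pytest.approx(1.0, abs=1e-10)
    assert abs(res.indirect) < 0.05


def test_mediation_total_equals_direct_plus_indirect():
    rng = np.random.default_rng(10)
    x = rng.standard_normal(300)
    m = 0.5 * x + rng.standard_normal(300)
    y = 0.4 * m + 0.2 * x + rng.standard_normal(300)
    res = mediate(x, m, y, n_boot=500, seed=0)
    assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-6)


def test_mediation_full_mediation_recovery():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(500)
    m = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(500)
    y = 0.5 * m + np.sqrt(1 - 0.25) * rng.standard_normal(500)
    res = mediate(x, m, y, n_boot=1000, seed=1)
    assert 0.15 <= res.indirect <= 0.35
    assert res.ci_low > 0
    assert res.p_value < 0.05


def test_mediation_collinear_mediator_rejected():
    x = RNG.standard_normal(100)
    with pytest.raises(NumericDegeneracyError):
        mediate(x, x + 1e-9 * RNG.standard_normal(100), x, n_boot=200, seed=0)


def test_mediation_summary_format():
    rng = np.random.default_rng(12)
    res = mediate(rng.standard_normal(100), rng.standard_normal(100),
                  rng.standard_normal(100), n_boot=200, seed=0)
    assert "indirect" in res.summary()
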