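"""Structural-model validation and view I/O."""

import numpy as np
import pandas as pd
import pytest

from dlvpm import (InvalidArgumentError, ViewData, align_views,
                   load_view_matrix, standardize_view, validate_path_spec,
                   variance_filter)
from dlvpm.data import read_dlv_table, write_dlv_table


# ------------------------------------------------------------------ path
def test_simple_two_view_path():
    ps = validate_path_spec([[0, 1], [1, 0]], ["a", "b"])
    assert ps.K == 2 and ps.n_edges == 1 and ps.edges() == [(0, 1)]


def test_star_graph_four_spokes():
    """Hub-and-spoke model with a transcriptomic view at the centre and
    four data types as spokes."""
    A = np.zeros((5, 5), dtype=int)
    A[0, 1:] = A[1:, 0] = 1
    ps = validate_path_spec(
        A, ["rnaseq", "histology", "snv", "methylation", "mirna"])
    assert ps.n_edges == 4
    assert set(ps.neighbours(0)) == {1, 2, 3, 4}


def test_diagonal_entries_zeroed_with_warning(caplog):
    ps = validate_path_spec([[1, 1], [1, 0]])
    assert np.all(np.diag(ps.adjacency) == 0)


def test_asymmetric_adjacency_symmetrized(caplog):
    ps = validate_path_spec([[0, 1, 0], [0, 0, 0], [0, 1, 0]])
    assert np.array_equal(ps.adjacency, ps.adjacency.T)
    assert ps.n_edges == 2


@pytest.mark.parametrize("bad", [
    [[0, 2], [2, 0]],                  # non-binary
    [[0]],                             # K < 2
    [[0, 0], [0, 0]],                  # no edges
    [[0, 1, 1], [1, 0, 1]],            # non-square
])
def test_invalid_adjacency_rejected(bad):
    with pytest.raises(InvalidArgumentError):
        validate_path_spec(bad)


# ------------------------------------------------------------------ data io
def test_load_view_matrix_roundtrip(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text("sample_id\tg1\tg2\nS1\t1.0\t2.0\nS2\t3.5\t4.0\nS3\t5\t6\n")
    vd = load_view_matrix(p, "toy")
    assert vd.n_samples == 3 and vd.n_features == 2
    assert vd.sample_ids == ["S1", "S2", "S3"]


def test_load_view_matrix_na_tokens_to_nan(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text("id\tg1\tg2\nS1\tNA\t2.0\nS2\t3.0\t4.0\nS3\t7.0\t1.0\n")
    vd = load_view_matrix(p)
    assert np.isnan(vd.matrix[0, 0])
    std = standardize_view(vd)
    assert std.matrix[0, 0] == 0.0          # imputed to the mean
    assert not np.isnan(std.matrix).any()


def test_load_view_matrix_duplicate_ids_error(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("id\tg1\nS1\t1.0\nS1\t2.0\n")
    with pytest.raises(InvalidArgumentError, match="S1"):
        load_view_matrix(p)


def test_load_view_matrix_non_numeric_cell_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("id\tg1\nS1\tok_not_number\nS2\t2.0\n")
    with pytest.raises(InvalidArgumentError, match="g1"):
        load_view_matrix(p)


def _mk_view(ids, p=2, seed=0, name="v"):
    rng = np.random.default_rng(seed)
    return ViewData(rng.standard_normal((len(ids), p)), list(ids),
                    [f"f{j}" for j in range(p)], name)


def test_align_views_shuffled_ids():
    a = _mk_view(["S1", "S2", "S3"], name="a")
    b = _mk_view(["S3", "S1", "S2"], seed=1, name="b")
    (aa, bb), _ = align_views([a, b])
    assert aa.sample_ids == bb.sample_ids == ["S1", "S2", "S3"]
    assert np.array_equal(bb.matrix[0], b.matrix[1])


def test_align_views_drops_extra_sample():
    a = _mk_view(["S1", "S2"], name="a")
    b = _mk_view(["S1", "S2", "S9"], seed=1, name="b")
    (aa, bb), _ = align_views([a, b])
    assert bb.n_samples == 2


def test_align_views_disjoint_error():
    with pytest.raises(InvalidArgumentError):
        align_views([_mk_view(["S1"]), _mk_view(["T1"])])


def test_variance_filter_keeps_top_fraction():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 10)) * np.arange(1, 11)
    vd = ViewData(X, [f"S{i}" for i in range(50)],
                  [f"f{j}" for j in range(10)], "v")
    out = variance_filter(vd, top_frac=0.3)
    assert out.n_features == 3
    assert out.feature_names == ["f7", "f8", "f9"]


def test_dlv_table_roundtrip_precision(tmp_path):
    rng = np.random.default_rng(0)
    Y = rng.standard_normal((20, 3))
    ids = [f"S{i}" for i in range(20)]
    p = tmp_path / "dlv.tsv"
    write_dlv_table(p, ids, Y)
    back = read_dlv_table(p)
    assert np.allclose(back.to_numpy(), Y, rtol=1e-12, atol=0)
    assert list(back.index) == ids
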