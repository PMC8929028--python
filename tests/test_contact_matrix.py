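import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from _oracles import smooth_rows_loop
from hprep.contact_matrix import build_chrom_matrix, build_matrix, smooth_matrix
from hprep.io_formats import AnchorSet, StudyConfig


def _norm_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "normalized"])


class TestBuildMatrix:
    def test_xor_pair_populates_one_cell(self):
        df = _norm_df([("chr1", 50_000, 70_000, 2.5)])
        mat = build_chrom_matrix(df, np.array([50_000]), "chr1", 10_000, 1_000_000)
        assert mat.values[0, mat.column_of(+2)] == 2.5
        assert np.count_nonzero(mat.values) == 1

    def test_and_pair_populates_both_anchor_rows(self):
        df = _norm_df([("chr1", 50_000, 80_000, 1.5)])
        mat = build_chrom_matrix(df, np.array([50_000, 80_000]), "chr1", 10_000, 1_000_000)
        assert mat.values[0, mat.column_of(+3)] == 1.5
        assert mat.values[1, mat.column_of(-3)] == 1.5
        assert np.count_nonzero(mat.values) == 2

    def test_nonzero_cell_count_bound(self):
        rng = np.random.default_rng(0)
        anchors = np.sort(rng.choice(100, 12, replace=False).astype(np.int64)) * 10_000
        aset = set(anchors)
        rows, n_and, n_xor = [], 0, 0
        for a in anchors:
            for off in rng.choice(np.arange(1, 50), 6, replace=False):
                other = a + int(off) * 10_000
                b1, b2 = min(a, other), max(a, other)
                rows.append(("chr1", b1, b2, rng.uniform(0.5, 2.0)))
                if b1 in aset and b2 in aset:
                    n_and += 1
                else:
                    n_xor += 1
        df = _norm_df(rows).drop_duplicates(["bin1", "bin2"])
        mat = build_chrom_matrix(df, anchors, "chr1", 10_000, 1_000_000)
        assert np.count_nonzero(mat.values) <= n_xor + 2 * n_and

    def test_matrix_width_at_5kb(self):
        cfg = StudyConfig(resolution=5_000, chromosomes=("chr1",))
        anchors = AnchorSet(5_000, {"chr1": np.array([0])})
        mats = build_matrix(_norm_df([]), anchors, cfg)
        assert mats["chr1"].values.shape == (1, 400)

    def test_pair_order_does_not_matter(self):
        rows = [("chr1", 0, 30_000, 1.0), ("chr1", 30_000, 60_000, 2.0), ("chr1", 0, 50_000, 0.5)]
        anchors = np.array([0, 30_000])
        m1 = build_chrom_matrix(_norm_df(rows), anchors, "chr1", 10_000, 1_000_000)
        m2 = build_chrom_matrix(_norm_df(rows[::-1]), anchors, "chr1", 10_000, 1_000_000)
        assert np.array_equal(m1.values, m2.values)

    def test_pair_beyond_binning_distance_dropped(self):
        df = _norm_df([("chr1", 0, 2_000_000, 3.0)])
        mat = build_chrom_matrix(df, np.array([0]), "chr1", 10_000, 1_000_000)
        assert np.count_nonzero(mat.values) == 0

    def test_pair_with_no_anchor_end_rejected(self):
        df = _norm_df([("chr1", 10_000, 30_000, 1.0)])
        with pytest.raises(ValueError, match="NOT"):
            build_chrom_matrix(df, np.array([50_000]), "chr1", 10_000, 1_000_000)


class TestSmoothing:
    def test_d_zero_is_identity(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(size=(4, 8)))
        out = smooth_matrix(mat, 0)
        assert np.array_equal(out.values, mat.values)
        assert out.smoothed_with == 0

    def test_hand_example_zero_fill(self):
        # row [0,0,6,0,0,0] with d=1: spike spreads to mean over 3 cells
        mat = make_matrix([[0.0, 0.0, 6.0, 0.0, 0.0, 0.0]])
        out = smooth_matrix(mat, 1)
        assert np.allclose(out.values[0], [0, 2, 2, 2, 0, 0])

    def test_edges_divide_by_full_window(self):
        mat = make_matrix([np.ones(6)])
        out = smooth_matrix(mat, 2)
        # interior cells keep 1.0; edge cell sees 3 ones / 5
        assert out.values[0, 2] == pytest.approx(1.0)
        assert out.values[0, 0] == pytest.approx(3 / 5)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(3, 10)), rng.normal(size=(3, 10))
        mx, my = make_matrix(x), make_matrix(y)
        mxy = make_matrix(2.5 * x + y)
        lhs = smooth_matrix(mxy, 2).values
        rhs = 2.5 * smooth_matrix(mx, 2).values + smooth_matrix(my, 2).values
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_interior_row_sum_conserved(self):
        row = np.zeros(12)
        row[4:8] = [1.0, 2.0, 3.0, 1.5]  # zero within d of both edges
        mat = make_matrix([row])
        out = smooth_matrix(mat, 2)
        assert out.values[0].sum() == pytest.approx(row.sum())

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 8))
        values[rng.uniform(size=(5, 8)) < 0.3] = 0.0
        mat = make_matrix(values)
        for d in (0, 1, 2, 3):
            assert np.allclose(
                smooth_matrix(mat, d).values, smooth_rows_loop(values, d), atol=1e-12
            )

    def test_oversized_window_rejected(self):
        mat = make_matrix(np.zeros((2, 6)))
        with pytest.raises(ValueError):
            smooth_matrix(mat, 6)
        with pytest.raises(ValueError):
            smooth_matrix(mat, -1)
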