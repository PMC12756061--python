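import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from pseudogrn import (
    ExpressionMatrix,
    PseudotimeVector,
    diffusion_pseudotime,
    load_precomputed_pseudotime,
    order_and_smooth,
    pca_pseudotime,
    preprocess,
)


def _line_expr(n=10, noise=0.0, seed=0):
    """Cells equally spaced on a line in a 2-gene space."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    vals = np.vstack([1 + 2 * t, 3 - t + 1]) + noise * rng.random((2, n))
    return ExpressionMatrix(vals, ["gA", "gB"], [f"c{i:02d}" for i in range(n)]), t


class TestPreprocess:
    def test_equal_column_sums_reduce_to_log1p(self):
        vals = np.array([[1.0, 2.0], [3.0, 2.0]])  # both columns sum to 4
        expr = ExpressionMatrix(vals, ["a", "b"], ["c1", "c2"])
        out = preprocess(expr, True)
        np.testing.assert_allclose(out.values, np.log1p(vals))

    def test_disabled_is_identity(self):
        vals = np.array([[1.0, 9.0], [3.0, 2.0]])
        expr = ExpressionMatrix(vals, ["a", "b"], ["c1", "c2"])
        assert preprocess(expr, False) is expr

    def test_median_scaling_hand_computed(self):
        # column sums (100, 200), median 150 -> scales 1.5 and 0.75
        vals = np.array([[40.0, 120.0], [60.0, 80.0]])
        expr = ExpressionMatrix(vals, ["a", "b"], ["c1", "c2"])
        out = preprocess(expr, True)
        expected = np.log1p(vals * np.array([1.5, 0.75]))
        np.testing.assert_allclose(out.values, expected)

    def test_zero_column_names_cell(self):
        vals = np.array([[1.0, 0.0], [3.0, 0.0]])
        expr = ExpressionMatrix(vals, ["a", "b"], ["c1", "c2"])
        with pytest.raises(ValueError, match="c2"):
            preprocess(expr, True)


class TestPcaPseudotime:
    def test_equally_spaced_line_gives_equally_spaced_pseudotime(self):
        expr, _ = _line_expr(10)
        pt = pca_pseudotime(expr)
        diffs = np.diff(np.sort(pt.values))
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-6)

    def test_root_at_extreme_maps_to_zero_and_opposite_to_max(self):
        expr, _ = _line_expr(10)
        pt = pca_pseudotime(expr, root_cell="c09")
        assert pt.values[9] == pytest.approx(0.0, abs=1e-9)
        assert np.argmax(pt.values) == 0

    def test_matches_closed_form_2x2_eigendecomposition(self):
        # 2 genes x 6 cells: pseudotime proportional to the projection on
        # the leading eigenvector of the 2x2 covariance matrix
        vals = np.array([[0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                         [1.0, 2.5, 2.0, 4.5, 4.0, 6.0]])
        expr = ExpressionMatrix(vals, ["gA", "gB"], [f"c{i}" for i in range(6)])
        X = vals - vals.mean(axis=1, keepdims=True)
        cov = X @ X.T / 6
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        proj = lead @ X
        proj = proj if proj[-1] > proj[0] else -proj
        expected = proj - proj.min()
        pt = pca_pseudotime(expr, root_cell="c0")
        np.testing.assert_allclose(pt.values, expected, atol=1e-9)

    def test_constant_matrix_is_hard_error(self):
        expr = ExpressionMatrix(np.full((2, 5), 3.0), ["a", "b"],
                                [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="constant"):
            pca_pseudotime(expr)


class TestDiffusionPseudotime:
    def test_root_gets_zero(self):
        expr, _ = _line_expr(30, noise=0.01)
        pt = diffusion_pseudotime(expr, root_cell="c00", n_neighbors=10)
        assert pt.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_of_root_gets_zero(self):
        vals = np.vstack([np.arange(12.0), np.arange(12.0)[::-1]])
        vals[:, 5] = vals[:, 0]  # c05 duplicates the root c00
        expr = ExpressionMatrix(vals, ["a", "b"], [f"c{i:02d}" for i in range(12)])
        pt = diffusion_pseudotime(expr, root_cell="c00", n_neighbors=4)
        assert pt.values[5] == pytest.approx(0.0, abs=1e-8)

    def test_chain_order_recovered(self):
        expr, t = _line_expr(30, noise=0.02, seed=3)
        pt = diffusion_pseudotime(expr, root_cell="c00", n_neighbors=10)
        rho = spearmanr(pt.values, t).statistic
        assert abs(rho) >= 0.95

    def test_disconnected_graph_advises_larger_k(self):
        vals = np.zeros((2, 10))
        vals[0, :5] = [0, 1, 2, 3, 4]
        vals[0, 5:] = [1000, 1001, 1002, 1003, 1004]
        vals[1] = 1.0
        expr = ExpressionMatrix(vals, ["a", "b"], [f"c{i}" for i in range(10)])
        with pytest.raises(ValueError, match="n_neighbors"):
            diffusion_pseudotime(expr, n_neighbors=2)


class TestPrecomputed:
    def test_shuffled_table_realigned(self, small_expr, tmp_path):
        p = tmp_path / "pt.tsv"
        rows = [(c, i * 0.5) for i, c in enumerate(small_expr.cell_ids)][::-1]
        p.write_text("cell\tpseudotime\n" + "\n".join(f"{c}\t{v}" for c, v in rows))
        pt = load_precomputed_pseudotime(p, small_expr)
        assert pt.cell_ids == small_expr.cell_ids
        np.testing.assert_allclose(pt.values, 0.5 * np.arange(8))

    def test_missing_cell_named(self, small_expr, tmp_path):
        p = tmp_path / "pt.tsv"
        p.write_text("\n".join(f"{c}\t1.0" for c in small_expr.cell_ids[:-1]))
        with pytest.raises(ValueError, match="c7"):
            load_precomputed_pseudotime(p, small_expr)

    def test_duplicate_cell_rejected_and_ties_accepted(self, small_expr, tmp_path):
        p = tmp_path / "pt.tsv"
        p.write_text("\n".join(f"{c}\t1.0" for c in small_expr.cell_ids))
        pt = load_precomputed_pseudotime(p, small_expr)  # ties are fine
        assert np.all(pt.values == 1.0)
        p.write_text(p.read_text() + f"\n{small_expr.cell_ids[0]}\t2.0")
        with pytest.raises(ValueError, match="duplicate"):
            load_precomputed_pseudotime(p, small_expr)


class TestOrderAndSmooth:
    def test_window_count_120_cells(self):
        rng = np.random.default_rng(0)
        n = 120
        expr = ExpressionMatrix(rng.random((2, n)), ["a", "b"],
                                [f"c{i:03d}" for i in range(n)])
        pt = PseudotimeVector(list(expr.cell_ids), np.arange(n, dtype=float))
        traj = order_and_smooth(expr, pt, width=5, step=1)
        assert traj.n_windows == 116

    def test_constant_gene_stays_constant(self, small_expr):
        pt = PseudotimeVector(list(small_expr.cell_ids), np.arange(8.0))
        traj = order_and_smooth(small_expr, pt, width=3, step=2)
        np.testing.assert_allclose(
            traj.gene_profile("gC"), small_expr.values[2, :3].mean(), atol=0.02
        )

    def test_width_one_is_sorted_identity(self, small_expr):
        pt = PseudotimeVector(list(small_expr.cell_ids), np.arange(8.0)[::-1])
        traj = order_and_smooth(small_expr, pt, width=1, step=1)
        np.testing.assert_array_equal(traj.values, small_expr.values[:, ::-1])

    def test_width_exceeding_n_is_error(self, small_expr):
        pt = PseudotimeVector(list(small_expr.cell_ids), np.arange(8.0))
        with pytest.raises(ValueError):
            order_and_smooth(small_expr, pt, width=9, step=1)

    @given(
        n=st.integers(6, 60),
        width=st.integers(1, 10),
        step=st.integers(1, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_formula(self, n, width, step):
        if width > n:
            return
        rng = np.random.default_rng(1)
        expr = ExpressionMatrix(rng.random((2, n)), ["a", "b"],
                                [f"c{i:03d}" for i in range(n)])
        pt = PseudotimeVector(list(expr.cell_ids), rng.random(n))
        traj = order_and_smooth(expr, pt, width, step)
        assert traj.n_windows == (n - width) // step + 1
        assert np.all(np.diff(traj.window_centers) >= -1e-12)

    def test_monotone_relabeling_invariance(self, small_expr):
        vals = np.arange(8.0)
        pt1 = PseudotimeVector(list(small_expr.cell_ids), vals)
        pt2 = PseudotimeVector(list(small_expr.cell_ids), np.exp(vals / 3))
        t1 = order_and_smooth(small_expr, pt1, 3, 1)
        t2 = order_and_smooth(small_expr, pt2, 3, 1)
        np.testing.assert_array_equal(t1.values, t2.values)


def test_pseudotime_recovery_on_noiseless_trajectory():
    expr, t = _line_expr(100)
    rho_pca = spearmanr(pca_pseudotime(expr).values, t).statistic
    rho_dm = spearmanr(diffusion_pseudotime(expr).values, t).statistic
    assert abs(rho_pca) >= 0.99
    assert abs(rho_dm) >= 0.9
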