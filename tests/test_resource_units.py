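import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habselect import (
    RasterGrid,
    aggregate_to_ru,
    distance_layer,
    kappa_accuracy,
    morans_i,
    pca_egv,
    pearson_screen,
    read_ascii_grid,
    write_ascii_grid,
)


def grid(values, cell=30.0, origin=None, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cell)
    return RasterGrid(values, cell, origin, nodata)


class TestRasterGrid:
    def test_cell_centre_formula(self):
        g = grid(np.zeros((4, 5)), cell=10.0, origin=(100.0, 240.0))
        x, y = g.cell_centres()
        assert x[0, 0] == 105.0 and y[0, 0] == 235.0
        assert x[3, 4] == 145.0 and y[3, 0] == 205.0

    def test_point_to_cell_half_open_boundaries(self):
        g = grid(np.zeros((3, 3)), cell=10.0, origin=(0.0, 30.0))
        # interior point
        assert g.point_to_cell(5.0, 25.0) == (0, 0)
        # vertical boundary -> eastern cell; horizontal -> southern cell
        assert g.point_to_cell(10.0, 25.0) == (0, 1)
        assert g.point_to_cell(5.0, 20.0) == (1, 0)

    def test_point_outside_raises(self):
        g = grid(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="outside"):
            g.point_to_cell(-1.0, 10.0)

    def test_ascii_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        g = grid(rng.standard_normal((7, 5)), cell=90.0, origin=(500.0, 1200.0))
        p = tmp_path / "layer.asc"
        write_ascii_grid(g, p)
        back = read_ascii_grid(p)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-9)
        assert back.cell_size == g.cell_size
        assert back.origin == pytest.approx(g.origin)


class TestAggregateToRU:
    def cover_3x3(self, codes):
        return grid(np.array(codes, dtype=float).reshape(3, 3))

    def test_proportions_by_counting(self):
        cover = self.cover_3x3([0, 0, 0, 1, 1, 1, 0, 0, 0])
        stack = aggregate_to_ru(cover, {}, factor=3)
        assert len(stack.table) == 1
        assert stack.table["prop_0"].iloc[0] == pytest.approx(6 / 9)
        assert stack.table["prop_1"].iloc[0] == pytest.approx(3 / 9)

    def test_constant_block_mean_identity(self):
        cover = self.cover_3x3([0] * 9)
        elev = grid(np.full((3, 3), 300.0))
        stack = aggregate_to_ru(cover, {"elevation": elev}, factor=3)
        assert stack.table["elevation"].iloc[0] == 300.0

    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(1)
        cover = grid(rng.integers(0, 3, (6, 6)).astype(float))
        elev = grid(rng.standard_normal((6, 6)))
        stack = aggregate_to_ru(cover, {"elevation": elev}, factor=1)
        assert len(stack.table) == 36
        np.testing.assert_allclose(
            stack.grids["elevation"].values, elev.values
        )

    def test_proportions_sum_to_one(self, null_sim):
        _, _, _, stack, _, _ = null_sim
        props = stack.table[
            [f"prop_{c}" for c in stack.cover_classes]
        ].sum(axis=1)
        np.testing.assert_allclose(props, 1.0, atol=1e-9)

    def test_reaggregation_idempotent_for_continuous(self):
        rng = np.random.default_rng(2)
        cover = grid(np.zeros((6, 6)))
        vals = rng.standard_normal((6, 6))
        stack = aggregate_to_ru(cover, {"v": grid(vals)}, factor=3)
        coarse = stack.grids["v"].values
        # disaggregate by replication, re-aggregate
        rep = np.kron(coarse, np.ones((3, 3)))
        stack2 = aggregate_to_ru(
            grid(np.zeros((6, 6))), {"v": grid(rep)}, factor=3
        )
        np.testing.assert_allclose(stack2.grids["v"].values, coarse, atol=1e-12)

    def test_mixed_cell_sizes_rejected(self):
        cover = grid(np.zeros((3, 3)), cell=30.0)
        other = grid(np.zeros((3, 3)), cell=10.0)
        with pytest.raises(ValueError, match="mixed cell sizes"):
            aggregate_to_ru(cover, {"x": other}, factor=3)

    def test_bad_factor_rejected(self):
        cover = grid(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="factor"):
            aggregate_to_ru(cover, {}, factor=0)


class TestDistanceLayer:
    def test_four_neighbour_and_diagonal(self):
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        d = distance_layer(grid(mask, cell=30.0))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(30.0)
        assert d.values[1, 2] == pytest.approx(30.0)
        assert d.values[1, 1] == pytest.approx(30.0 * np.sqrt(2))

    def test_all_feature_cells_zero(self):
        d = distance_layer(grid(np.ones((4, 4))))
        assert (d.values == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no feature"):
            distance_layer(grid(np.zeros((4, 4))))

    def test_neighbour_lipschitz_property(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((20, 20)) < 0.05).astype(float)
        mask[0, 0] = 1
        d = distance_layer(grid(mask, cell=30.0)).values
        lim = 30.0 * np.sqrt(2) + 1e-9
        for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            a = d[max(dr, 0):d.shape[0] + min(dr, 0),
                  max(dc, 0):d.shape[1] + min(dc, 0)]
            b = d[max(-dr, 0):d.shape[0] + min(-dr, 0),
                  max(-dc, 0):d.shape[1] + min(-dc, 0)]
            assert np.abs(a - b).max() <= lim


class TestPearsonScreen:
    def test_exact_correlations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "negx": -x, "y": x**2})
        mat, flagged = pearson_screen(df, threshold=0.99,
                                      columns=["x", "negx", "y"])
        assert mat.loc["x", "x"] == pytest.approx(1.0)
        assert mat.loc["x", "negx"] == pytest.approx(-1.0)
        assert ("x", "negx") in [(a, b) for a, b, _ in flagged]

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        mat, flagged = pearson_screen(df, columns=["a", "b"])
        assert abs(mat.loc["a", "b"]) < 0.05
        assert not flagged

    def test_constant_column_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [5.0] * 4,
                           "b": [2.0, 1, 4, 3]})
        with pytest.warns(UserWarning, match="constant"):
            mat, _ = pearson_screen(df, columns=["a", "c", "b"])
        assert list(mat.columns) == ["a", "b"]
        assert not mat.isna().any().any()


class TestPCA:
    def test_perfectly_correlated_columns_one_component(self):
        x = np.arange(50.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_egv(df, columns=["a", "b"])
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_isotropic_gaussian_equal_eigenvalues(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        res = pca_egv(df, columns=["a", "b"])
        assert res.eigenvalues[0] / res.eigenvalues[1] < 1.05

    def test_loadings_unit_norm(self, standard_normal_rut):
        res = pca_egv(standard_normal_rut, columns=list("abcd"))
        norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        g = grid(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert morans_i(g, "rook") == pytest.approx(-1.0)

    def test_smooth_ramp_strongly_positive(self):
        ramp = np.tile(np.arange(50.0), (50, 1))
        assert morans_i(grid(ramp), "rook") > 0.9

    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(6)
        g = grid(rng.standard_normal((50, 50)))
        assert abs(morans_i(g, "rook")) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((15, 15))
        i1 = morans_i(grid(vals), "queen")
        i2 = morans_i(grid(3.5 * vals - 100.0), "queen")
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(grid(np.ones((4, 4))), "rook")


class TestKappa:
    @pytest.mark.parametrize("cm, acc, kap", [
        (np.diag([10, 20, 30]), 1.0, 1.0),
        ([[40, 10], [5, 45]], 0.85, 0.70),
        ([[25, 25], [25, 25]], 0.5, 0.0),
    ])
    def test_known_values(self, cm, acc, kap):
        a, k = kappa_accuracy(np.asarray(cm))
        assert a == pytest.approx(acc)
        assert k == pytest.approx(kap)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            kappa_accuracy(np.array([[10, 0], [0, 0]]))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_moran_bounded_for_contiguity_weights(seed):
    rng = np.random.default_rng(seed)
    g = grid(rng.standard_normal((8, 8)))
    i = morans_i(g, "rook")
    assert -1.0 - 1e-9 <= i <= 1.0 + 1e-9
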