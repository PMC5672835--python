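import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habselect import (
    RasterGrid,
    boyce_index,
    fi_curve,
    fit_niche,
    mahalanobis_d2,
    reclassify_and_summarize,
    suitability_map,
)
from habselect.suitability import FiCurve


def frame(values, columns):
    return pd.DataFrame(np.asarray(values, float), columns=columns)


def suit_raster(values, cell=90.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, cell, (0.0, values.shape[0] * cell))


class TestFitNiche:
    def test_identical_locations_singular(self):
        df = frame(np.ones((10, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="singular|constant"):
            fit_niche(df)

    def test_recovers_mean_and_covariance(self):
        rng = np.random.default_rng(24)
        df = frame(rng.standard_normal((10_000, 2)), ["a", "b"])
        model = fit_niche(df)
        np.testing.assert_allclose(model.mean, 0.0, atol=0.05)
        np.testing.assert_allclose(model.cov, np.eye(2), atol=0.05)

    def test_row_order_invariant(self):
        rng = np.random.default_rng(25)
        df = frame(rng.standard_normal((100, 3)), ["a", "b", "c"])
        m1 = fit_niche(df)
        m2 = fit_niche(df.iloc[::-1].reset_index(drop=True))
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-12)
        np.testing.assert_allclose(m1.cov, m2.cov, atol=1e-12)

    def test_needs_more_rows_than_columns(self):
        df = frame(np.random.default_rng(0).standard_normal((3, 3)),
                   ["a", "b", "c"])
        with pytest.raises(ValueError, match="more locations"):
            fit_niche(df)

    def test_ridge_rescues_singular_fit(self):
        rng = np.random.default_rng(26)
        x = rng.standard_normal(50)
        df = frame(np.column_stack([x, 2 * x]), ["a", "b"])
        with pytest.raises(ValueError):
            fit_niche(df)
        model = fit_niche(df, ridge=1e-3)
        assert model.condition_number < 1e8


class TestMahalanobis:
    def test_centre_gives_zero_and_unit_suitability(self):
        rng = np.random.default_rng(27)
        df = frame(rng.standard_normal((100, 2)), ["a", "b"])
        model = fit_niche(df)
        d2 = mahalanobis_d2(model.mean[None, :], model)
        assert d2[0] == pytest.approx(0.0, abs=1e-12)
        assert stats.chi2.sf(d2[0], model.p) == pytest.approx(1.0)

    def test_one_dim_oracle(self):
        """p = 1, sigma^2 = 1, x - mu = 2 -> D2 = 4, sf(4;1) ~ 0.0455."""
        rng = np.random.default_rng(28)
        x = rng.standard_normal(100_000)
        df = frame(x[:, None], ["a"])
        model = fit_niche(df)
        d2 = mahalanobis_d2(np.array([[model.mean[0] + 2.0]]), model)
        assert d2[0] == pytest.approx(4.0, rel=0.02)
        assert stats.chi2.sf(4.0, 1) == pytest.approx(0.0455, abs=1e-4)

    def test_suitability_monotone_in_d2(self):
        d2 = np.linspace(0, 20, 50)
        s = stats.chi2.sf(d2, 3)
        assert np.all(np.diff(s) < 0)

    def test_d2_of_model_draws_follows_chi_square(self):
        rng = np.random.default_rng(29)
        df = frame(rng.multivariate_normal([1, -2, 0], np.diag([1, 2, 0.5]),
                                           4000), ["a", "b", "c"])
        model = fit_niche(df)
        draws = rng.multivariate_normal(model.mean, model.cov, 5000)
        d2 = mahalanobis_d2(draws, model)
        ks = stats.kstest(d2, stats.chi2(df=3).cdf)
        assert ks.pvalue > 0.01


class TestFiCurve:
    def test_two_class_arithmetic(self):
        """E = (0.5, 0.5), P = (0.2, 0.8) -> F = (0.4, 1.6)."""
        vals = np.array([[0.2, 0.2], [0.8, 0.8]])  # classes 4 and 16 of 20
        grid = suit_raster(vals)
        # 1 point on the low-suitability row, 4 points on the high row
        pts = np.array([[45.0, 135.0]] + [[45.0 + 90 * (i % 2), 45.0]
                                          for i in range(4)])
        curve = fi_curve(grid, pts, n_classes=20)
        tab = curve.table
        assert len(tab) == 2
        np.testing.assert_allclose(tab["E"], [0.5, 0.5])
        np.testing.assert_allclose(tab["P"], [0.2, 0.8])
        np.testing.assert_allclose(tab["F"], [0.4, 1.6])
        assert curve.threshold == pytest.approx(0.80)

    def test_uniform_points_give_flat_curve(self):
        rng = np.random.default_rng(30)
        vals = rng.uniform(0, 1, (40, 40))
        grid = suit_raster(vals)
        pts = rng.uniform(1.0, 3599.0, (20_000, 2))
        curve = fi_curve(grid, pts, n_classes=10)
        np.testing.assert_allclose(curve.table["F"], 1.0, atol=0.1)

    def test_normalization_invariants(self):
        rng = np.random.default_rng(31)
        vals = rng.uniform(0, 1, (20, 20))
        grid = suit_raster(vals)
        pts = rng.uniform(1.0, 1799.0, (500, 2))
        curve = fi_curve(grid, pts)
        assert curve.table["P"].sum() == pytest.approx(1.0)
        assert curve.table["E"].sum() == pytest.approx(1.0)
        assert (curve.table["F"] >= 0).all()

    def test_all_points_on_nodata_rejected(self):
        vals = np.full((3, 3), -9999.0)
        vals[0, :] = 0.5  # some valid area, but the points miss it
        grid = suit_raster(vals)
        with pytest.raises(ValueError, match="nodata"):
            fi_curve(grid, np.array([[45.0, 45.0]]))


class TestBoyce:
    def make_curve(self, F):
        n = len(F)
        tab = pd.DataFrame({
            "class_index": np.arange(1, n + 1),
            "lo": np.linspace(0, 1, n + 1)[:-1],
            "hi": np.linspace(0, 1, n + 1)[1:],
            "P": np.asarray(F) / np.sum(F),
            "E": np.full(n, 1.0 / n),
        })
        tab["F"] = tab["P"] / tab["E"]
        return FiCurve(tab, n, None)

    def test_monotone_curves(self):
        up = boyce_index(self.make_curve([0.2, 0.5, 1.4, 2.0]))
        assert up.boyce_r == pytest.approx(1.0)
        down = boyce_index(self.make_curve([2.0, 1.4, 0.5, 0.2]))
        assert down.boyce_r == pytest.approx(-1.0)

    def test_constant_curve_flagged_undefined(self):
        curve = boyce_index(self.make_curve([1.0, 1.0, 1.0]))
        assert curve.boyce_r is None

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            boyce_index(self.make_curve([0.5, 1.5]))


class TestReclassify:
    def curve_with_threshold(self, t):
        c = TestBoyce().make_curve([0.5, 0.8, 1.5, 2.0])
        c.threshold = t
        return c

    def test_threshold_zero_everything_suitable(self):
        vals = np.random.default_rng(32).uniform(0, 1, (10, 10))
        grid = suit_raster(vals)
        _, summary = reclassify_and_summarize(grid, self.curve_with_threshold(0.0))
        assert summary["percent_suitable"].iloc[0] == pytest.approx(100.0)

    def test_impossible_threshold_nothing_suitable(self):
        vals = np.random.default_rng(33).uniform(0, 1, (10, 10))
        grid = suit_raster(vals)
        _, summary = reclassify_and_summarize(
            grid, self.curve_with_threshold(1.0 + 1e-9))
        assert summary["percent_suitable"].iloc[0] == 0.0

    def test_monotone_in_threshold(self):
        vals = np.random.default_rng(34).uniform(0, 1, (20, 20))
        grid = suit_raster(vals)
        pcts = [
            reclassify_and_summarize(
                grid, self.curve_with_threshold(t))[1]["percent_suitable"].iloc[0]
            for t in (0.2, 0.5, 0.8)
        ]
        assert pcts[0] >= pcts[1] >= pcts[2]

    def test_zone_summary(self):
        vals = np.array([[0.9, 0.1], [0.9, 0.1]])
        zones = RasterGrid(np.array([[0.0, 0.0], [1.0, 1.0]]), 90.0,
                           (0.0, 180.0))
        grid = suit_raster(vals)
        _, summary = reclassify_and_summarize(
            grid, self.curve_with_threshold(0.5), zones)
        assert set(summary["zone"]) == {0.0, 1.0}
        np.testing.assert_allclose(summary["percent_suitable"], 50.0)

    def test_missing_threshold_rejected(self):
        grid = suit_raster(np.array([[0.5, 0.5], [0.5, 0.5]]))
        c = TestBoyce().make_curve([1.0, 1.0, 1.0])
        c.threshold = None
        with pytest.raises(ValueError, match="threshold"):
            reclassify_and_summarize(grid, c)
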