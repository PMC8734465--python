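import numpy as np
import pandas as pd
import pytest

from standpp import (CovariateRaster, PlotWindow, ensemble_importance,
                     fit_citree, focal_abundance_surface,
                     neighborhood_features, sample_raster_at_points)
from standpp.errors import ConfigurationError, StandppError

from conftest import make_census
from oracles import neighborhood_brute


class TestFocalSurface:
    def test_uniform_density_gives_constant_surface(self):
        # one stem at each 20-m cell centre of a 100 x 100 plot
        g = np.arange(10.0, 100.0, 20.0)
        pts = [(x, y) for x in g for y in g]
        census = make_census(x=[p[0] for p in pts], y=[p[1] for p in pts],
                             dbh=[5.0] * len(pts),
                             window=PlotWindow(100.0, 100.0))
        surf = focal_abundance_surface(census)
        np.testing.assert_allclose(surf.values, 1.0)

    def test_interior_point_mass_spreads_over_nine_cells(self):
        census = make_census(x=[50.0] * 9, y=[50.0] * 9, dbh=[5.0] * 9,
                             window=PlotWindow(100.0, 100.0))
        surf = focal_abundance_surface(census)
        # the loaded cell (2,2) and its 8 neighbours all average 9/9 = 1
        np.testing.assert_allclose(surf.values[1:4, 1:4], 1.0)
        assert surf.values[0, 0] == 0.0

    def test_corner_truncated_window_divides_by_four(self):
        census = make_census(x=[1.0] * 9, y=[1.0] * 9, dbh=[5.0] * 9,
                             window=PlotWindow(100.0, 100.0))
        surf = focal_abundance_surface(census)
        assert surf.values[0, 0] == pytest.approx(9 / 4)  # 2x2 corner window


class TestRasterSampling:
    @pytest.fixture
    def raster(self):
        return CovariateRaster(np.array([[1.0, 2.0], [3.0, 4.0]]),
                               cell_size=10.0)

    def test_cell_center_value(self, raster):
        assert sample_raster_at_points(raster, [(5.0, 5.0)])[0] == 1.0
        assert sample_raster_at_points(raster, [(15.0, 15.0)])[0] == 4.0

    def test_shared_edge_uses_half_open_rule(self, raster):
        # x = 10 on the shared edge belongs to the higher-index column
        assert sample_raster_at_points(raster, [(10.0, 5.0)])[0] == 2.0
        # the raster's own maximal edge folds in
        assert sample_raster_at_points(raster, [(20.0, 20.0)])[0] == 4.0

    def test_point_outside_extent_raises(self, raster):
        with pytest.raises(StandppError):
            sample_raster_at_points(raster, [(25.0, 5.0)])


class TestNeighborhoodFeatures:
    def test_hand_computed_example(self):
        # focal at origin; neighbours at 5 m and 8 m with dbh 20 and 30
        census = make_census(x=[0.0, 5.0, 0.0], y=[0.0, 0.0, 8.0],
                             dbh=[10.0, 20.0, 30.0])
        feats = neighborhood_features(census, radius=10.0)
        row = feats.iloc[0]
        assert row.nbr_count == 2
        assert row.nbr_mean_dbh == pytest.approx(25.0)
        assert row.nbr_mean_dist == pytest.approx(6.5)
        # sample sd of {5, 8} = 2.1213; CV = 2.1213/6.5
        assert row.nbr_cv_dist == pytest.approx(0.3264, abs=2e-4)
        assert row.border  # within 10 m of the plot edge

    def test_isolated_tree_flagged_undefined(self):
        census = make_census(x=[50.0, 450.0], y=[50.0, 650.0], dbh=[10.0, 12.0])
        feats = neighborhood_features(census, radius=10.0)
        assert feats.iloc[0].nbr_count == 0
        assert np.isnan(feats.iloc[0].nbr_mean_dbh)
        assert np.isnan(feats.iloc[0].nbr_cv_dist)

    def test_matches_brute_force_oracle(self, rng):
        n = 300
        census = make_census(x=rng.uniform(0, 500, n), y=rng.uniform(0, 700, n),
                             dbh=rng.lognormal(2, 0.5, n))
        feats = neighborhood_features(census, radius=10.0)
        oracle = neighborhood_brute(census.table[["x", "y"]].to_numpy(),
                                    census.table["dbh"].to_numpy(), 10.0)
        got = feats[["nbr_count", "nbr_mean_dbh", "nbr_cv_dbh",
                     "nbr_mean_dist", "nbr_cv_dist"]].to_numpy()
        np.testing.assert_allclose(got, oracle, rtol=1e-12, equal_nan=True)


class TestCITree:
    def test_pure_noise_yields_root_only_tree(self):
        # type-I control: splits on 500 noise rows should be rare at alpha=.05
        root_only = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"x1": rng.normal(size=500),
                              "x2": rng.normal(size=500),
                              "x3": rng.choice(list("abcd"), 500)})
            y = rng.normal(size=500)
            tree = fit_citree(X, y, alpha=0.05)
            root_only += tree.root.is_leaf
        assert root_only >= 18  # >= 90% of runs; nominal is >= 95% per test

    def test_noise_free_step_recovers_cutpoint(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = (x > 0).astype(float)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=200)})
        tree = fit_citree(X, y)
        assert tree.root.predictor == "x"
        lo = x[x <= 0].max()
        hi = x[x > 0].min()
        assert lo < tree.root.cutpoint <= hi
        np.testing.assert_allclose(tree.predict(X), y)

    def test_tie_break_prefers_lowest_column_index(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x, "b": x.copy()})  # identical predictors
        y = 2.0 * x + rng.normal(scale=0.1, size=300)
        tree = fit_citree(X, y)
        assert tree.root.predictor == "a"

    def test_constant_response_gives_root_only_tree(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=100), "z": rng.normal(size=100)})
        tree = fit_citree(X, np.full(100, 3.0))
        assert tree.root.is_leaf
        assert tree.root.value == 3.0

    def test_categorical_split_on_level_subset(self, rng):
        levels = np.array(list("abcdef"))
        x = levels[rng.integers(0, 6, 600)]
        y = np.where(np.isin(x, ["a", "b"]), 5.0, 0.0) \
            + rng.normal(scale=0.2, size=600)
        X = pd.DataFrame({"cls": pd.Categorical(x), "noise": rng.normal(size=600)})
        tree = fit_citree(X, y)
        assert tree.root.predictor == "cls"
        assert tree.root.left_levels in (frozenset({"a", "b"}),
                                         frozenset({"c", "d", "e", "f"}))
        pred = tree.predict(X)
        assert abs(pred[np.isin(x, ["a", "b"])].mean() - 5.0) < 0.2


class TestEnsembleImportance:
    def test_signal_dominates_noise_and_noise_scores_near_zero(self, rng):
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1.copy()  # y = x1 exactly
        X = pd.DataFrame({"x1": x1, "x2": x2})
        imp = ensemble_importance(X, y, n_iter=30, rng=rng)
        assert imp.ranking[0] == "x1"
        assert imp.scores["x1"] > 10 * max(imp.scores["x2"], 1e-9)
        se = imp.standard_errors()["x2"]
        assert abs(imp.scores["x2"]) < 2 * se + 1e-9

    def test_importance_invariant_to_affine_predictor_rescaling(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 2 * x1 + x2 + rng.normal(scale=0.3, size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        Xs = pd.DataFrame({"x1": 1000.0 * x1 - 5.0, "x2": x2 / 77.0})
        r1 = ensemble_importance(X, y, n_iter=20,
                                 rng=np.random.default_rng(1)).ranking
        r2 = ensemble_importance(Xs, y, n_iter=20,
                                 rng=np.random.default_rng(1)).ranking
        assert r1 == r2

    def test_per_iteration_scores_average_to_overall(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=200),
                          "x2": rng.normal(size=200)})
        y = X["x1"].to_numpy() + rng.normal(scale=0.5, size=200)
        imp = ensemble_importance(X, y, n_iter=10, rng=rng)
        np.testing.assert_allclose(imp.per_iteration.mean().to_numpy(),
                                   imp.scores.to_numpy(), rtol=1e-12)

    def test_configuration_guards(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        y = rng.normal(size=50)
        with pytest.raises(ConfigurationError):
            ensemble_importance(X, y, n_iter=0, rng=rng)
        with pytest.raises(ConfigurationError):
            ensemble_importance(X[["x1"]], y, n_iter=5, rng=rng)
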