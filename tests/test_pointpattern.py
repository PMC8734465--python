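import numpy as np
import pytest

from standpp import LagSpec, MarkedPattern, PlotWindow, mark_correlation, \
    pcf_estimate, schlather_I
from standpp.errors import DomainError, EstimationError
from standpp.montecarlo import simulate_csr

from conftest import make_census
from oracles import kmm_brute, pcf_brute, schlather_brute

LAGS = LagSpec(r_values=(5.0, 10.0, 15.0, 20.0, 25.0), h=5.0)


@pytest.fixture
def clustered_pattern(small_window, rng):
    """A clumped 300-point marked pattern in the 100 x 100 m window."""
    centers = rng.uniform(0, 100, size=(15, 2))
    pts = centers[rng.integers(0, 15, 300)] + rng.normal(0, 5, size=(300, 2))
    pts = np.clip(pts, 0, 100)
    marks = rng.lognormal(np.log(10), 0.4, 300)
    return MarkedPattern(pts, small_window, marks)


class TestPatternContainer:
    def test_points_outside_window_rejected(self, small_window):
        with pytest.raises(Exception):
            MarkedPattern(np.array([[150.0, 5.0]]), small_window)

    def test_marks_must_align(self, small_window):
        with pytest.raises(Exception):
            MarkedPattern(np.array([[1.0, 1.0]]), small_window,
                          marks=np.array([1.0, 2.0]))

    def test_from_census_one_point_per_individual_keeps_largest_stem(self):
        census = make_census(x=[1, 1, 9], y=[1, 1, 9], dbh=[6.0, 8.0, 3.0],
                             individual=["I1", "I1", "I2"])
        pat = MarkedPattern.from_census(census)
        assert pat.n == 2
        assert sorted(pat.marks.tolist()) == [3.0, 8.0]

    def test_lag_spec_guards(self, small_window):
        with pytest.raises(DomainError):
            LagSpec(r_values=(0.0, 5.0))
        with pytest.raises(DomainError):
            LagSpec(r_values=(5.0, 100.0)).check_window(small_window)
        LagSpec(r_values=(5.0, 100.0), allow_large_r=True).check_window(small_window)


class TestPairCorrelation:
    def test_needs_two_points(self, small_window):
        with pytest.raises(EstimationError):
            pcf_estimate(MarkedPattern(np.array([[1.0, 1.0]]), small_window))

    def test_matches_brute_force_oracle(self, clustered_pattern):
        est = pcf_estimate(clustered_pattern, LAGS)
        oracle = pcf_brute(clustered_pattern.points, clustered_pattern.window,
                           LAGS.r, LAGS.h)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_csr_expectation_near_one(self, rng):
        window = PlotWindow(500.0, 700.0)
        spec = LagSpec(tuple(float(r) for r in range(10, 51)), h=5.0)
        means = [pcf_estimate(simulate_csr(2000, window,
                                           np.random.default_rng(seed)),
                              spec).values.mean()
                 for seed in range(5)]
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_lattice_has_no_pairs_at_off_lattice_distance(self):
        window = PlotWindow(100.0, 100.0)
        g = np.arange(0.0, 101.0, 20.0)
        pts = np.array([[x, y] for x in g for y in g])
        est = pcf_estimate(MarkedPattern(pts, window),
                           LagSpec(r_values=(10.0,), h=5.0))
        assert est.values[0] == 0.0
        assert est.n_pairs[0] == 0

    def test_permutation_invariance(self, clustered_pattern, rng):
        est = pcf_estimate(clustered_pattern, LAGS)
        perm = rng.permutation(clustered_pattern.n)
        shuffled = MarkedPattern(clustered_pattern.points[perm],
                                 clustered_pattern.window,
                                 clustered_pattern.marks[perm])
        est2 = pcf_estimate(shuffled, LAGS)
        np.testing.assert_allclose(est.values, est2.values, atol=1e-10)


class TestMarkCorrelation:
    def test_matches_brute_force_oracle(self, clustered_pattern):
        est = mark_correlation(clustered_pattern, LAGS)
        oracle = kmm_brute(clustered_pattern.points, clustered_pattern.marks,
                           LAGS.r, LAGS.h)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_constant_marks_give_exactly_one(self, small_window, rng):
        pts = rng.uniform(0, 100, size=(80, 2))
        pat = MarkedPattern(pts, small_window, np.full(80, 7.0))
        est = mark_correlation(pat, LAGS)
        has_pairs = est.n_pairs > 0
        np.testing.assert_allclose(est.values[has_pairs], 1.0, atol=1e-12)

    def test_iid_marks_near_one_on_clustered_pattern(self, clustered_pattern):
        est = mark_correlation(clustered_pattern, LAGS)
        assert np.all(np.abs(est.values - 1.0) < 0.15)

    def test_crowding_marks_below_one_at_short_lags(self, small_window, rng):
        centers = rng.uniform(0, 100, size=(10, 2))
        pts = np.clip(centers[rng.integers(0, 10, 400)]
                      + rng.normal(0, 4, size=(400, 2)), 0, 100)
        from scipy.spatial import cKDTree
        counts = np.array([len(nb) - 1 for nb in
                           cKDTree(pts).query_ball_point(pts, 10.0)])
        marks = np.maximum(50.0 - counts, 1.0)
        pat = MarkedPattern(pts, small_window, marks)
        spec = LagSpec(r_values=(5.0, 8.0), h=3.0)
        est = mark_correlation(pat, spec)
        oracle = kmm_brute(pts, marks, spec.r, spec.h)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)
        assert np.all(est.values < 1.0)

    def test_scale_invariance_of_marks(self, clustered_pattern):
        est = mark_correlation(clustered_pattern, LAGS)
        scaled = MarkedPattern(clustered_pattern.points,
                               clustered_pattern.window,
                               clustered_pattern.marks * 37.5)
        est2 = mark_correlation(scaled, LAGS)
        np.testing.assert_allclose(est.values, est2.values, rtol=1e-10)

    def test_requires_marks(self, small_window, rng):
        pat = MarkedPattern(rng.uniform(0, 100, size=(10, 2)), small_window)
        with pytest.raises(EstimationError):
            mark_correlation(pat, LAGS)


class TestSchlatherI:
    @pytest.fixture
    def two_patterns(self, small_window, rng):
        p1 = MarkedPattern(rng.uniform(0, 100, size=(120, 2)), small_window,
                           rng.lognormal(np.log(12), 0.5, 120))
        p2 = MarkedPattern(rng.uniform(0, 100, size=(150, 2)), small_window,
                           rng.lognormal(np.log(8), 0.5, 150))
        return p1, p2

    def test_matches_brute_force_oracle(self, two_patterns):
        p1, p2 = two_patterns
        est = schlather_I(p1, p2, LAGS)
        oracle = schlather_brute(p1.points, p1.marks, p2.points, p2.marks,
                                 LAGS.r, LAGS.h)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_independent_marks_near_zero(self, two_patterns):
        p1, p2 = two_patterns
        est = schlather_I(p1, p2, LAGS)
        assert np.all(np.abs(est.values) < 0.25)

    def test_shared_gradient_approaches_plus_one(self, rng):
        window = PlotWindow(500.0, 500.0)
        pts1 = rng.uniform(0, 500, size=(200, 2))
        pts2 = rng.uniform(0, 500, size=(200, 2))
        p1 = MarkedPattern(pts1, window, pts1[:, 0])
        p2 = MarkedPattern(pts2, window, pts2[:, 0])
        spec = LagSpec(r_values=(5.0, 10.0), h=5.0)
        est = schlather_I(p1, p2, spec)
        oracle = schlather_brute(pts1, pts1[:, 0], pts2, pts2[:, 0],
                                 spec.r, spec.h)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)
        assert np.all(est.values > 0.9)

    def test_opposed_gradients_approach_minus_one(self, rng):
        window = PlotWindow(500.0, 500.0)
        pts1 = rng.uniform(0, 500, size=(200, 2))
        pts2 = rng.uniform(0, 500, size=(200, 2))
        p1 = MarkedPattern(pts1, window, pts1[:, 0])
        p2 = MarkedPattern(pts2, window, 600.0 - pts2[:, 0])
        est = schlather_I(p1, p2, LagSpec(r_values=(5.0, 10.0), h=5.0))
        assert np.all(est.values < -0.9)

    def test_affine_invariance_and_sign_flip(self, two_patterns):
        p1, p2 = two_patterns
        base = schlather_I(p1, p2, LAGS).values
        p2_aff = MarkedPattern(p2.points, p2.window, 3.0 * p2.marks + 11.0)
        np.testing.assert_allclose(schlather_I(p1, p2_aff, LAGS).values,
                                   base, rtol=1e-9, atol=1e-12)
        p2_neg = MarkedPattern(p2.points, p2.window, 100.0 - 2.0 * p2.marks)
        np.testing.assert_allclose(schlather_I(p1, p2_neg, LAGS).values,
                                   -base, rtol=1e-9, atol=1e-12)

    def test_same_pattern_excludes_self_pairs(self, two_patterns):
        p1, _ = two_patterns
        est = schlather_I(p1, p1, LAGS)
        oracle = schlather_brute(p1.points, p1.marks, p1.points, p1.marks,
                                 LAGS.r, LAGS.h, same=True)
        np.testing.assert_allclose(est.values, oracle, atol=1e-10)

    def test_zero_variance_marks_rejected(self, small_window, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        flat = MarkedPattern(pts, small_window, np.full(20, 3.0))
        other = MarkedPattern(pts, small_window, rng.uniform(1, 5, 20))
        with pytest.raises(EstimationError):
            schlather_I(flat, other, LAGS)
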