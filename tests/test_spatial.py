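"""Spatial statistics: G/F/K estimators, CSR envelopes, dead space."""

import numpy as np
import pytest

from synquant import spatial, synthgen
from synquant.geometry import PointPattern, Window3D

from oracles import naive_f, naive_g, naive_k, naive_nn_distances


class TestNN:
    def test_two_points(self):
        w = Window3D(extents=(2000.0,) * 3)
        p = PointPattern([[500, 500, 500], [1000, 500, 500]], w)
        d = spatial.nn_distances(p)
        np.testing.assert_allclose(d, [500.0, 500.0])
        assert spatial.nn_mean(p) == 500.0

    def test_single_point_rejected(self):
        w = Window3D(extents=(100.0,) * 3)
        with pytest.raises(ValueError):
            spatial.nn_distances(PointPattern([[1, 1, 1]], w))

    def test_matches_naive(self, hardcore_pattern):
        sub = PointPattern(hardcore_pattern.points[:40], hardcore_pattern.window)
        np.testing.assert_allclose(spatial.nn_distances(sub),
                                   naive_nn_distances(sub.points), rtol=1e-12)

    def test_csr_guarded_mean_matches_closed_form(self, cube_window):
        import math

        cf = math.gamma(4 / 3) * (4 * np.pi * 0.5e-9 / 3) ** (-1 / 3)
        means = [spatial.nn_mean(synthgen.simulate_csr_pattern(0.5, cube_window, seed=s),
                                 guard_nm=2000.0)
                 for s in range(30)]
        assert np.mean(means) == pytest.approx(cf, rel=0.02)


@pytest.fixture(scope="module")
def small_patterns():
    w = Window3D(extents=(5000.0,) * 3)
    pats = [synthgen.simulate_binomial_pattern(n, w, seed=n) for n in (5, 20, 50)]
    pats.append(synthgen.simulate_hardcore_pattern(0.3, 300.0, w, seed=4))
    return pats


class TestOracleEquivalence:
    """Estimators agree exactly with naive O(n²) implementations at n ≤ 50."""

    @pytest.mark.parametrize("correction", ["border", "none"])
    def test_g(self, small_patterns, correction):
        r = np.linspace(0, 1200, 25)
        for p in small_patterns:
            est = spatial.g_function(p, r, correction=correction).estimate
            np.testing.assert_allclose(
                est, naive_g(p.points, p.window, r, correction), atol=1e-12)

    @pytest.mark.parametrize("correction", ["border", "none"])
    def test_f(self, small_patterns, correction):
        r = np.linspace(0, 1200, 25)
        for p in small_patterns:
            res = spatial.f_function(p, r, n_test_points=125, correction=correction)
            test_pts = spatial._test_point_grid(p.window, 125)
            np.testing.assert_allclose(
                res.estimate, naive_f(p.points, test_pts, p.window, r, correction),
                atol=1e-12)

    def test_k(self, small_patterns):
        r = np.linspace(0, 1200, 25)
        for p in small_patterns:
            est = spatial.k_function(p, r).estimate
            np.testing.assert_allclose(est, naive_k(p.points, p.window, r),
                                       rtol=1e-10)


class TestAgainstCSRTheory:
    def test_g_close_to_closed_form_at_large_n(self):
        w = Window3D(extents=(10_000.0,) * 3)
        p = synthgen.simulate_binomial_pattern(1_000, w, seed=0)
        g = spatial.g_function(p)
        valid = ~np.isnan(g.estimate)
        assert np.max(np.abs(g.estimate[valid] - g.theoretical[valid])) < 0.06

    def test_k_close_to_volume_formula(self):
        w = Window3D(extents=(10_000.0,) * 3)
        p = synthgen.simulate_binomial_pattern(1_000, w, seed=1)
        k = spatial.k_function(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(k.estimate[1:] - k.theoretical[1:]) / k.theoretical[-1]
        assert np.nanmax(rel) < 0.05

    def test_f_equals_g_in_distribution_under_csr(self, cube_window):
        diffs = []
        for s in range(10):
            p = synthgen.simulate_csr_pattern(0.5, cube_window, seed=60 + s)
            g = spatial.g_function(p)
            f = spatial.f_function(p, r_grid=g.r)
            valid = ~np.isnan(g.estimate) & ~np.isnan(f.estimate)
            diffs.append(np.mean(g.estimate[valid] - f.estimate[valid]))
        assert abs(np.mean(diffs)) < 0.02

    def test_hardcore_f_exceeds_csr_f(self, cube_window):
        """More regular patterns empty space faster: F̂_hc ≥ F̂_CSR at mid r."""
        r = np.array([0.0, 600.0])
        hc, csr = [], []
        for s in range(8):
            ph = synthgen.simulate_hardcore_pattern(0.5, 250.0, cube_window, seed=s)
            pc = synthgen.simulate_binomial_pattern(ph.n, cube_window, seed=1000 + s)
            hc.append(spatial.f_function(ph, r).estimate[1])
            csr.append(spatial.f_function(pc, r).estimate[1])
        assert np.mean(hc) >= np.mean(csr)


class TestShapeInvariants:
    def test_bounds_and_monotonicity(self, csr_pattern):
        g = spatial.g_function(csr_pattern, correction="none")
        f = spatial.f_function(csr_pattern, correction="none")
        for est in (g, f):
            assert np.all(est.estimate >= 0) and np.all(est.estimate <= 1)
            assert np.all(np.diff(est.estimate) >= 0)
        k = spatial.k_function(csr_pattern)
        assert np.all(k.estimate >= 0)
        assert np.all(np.diff(k.estimate) >= -1e-9)

    def test_corrected_estimates_stay_in_unit_interval(self, hardcore_pattern):
        for fn in (spatial.g_function, spatial.f_function):
            est = fn(hardcore_pattern).estimate
            valid = ~np.isnan(est)
            assert np.all(est[valid] >= 0) and np.all(est[valid] <= 1)

    def test_zero_radius_values(self, csr_pattern):
        r = np.array([0.0, 500.0])
        assert spatial.g_function(csr_pattern, r).estimate[0] == 0.0
        assert spatial.k_function(csr_pattern, r).estimate[0] == 0.0

    def test_r_grid_truncated_with_warning(self, csr_pattern):
        r = np.linspace(0, 20_000, 50)
        with pytest.warns(UserWarning, match="truncated"):
            g = spatial.g_function(csr_pattern, r)
        assert g.r[-1] <= 5_000.0


class TestDeadSpace:
    def test_hardcore_dead_space_at_twice_radius(self, hardcore_pattern):
        g = spatial.g_function(hardcore_pattern)
        ds = spatial.dead_space_radius(g)
        grid_step = g.r[1] - g.r[0]
        assert abs(ds - 500.0) <= 2 * grid_step
        # Ĝ is identically zero below the hard-core diameter
        assert np.all(np.nan_to_num(g.estimate[g.r < 500.0]) == 0.0)

    def test_csr_dead_space_shrinks_with_n(self, cube_window):
        small = synthgen.simulate_binomial_pattern(50, cube_window, seed=2)
        big = synthgen.simulate_binomial_pattern(2_000, cube_window, seed=2)
        r = np.linspace(0, 2_500, 512)
        ds_small = spatial.dead_space_radius(spatial.g_function(small, r))
        ds_big = spatial.dead_space_radius(spatial.g_function(big, r))
        assert ds_big < ds_small

    def test_positive_at_first_grid_point_returns_zero(self, cube_window):
        p = synthgen.simulate_binomial_pattern(300, cube_window, seed=3)
        # grid starting above the minimum NN distance
        r = np.linspace(spatial.nn_distances(p).min() + 1, 2_000, 10)
        assert spatial.dead_space_radius(spatial.g_function(p, r)) == 0.0


class TestEnvelope:
    def test_default_simulation_count_is_100(self, csr_pattern):
        env = spatial.csr_envelope(csr_pattern, "G", seed=1)
        assert env.n_simulations == 100

    def test_csr_input_mostly_consistent(self, cube_window):
        verdicts = []
        for s in range(10):
            p = synthgen.simulate_csr_pattern(0.5, cube_window, seed=300 + s)
            env = spatial.csr_envelope(p, "G", n_sim=100, seed=400 + s)
            verdicts.append(env.verdict == "consistent with CSR")
        assert sum(verdicts) >= 9

    def test_clustered_pattern_exits_g_envelope(self, cube_window):
        # Thomas-like cluster process: parents + tight Gaussian offspring
        rng = np.random.default_rng(8)
        parents = cube_window.lo + rng.random((12, 3)) * np.asarray(cube_window.extents)
        pts = np.concatenate([
            par + rng.normal(0, 150.0, size=(40, 3)) for par in parents])
        pts = pts[cube_window.contains(pts)]
        p = PointPattern(pts, cube_window)
        env = spatial.csr_envelope(p, "G", n_sim=100, seed=9)
        assert env.verdict == "departs from CSR"
        assert env.outside_fraction > 0.05

    def test_envelope_bounds_enclose_theory(self, csr_pattern):
        env = spatial.csr_envelope(csr_pattern, "K", n_sim=50, seed=2)
        inside = (env.theoretical >= env.lo - 1e-9) & (env.theoretical <= env.hi + 1e-9)
        assert inside.mean() > 0.9
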