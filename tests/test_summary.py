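import math

import numpy as np
import pytest

from tmespat import (IntensityEstimate, PointPattern, RGrid, Window, g_function,
                     k_function, kernel_intensity, pcf, quadrat_test,
                     simulate_poisson, simulate_thomas)

from .conftest import oracle_g, oracle_k


class TestQuadrat:
    def _pattern_with_quadrant_counts(self, counts):
        """Place `counts` points in the four quadrants (ll, lr, ul, ur)."""
        rng = np.random.default_rng(0)
        xs, ys = [], []
        offsets = [(0, 0), (0.5, 0), (0, 0.5), (0.5, 0.5)]
        for c, (ox, oy) in zip(counts, offsets):
            xs.append(ox + 0.01 + 0.48 * rng.uniform(size=c))
            ys.append(oy + 0.01 + 0.48 * rng.uniform(size=c))
        return PointPattern(np.concatenate(xs), np.concatenate(ys), Window.unit_square())

    def test_uniform_counts_give_zero_statistic(self):
        p = self._pattern_with_quadrant_counts([5, 5, 5, 5])
        qt = quadrat_test(p, 2, 2)
        assert qt.statistic == pytest.approx(0.0, abs=1e-12)
        assert qt.p_value == pytest.approx(1.0)
        assert qt.counts.sum() == p.n

    def test_concentrated_counts_hand_computed(self):
        # counts (10, 0, 0, 10), E = 5 each: statistic = 4 * 25/5 = 20, df 3
        p = self._pattern_with_quadrant_counts([10, 0, 0, 10])
        qt = quadrat_test(p, 2, 2)
        assert qt.statistic == pytest.approx(20.0, abs=1e-9)
        assert qt.df == 3
        assert qt.residuals[0, 0] == pytest.approx((10 - 5) / math.sqrt(5))

    def test_clustered_pattern_detected(self):
        detected = 0
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = simulate_thomas(Window.unit_square(), 20.0, 0.03, 20.0, seed=rng)
            if quadrat_test(p, 5, 5).p_value < 0.05:
                detected += 1
        assert detected >= 95

    def test_low_expected_counts_warn(self, unit_square):
        p = PointPattern(np.array([0.5, 0.6]), np.array([0.5, 0.6]), unit_square)
        qt = quadrat_test(p, 3, 3)
        assert "warning" in qt.metadata

    def test_disc_window_expected_proportional_to_clipped_area(self):
        w = Window.disc(0, 0, 1.0)
        p = simulate_poisson(w, n_fixed=100, seed=1)
        qt = quadrat_test(p, 3, 3)
        assert qt.expected.sum() == pytest.approx(100.0, rel=1e-9)
        assert qt.expected[1, 1] > qt.expected[0, 0]


class TestG:
    def test_hand_enumerated_toy(self, toy3):
        g = g_function(toy3, RGrid(np.linspace(0, 0.2, 201)))
        assert g.at(0.2) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_zero_at_origin(self, toy3, grid_025):
        assert g_function(toy3, grid_025).estimate[0] == 0.0

    def test_needs_two_points(self, unit_square):
        p = PointPattern(np.array([0.5]), np.array([0.5]), unit_square)
        with pytest.raises(ValueError):
            g_function(p)

    def test_matches_brute_force(self, unit_square, grid_025):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(5, 20))
            x, y = unit_square.sample_uniform(n, rng)
            p = PointPattern(x, y, unit_square)
            est = g_function(p, grid_025).estimate
            exp = oracle_g(p, grid_025.values)
            np.testing.assert_allclose(est, exp, atol=1e-10)

    def test_bounded_by_one(self, unit_square, grid_025):
        p = simulate_poisson(unit_square, n_fixed=100, seed=8)
        g = g_function(p, grid_025)
        assert np.nanmax(g.estimate) <= 1.0 + 1e-12

    def test_inhomogeneous_monotone_and_referenced(self, unit_square, grid_025):
        p = simulate_poisson(unit_square, n_fixed=200, seed=13)
        inten = kernel_intensity(p, bandwidth=0.125)
        g = g_function(p, grid_025, "inhomogeneous", inten)
        assert np.all(np.diff(g.estimate) >= -1e-12)
        lam_min = inten.lambda_min
        np.testing.assert_allclose(
            g.theoretical, 1 - np.exp(-lam_min * np.pi * grid_025.values**2)
        )

    def test_inhomogeneous_requires_intensity(self, toy3, grid_025):
        with pytest.raises(ValueError):
            g_function(toy3, grid_025, "inhomogeneous")


class TestK:
    def test_hand_enumerated_toy(self, toy3, grid_025):
        # only the pair at distance 0.2 counts at r=0.25; translation
        # overlap (1-0.2)*1 = 0.8 gives weight 1.25 per ordered pair:
        # K = (1/6) * (1.25 + 1.25)
        k = k_function(toy3, grid_025)
        assert k.at(0.25) == pytest.approx(0.41667, abs=1e-5)

    def test_zero_at_origin(self, toy3, grid_025):
        assert k_function(toy3, grid_025).estimate[0] == 0.0

    def test_monotone(self, unit_square, grid_025):
        p = simulate_poisson(unit_square, n_fixed=100, seed=21)
        k = k_function(p, grid_025)
        assert np.all(np.diff(k.estimate) >= -1e-12)

    def test_matches_brute_force(self, unit_square, grid_025):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 20))
            x, y = unit_square.sample_uniform(n, rng)
            p = PointPattern(x, y, unit_square)
            np.testing.assert_allclose(
                k_function(p, grid_025).estimate,
                oracle_k(p, grid_025.values),
                atol=1e-10,
            )

    def test_constant_intensity_reproduces_homogeneous(self, unit_square, grid_025):
        rng = np.random.default_rng(14)
        for _ in range(5):
            p = simulate_poisson(unit_square, n_fixed=int(rng.integers(10, 60)), seed=rng)
            inten = IntensityEstimate.constant(p.intensity, p.n)
            kh = k_function(p, grid_025, "homogeneous")
            ki = k_function(p, grid_025, "inhomogeneous", inten)
            np.testing.assert_allclose(ki.estimate, kh.estimate, atol=1e-9)


class TestPcf:
    def test_nan_at_origin(self, unit_square, grid_025):
        p = simulate_poisson(unit_square, n_fixed=50, seed=3)
        assert np.isnan(pcf(p, grid_025).estimate[0])

    def test_zero_when_no_close_pairs(self, unit_square):
        p = PointPattern(np.array([0.05, 0.95]), np.array([0.05, 0.95]), unit_square)
        g = pcf(p, RGrid(np.linspace(0, 0.2, 101)), pcf_bandwidth=0.01)
        assert np.nanmax(np.abs(g.estimate)) == 0.0

    def test_derivative_of_k_tracks_pcf_on_csr(self, unit_square):
        r = RGrid(np.linspace(0, 0.25, 251))
        rng = np.random.default_rng(6)
        gs, dks = [], []
        for _ in range(20):
            p = simulate_poisson(unit_square, n_fixed=300, seed=rng)
            k = k_function(p, r).estimate
            dk = np.gradient(k, r.values) / (2 * np.pi * np.maximum(r.values, 1e-12))
            gs.append(pcf(p, r).estimate)
            dks.append(dk)
        interior = slice(60, 220)
        mean_g = np.mean(gs, axis=0)[interior]
        mean_dk = np.mean(dks, axis=0)[interior]
        assert np.max(np.abs(mean_g - mean_dk)) < 0.1

    def test_bad_bandwidth_rejected(self, toy3, grid_025):
        with pytest.raises(ValueError):
            pcf(toy3, grid_025, pcf_bandwidth=-1.0)
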