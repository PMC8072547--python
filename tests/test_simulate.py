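import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmespat import (CellClass, MicroenvConfig, RGrid, Window, pcf,
                     simulate_inhibited, simulate_inhomogeneous_poisson,
                     simulate_microenvironment, simulate_poisson, simulate_thomas)


class TestPoisson:
    def test_fixed_zero_is_empty(self, unit_square):
        assert simulate_poisson(unit_square, n_fixed=0, seed=0).n == 0

    def test_same_seed_identical(self, unit_square):
        p1 = simulate_poisson(unit_square, intensity=200, seed=5)
        p2 = simulate_poisson(unit_square, intensity=200, seed=5)
        assert np.array_equal(p1.x, p2.x) and np.array_equal(p1.y, p2.y)

    def test_count_moments(self, unit_square):
        counts = [simulate_poisson(unit_square, intensity=400, seed=s).n for s in range(500)]
        assert abs(np.mean(counts) - 400) < 3 * math.sqrt(400 / 500)

    def test_exactly_one_size_argument(self, unit_square):
        with pytest.raises(ValueError):
            simulate_poisson(unit_square, intensity=10, n_fixed=5)


class TestInhomogeneousPoisson:
    def test_constant_function_matches_homogeneous_counts(self, unit_square):
        ci = [
            simulate_inhomogeneous_poisson(
                unit_square, lambda x, y: np.full_like(x, 300.0), 300.0, seed=s
            ).n
            for s in range(500)
        ]
        ch = [simulate_poisson(unit_square, intensity=300, seed=10_000 + s).n for s in range(500)]
        assert abs(np.mean(ci) - np.mean(ch)) < 3 * math.sqrt(300 / 500) * math.sqrt(2)
        assert np.var(ci) == pytest.approx(np.var(ch), rel=0.3)

    def test_linear_ramp_half_ratio(self, unit_square):
        left = right = 0
        for s in range(500):
            p = simulate_inhomogeneous_poisson(unit_square, lambda x, y: 40.0 * x, 40.0, seed=s)
            left += np.sum(p.x < 0.5)
            right += np.sum(p.x >= 0.5)
        assert right / left == pytest.approx(3.0, rel=0.1)

    def test_zero_function_empty(self, unit_square):
        p = simulate_inhomogeneous_poisson(unit_square, lambda x, y: np.zeros_like(x), 1.0, seed=1)
        assert p.n == 0

    def test_bound_violation_rejected(self, unit_square):
        with pytest.raises(ValueError):
            simulate_inhomogeneous_poisson(
                unit_square, lambda x, y: np.full_like(x, 500.0), 100.0, seed=2
            )


class TestThomas:
    def test_zero_offspring_empty(self, unit_square):
        assert simulate_thomas(unit_square, 20.0, 0.05, 0.0, seed=0).n == 0

    def test_deterministic(self, unit_square):
        p1 = simulate_thomas(unit_square, 20, 0.03, 10, seed=4)
        p2 = simulate_thomas(unit_square, 20, 0.03, 10, seed=4)
        assert np.array_equal(p1.x, p2.x)

    def test_large_cluster_sd_approaches_csr(self, unit_square):
        # cluster spread comparable to the window: pcf ~ 1
        r = RGrid(np.linspace(0, 0.25, 126))
        rng = np.random.default_rng(5)
        vals = [
            pcf(simulate_thomas(unit_square, 50, 1.0, 10, seed=rng), r).estimate
            for _ in range(40)
        ]
        mean = np.mean(vals, axis=0)
        interior = r.values >= 0.05
        assert np.max(np.abs(mean[interior] - 1.0)) < 0.15


class TestInhibited:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), hc=st.floats(0.02, 0.2))
    def test_min_distance_at_least_hardcore(self, seed, hc):
        p = simulate_inhibited(Window.unit_square(), 500.0, hc, seed=seed)
        if p.n >= 2:
            d = p.pairwise_distances()
            np.fill_diagonal(d, np.inf)
            assert d.min() >= hc - 1e-12

    def test_pcf_below_one_inside_hardcore(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        r = RGrid(np.linspace(0, 100, 101))
        rng = np.random.default_rng(6)
        vals = [
            pcf(simulate_inhibited(w, 1e-3, 25.0, seed=rng), r).estimate
            for _ in range(50)
        ]
        inside = (r.values > 5) & (r.values < 25)
        mean = np.nanmean(np.asarray(vals)[:, inside], axis=0)
        assert np.all(mean < 1.0)

    def test_huge_hardcore_keeps_at_most_one(self, unit_square):
        p = simulate_inhibited(unit_square, 100.0, 5.0, seed=7)
        assert p.n <= 1


class TestMicroenvironment:
    def test_deterministic_given_seed(self):
        p1 = simulate_microenvironment(seed=1)
        p2 = simulate_microenvironment(seed=1)
        assert np.array_equal(p1.x, p2.x) and np.array_equal(p1.marks, p2.marks)

    def test_all_classes_present_and_counts_match_metadata(self):
        p = simulate_microenvironment(seed=1)
        counts = p.counts_by_class()
        for c in CellClass:
            assert counts[c] > 0
            assert counts[c] == p.metadata["counts"][c.name]

    def test_total_cell_count_near_twenty_thousand(self):
        totals = [simulate_microenvironment(seed=s).n for s in range(20)]
        assert abs(np.mean(totals) - 20_000) / 20_000 < 0.25

    def test_retention_ratio_reflected_in_ctl_densities(self):
        p = simulate_microenvironment(seed=11)
        md = p.metadata
        ratio = (md["ctl_in_core"] / md["area_core"]) / (md["ctl_in_rim"] / md["area_rim"])
        assert ratio == pytest.approx(0.2, rel=0.2)

    def test_null_config_equalises_retention(self):
        cfg = MicroenvConfig().null()
        assert cfg.retention_hypoxic == cfg.retention_normoxic
        p = simulate_microenvironment(cfg, seed=3)
        md = p.metadata
        ratio = (md["ctl_in_core"] / md["area_core"]) / (md["ctl_in_rim"] / md["area_rim"])
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_scaled_down_shrinks_counts(self):
        p = simulate_microenvironment(MicroenvConfig().scaled_down(), seed=2)
        assert 3000 < p.n < 8000

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            MicroenvConfig(retention_hypoxic=1.5)

    def test_points_inside_window(self):
        p = simulate_microenvironment(seed=4)
        assert np.all(p.window.contains(p.x, p.y))


class TestArchetypeDirections:
    def test_clustered_above_and_inhibited_below_csr(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        r = RGrid(np.linspace(0, 100, 101))
        rng = np.random.default_rng(8)
        above = below = 0
        reps = 20
        for _ in range(reps):
            pt = simulate_thomas(w, 30e-6, 20.0, 30.0, seed=rng)
            gi = pcf(pt, r).estimate
            band = (r.values > 10) & (r.values < 50)
            above += np.nanmean(gi[band]) > 1.0
            pi_ = simulate_inhibited(w, 1e-3, 25.0, seed=rng)
            gg = pcf(pi_, r).estimate
            inside = (r.values > 5) & (r.values < 25)
            below += np.nanmean(gg[inside]) < 1.0
        assert above >= 0.9 * reps
        assert below >= 0.9 * reps
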