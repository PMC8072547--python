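import numpy as np
import pytest

from tmespat import (CellClass, CrossSpec, IntensityEstimate, PointPattern, RGrid,
                     Window, k_cross, pcf_cross, simulate_poisson)

from .conftest import oracle_k_cross, random_marked_pattern

CTL, NORM, HYP = CellClass.CTL, CellClass.NORMOXIC_TUMOR, CellClass.HYPOXIC_TUMOR


class TestKCross:
    def test_small_class_rejected_by_name(self, unit_square, grid_025):
        p = PointPattern(
            np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]), unit_square,
            np.array([1, 2, 2]),
        )
        with pytest.raises(ValueError, match="CTL"):
            k_cross(p, CrossSpec(CTL, NORM), grid_025)

    def test_same_class_rejected(self):
        with pytest.raises(ValueError):
            CrossSpec(CTL, CTL)

    def test_hand_enumerable_toy_matches_oracle(self, unit_square):
        # two subjects near the middle, two targets; indicators at r=0.15
        # enumerable by hand (one close subject-target pair each way)
        p = PointPattern(
            np.array([0.5, 0.45, 0.5, 0.9]),
            np.array([0.45, 0.40, 0.55, 0.9]),
            unit_square,
            np.array([1, 1, 2, 2]),
        )
        r = RGrid(np.linspace(0, 0.15, 151))
        est = k_cross(p, CrossSpec(CTL, NORM), r).estimate
        exp = oracle_k_cross(p, CTL, NORM, r.values)
        np.testing.assert_allclose(est, exp, atol=1e-10)

    def test_matches_oracle_on_random_patterns(self, grid_025):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_marked_pattern(rng)
            est = k_cross(p, CrossSpec(CTL, NORM), grid_025).estimate
            exp = oracle_k_cross(p, CTL, NORM, grid_025.values)
            np.testing.assert_allclose(est, exp, atol=1e-10)

    def test_homogeneous_symmetry(self, grid_025):
        rng = np.random.default_rng(4)
        p = random_marked_pattern(rng, n=30)
        k12 = k_cross(p, CrossSpec(CTL, NORM), grid_025).estimate
        k21 = k_cross(p, CrossSpec(NORM, CTL), grid_025).estimate
        np.testing.assert_allclose(k12, k21, atol=1e-10)

    def test_inhomogeneous_symmetry_with_fixed_intensities(self, grid_025):
        rng = np.random.default_rng(5)
        p = random_marked_pattern(rng, n=30)
        parts = p.split_by_mark()
        i1 = IntensityEstimate.constant(parts[CTL].intensity * 1.3, parts[CTL].n)
        i2 = IntensityEstimate.constant(parts[NORM].intensity * 0.7, parts[NORM].n)
        k12 = k_cross(p, CrossSpec(CTL, NORM), grid_025, "inhomogeneous", i1, i2).estimate
        k21 = k_cross(p, CrossSpec(NORM, CTL), grid_025, "inhomogeneous", i2, i1).estimate
        np.testing.assert_allclose(k12, k21, atol=1e-9)

    def test_constant_intensity_reproduces_homogeneous(self, grid_025):
        rng = np.random.default_rng(6)
        p = random_marked_pattern(rng, n=40)
        parts = p.split_by_mark()
        i1 = IntensityEstimate.constant(parts[CTL].intensity, parts[CTL].n)
        i2 = IntensityEstimate.constant(parts[NORM].intensity, parts[NORM].n)
        kh = k_cross(p, CrossSpec(CTL, NORM), grid_025).estimate
        ki = k_cross(p, CrossSpec(CTL, NORM), grid_025, "inhomogeneous", i1, i2).estimate
        np.testing.assert_allclose(ki, kh, atol=1e-9)

    def test_displaced_copy_jumps_at_offset(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        rng = np.random.default_rng(7)
        x, y = Window.rectangle(10, 990, 10, 990).sample_uniform(60, rng)
        # every target sits exactly 5 µm from one subject
        px = np.concatenate([x, x + 5.0])
        py = np.concatenate([y, y])
        p = PointPattern(px, py, w, np.repeat([1, 2], 60))
        r = RGrid(np.linspace(0, 10, 101))
        k = k_cross(p, CrossSpec(CTL, NORM), r)
        jump = k.at(5.5) - k.at(4.5)
        assert jump > 5 * max(k.at(4.5), 1.0)

    def test_target_thinning_leaves_mean_invariant(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        r = RGrid(np.linspace(0, 100, 101))
        rng = np.random.default_rng(8)
        full, thin = [], []
        for _ in range(50):
            xs, ys = w.sample_uniform(100, rng)
            xt, yt = w.sample_uniform(200, rng)
            marks = np.repeat([1, 2], [100, 200])
            p = PointPattern(np.r_[xs, xt], np.r_[ys, yt], w, marks)
            full.append(k_cross(p, CrossSpec(CTL, NORM), r).at(50))
            keep = rng.uniform(size=200) < 0.5
            if keep.sum() >= 2:
                p2 = PointPattern(
                    np.r_[xs, xt[keep]], np.r_[ys, yt[keep]], w,
                    np.repeat([1, 2], [100, int(keep.sum())]),
                )
                thin.append(k_cross(p2, CrossSpec(CTL, NORM), r).at(50))
        truth = np.pi * 50**2
        assert np.mean(full) == pytest.approx(truth, rel=0.05)
        assert np.mean(thin) == pytest.approx(np.mean(full), rel=0.10)


class TestPcfCross:
    def test_independent_csr_near_one(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        r = RGrid.default(w)
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(50):
            x1, y1 = w.sample_uniform(300, rng)
            x2, y2 = w.sample_uniform(300, rng)
            p = PointPattern(np.r_[x1, x2], np.r_[y1, y2], w, np.repeat([1, 2], 300))
            vals.append(pcf_cross(p, CrossSpec(CTL, NORM), r).estimate)
        mean = np.mean(vals, axis=0)
        interior = r.values >= 20
        assert np.max(np.abs(mean[interior] - 1.0)) < 0.05

    def test_hard_exclusion_suppresses_small_r(self):
        w = Window.rectangle(0, 1000, 0, 1000)
        r = RGrid.default(w)
        rng = np.random.default_rng(10)
        hits = 0
        reps = 30
        for _ in range(reps):
            xs, ys = w.sample_uniform(150, rng)
            xt, yt = w.sample_uniform(600, rng)
            dmin = np.min(np.hypot(xt[:, None] - xs[None, :], yt[:, None] - ys[None, :]), axis=1)
            keep = dmin > 30.0
            p = PointPattern(
                np.r_[xs, xt[keep]], np.r_[ys, yt[keep]], w,
                np.repeat([1, 2], [150, int(keep.sum())]),
            )
            g = pcf_cross(p, CrossSpec(CTL, NORM), r)
            band = (r.values > 5) & (r.values < 25)
            if np.nanmax(g.estimate[band]) < 0.2:
                hits += 1
        assert hits >= 0.9 * reps

    def test_small_bandwidth_concentrates_at_pair_distance(self, unit_square):
        p = PointPattern(
            np.array([0.5, 0.5, 0.3, 0.8]), np.array([0.45, 0.55, 0.9, 0.1]),
            unit_square, np.array([1, 2, 1, 2]),
        )
        r = RGrid(np.linspace(0, 0.25, 501))
        g = pcf_cross(p, CrossSpec(CTL, NORM), r, bandwidth=1e-3)
        nz = r.values[np.nan_to_num(g.estimate) > 0]
        # the only cross distance below r_max is 0.1 (subject (0.5,0.45)
        # to target (0.5,0.55)); all kernel mass must sit within h of it
        assert nz.size > 0
        assert np.all(np.abs(nz - 0.1) <= 2e-3)
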