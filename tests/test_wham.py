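"""Reaction coordinate, WHAM reconstruction, basin analysis, titration fits."""

import numpy as np
import pytest

from mgfold import (BasinSet, EnergyParams, FreeEnergySurface,
                    SimulationConfig, SystemState, UmbrellaWindow,
                    basin_delta_g, estimate_tf, fit_sigmoid, q_hard,
                    q_smooth, wham_1d, wham_2d)
from mgfold.synthetic import (double_well_potential,
                              make_double_well_samples)
from mgfold.wham import QBias, check_overlap, folded_fraction


class TestQ:
    def test_native_is_high_q(self, hairpin10):
        _, topo, _ = hairpin10
        assert q_smooth(topo.native_coords, topo) >= 0.95
        assert q_hard(topo.native_coords, topo) == 1.0

    def test_stretched_chain_is_low_q(self, hairpin10):
        _, topo, _ = hairpin10
        stretched = np.column_stack([
            np.arange(topo.n_atoms) * 3.0,
            np.zeros(topo.n_atoms), np.zeros(topo.n_atoms)])
        assert q_smooth(stretched, topo) < 0.05

    def test_hard_and_smooth_agree_on_ensemble(self):
        from mgfold.synthetic import make_hairpin
        _, topo, _ = make_hairpin(24)
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(100):
            x = topo.native_coords + 0.35 * rng.standard_normal(
                (topo.n_atoms, 3))
            diffs.append(abs(q_smooth(x, topo) - q_hard(x, topo)))
        assert np.mean(diffs) < 0.03

    def test_bias_gradient_matches_finite_difference(self, hairpin10):
        _, topo, _ = hairpin10
        from mgfold.energy import Forces
        rng = np.random.default_rng(1)
        x = topo.native_coords + 0.2 * rng.standard_normal(
            (topo.n_atoms, 3))
        bias = QBias(topo, q0=0.5, k=40.0)
        state = SystemState(coords=x.copy(),
                            theta=np.zeros(len(topo.phosphate_idx)))
        f = Forces(np.zeros_like(x), np.empty((0, 3)), np.zeros(0))
        e = bias(state, f)
        h = 1e-6
        for i, d in [(3, 0), (17, 2), (30, 1)]:
            s1, s2 = state.copy(), state.copy()
            s1.coords[i, d] += h
            s2.coords[i, d] -= h
            num = -(bias(s1, None) - bias(s2, None)) / (2 * h)
            assert f.atoms[i, d] == pytest.approx(num, abs=1e-6)


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.5, 0.1, 5000)
        w = UmbrellaWindow(q0=0.5, k=1e-9, q_samples=samples)
        surf = wham_1d([w], n_bins=25, n_bootstrap=20, seed=0)
        h, edges = np.histogram(samples, bins=25,
                                range=(samples.min(),
                                       samples.max() + 1e-9))
        g_ref = -np.log(h / h.sum())
        g_ref -= g_ref.min()
        ok = np.isfinite(surf.g)
        np.testing.assert_allclose(surf.g[ok], g_ref[ok], atol=1e-6)

    def test_double_well_barrier_recovered(self):
        windows, truth = make_double_well_samples(
            barrier=3.0, n_per_window=2000, seed=3)
        surf = wham_1d(windows, n_bins=36, q_range=(-1.8, 1.8), seed=0)
        q, g = surf.centers[0], surf.g
        barrier = g[np.argmin(np.abs(q))] - min(
            np.nanmin(g[np.abs(q + 1) < 0.2]),
            np.nanmin(g[np.abs(q - 1) < 0.2]))
        assert barrier == pytest.approx(truth["barrier"], abs=0.15)

    def test_window_order_and_bias_offset_invariance(self):
        windows, _ = make_double_well_samples(barrier=2.0,
                                              n_per_window=1500, seed=7)
        surf = wham_1d(windows, n_bins=30, q_range=(-1.8, 1.8), seed=0)
        surf_rev = wham_1d(windows[::-1], n_bins=30, q_range=(-1.8, 1.8),
                           seed=0)
        ok = np.isfinite(surf.g) & np.isfinite(surf_rev.g)
        assert np.abs(surf.g[ok] - surf_rev.g[ok]).max() < 1e-6

    def test_half_window_split_consistency(self):
        windows, _ = make_double_well_samples(barrier=2.0,
                                              n_per_window=3000, seed=9)
        w0 = windows[len(windows) // 2]
        half = len(w0.q_samples) // 2
        split = (windows[:len(windows) // 2]
                 + [UmbrellaWindow(w0.q0, w0.k, w0.q_samples[:half]),
                    UmbrellaWindow(w0.q0, w0.k, w0.q_samples[half:])]
                 + windows[len(windows) // 2 + 1:])
        a = wham_1d(windows, n_bins=30, q_range=(-1.8, 1.8), seed=0)
        b = wham_1d(split, n_bins=30, q_range=(-1.8, 1.8), seed=0)
        ok = np.isfinite(a.g) & np.isfinite(b.g) & (a.counts > 30)
        err = np.maximum(a.error[ok] + b.error[ok], 0.05)
        assert np.all(np.abs(a.g[ok] - b.g[ok]) < 4 * err)

    def test_convergence_with_sample_size(self):
        """RMS error against the analytic well decreases with sampling."""
        errors = []
        for n in (250, 1000, 4000):
            windows, _ = make_double_well_samples(barrier=3.0,
                                                  n_per_window=n, seed=11)
            surf = wham_1d(windows, n_bins=30, q_range=(-1.6, 1.6), seed=0)
            q, g = surf.centers[0], surf.g
            ga = double_well_potential(q, 3.0)
            ok = np.isfinite(g) & (surf.counts > 10)
            resid = (g - ga)[ok]
            resid -= resid.mean()
            errors.append(np.sqrt(np.mean(resid ** 2)))
        assert errors[2] < errors[0]

    def test_wham_2d_reweights_auxiliary_coordinates(self):
        windows, _ = make_double_well_samples(barrier=2.0,
                                              n_per_window=2000, seed=5)
        for w in windows:   # x and a deterministic function of x
            w.aux = {"x": w.q_samples, "x2": w.q_samples ** 2}
        surf = wham_2d(windows, ("x", "x2"), n_bins=(24, 24),
                       n_bootstrap=20, seed=0)
        assert surf.names == ("x", "x2")
        # support concentrated on the parabola x2 = x^2
        finite = np.argwhere(np.isfinite(surf.g))
        xs = surf.centers[0][finite[:, 0]]
        ys = surf.centers[1][finite[:, 1]]
        dx = surf.centers[0][1] - surf.centers[0][0]
        dy = surf.centers[1][1] - surf.centers[1][0]
        assert np.all(np.abs(ys - xs ** 2) < dy + 2 * np.abs(xs) * dx + 0.05)

    def test_overlap_check_flags_gaps(self):
        rng = np.random.default_rng(0)
        far = [UmbrellaWindow(0.0, 50.0, rng.normal(0.0, 0.02, 500)),
               UmbrellaWindow(1.0, 50.0, rng.normal(1.0, 0.02, 500))]
        with pytest.raises(ValueError, match="overlap"):
            check_overlap(far)


class TestBasins:
    def make_surface(self, populations, qs):
        g = -np.log(np.asarray(populations, float))
        return FreeEnergySurface(centers=(np.asarray(qs),), g=g,
                                 counts=np.ones(len(qs)),
                                 error=np.zeros(len(qs)))

    def test_symmetric_basins_zero_dg(self):
        surf = self.make_surface([0.5, 0.5], [0.3, 0.7])
        basins = BasinSet({"A": (0.0, 0.5), "B": (0.5, 1.0)})
        assert basin_delta_g(surf, basins, ("A", "B")) == pytest.approx(0.0)

    def test_ninety_ten_split_is_ln9(self):
        surf = self.make_surface([0.9, 0.1], [0.3, 0.7])
        basins = BasinSet({"A": (0.0, 0.5), "B": (0.5, 1.0)})
        dg = basin_delta_g(surf, basins, ("B", "A"))
        assert dg == pytest.approx(np.log(9.0), abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        qs = np.linspace(0.05, 0.95, 40)
        g = rng.uniform(0, 5, 40)
        surf = FreeEnergySurface(centers=(qs,), g=g.copy(),
                                 counts=np.ones(40), error=np.zeros(40))
        basins = BasinSet({"lo": (0.0, 0.5), "hi": (0.5, 1.0)})
        gmin = g - g.min()
        lo = -np.log(np.sum(np.exp(-gmin[qs < 0.5])))
        hi = -np.log(np.sum(np.exp(-gmin[qs >= 0.5])))
        assert basin_delta_g(surf, basins, ("hi", "lo")) == pytest.approx(
            hi - lo, abs=1e-12)

    def test_empty_basin_raises(self):
        surf = self.make_surface([1.0], [0.9])
        basins = BasinSet({"A": (0.0, 0.5), "B": (0.5, 1.0)})
        with pytest.raises(ValueError, match="no defined bins"):
            basin_delta_g(surf, basins, ("A", "B"))

    def test_default_basins_ordered(self):
        b = BasinSet.default_sam2()
        assert list(b.intervals) == ["U", "O", "PO", "PC", "C"]


class TestSigmoid:
    def test_midpoint_recovery_with_noise(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0.25, 16.0, 14)
        y = 30.0 - 10.0 / (1 + np.exp((x - 6.0) / 1.2)) \
            + 0.02 * rng.standard_normal(len(x))
        fit = fit_sigmoid(x, y)
        assert fit.defined
        assert fit.midpoint == pytest.approx(6.0, abs=0.3)

    def test_exact_sigmoid_noise_free(self):
        x = np.linspace(0.5, 12.0, 20)
        y = 1.0 + 2.0 / (1 + np.exp((x - 6.0) / 1.5))
        fit = fit_sigmoid(x, y)
        assert fit.residual < 1e-10
        assert fit.midpoint == pytest.approx(6.0, abs=1e-5)

    def test_constant_data_flagged_undefined(self):
        fit = fit_sigmoid(np.linspace(0, 10, 8), np.full(8, 3.3))
        assert not fit.defined
        assert np.isnan(fit.midpoint)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestFoldingTemperature:
    def surfaces_for(self, de, ds, temps):
        out = []
        for t in temps:
            g_unfolded = 0.0
            g_folded = de / t - ds
            out.append(FreeEnergySurface(
                centers=(np.array([0.2, 0.8]),),
                g=np.array([g_unfolded, g_folded]),
                counts=np.ones(2), error=np.zeros(2)))
        return out

    def test_two_state_tf_is_de_over_ds(self):
        de, ds = 3.0, 2.5
        temps = [0.9, 1.1, 1.3, 1.5]
        tf = estimate_tf(temps, self.surfaces_for(de, ds, temps))
        assert tf == pytest.approx(de / ds, rel=0.02)

    def test_symmetric_model_tf_at_simulated_temperature(self):
        temps = [0.8, 1.0, 1.2]
        surfs = self.surfaces_for(1.0, 1.0, temps)
        assert estimate_tf(temps, surfs) == pytest.approx(1.0, rel=0.02)

    def test_no_crossover_raises(self):
        temps = [1.5, 1.7, 2.0]
        surfs = self.surfaces_for(30.0, 2.0, temps)   # always folded... not
        with pytest.raises(ValueError, match="bracket"):
            estimate_tf(temps, surfs)

    def test_folded_fraction_normalised(self):
        surf = FreeEnergySurface(centers=(np.array([0.2, 0.8]),),
                                 g=np.array([0.0, 0.0]),
                                 counts=np.ones(2), error=np.zeros(2))
        assert folded_fraction(surf) == pytest.approx(0.5)
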