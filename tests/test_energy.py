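"""Energy terms, analytic gradients and electrostatic limits."""

import numpy as np
import pytest

from mgfold import (EnergyParams, SystemState, condensed_density,
                    debye_kappa, energy_and_forces, energy_contacts,
                    energy_ion_effect, energy_local, energy_mg_size,
                    total_energy)
from mgfold.energy import _cloud_inv_r

from conftest import point_topology


def contact_topology(r0=4.0):
    """Two atoms in distant residues with one native contact at r0."""
    topo = point_topology(np.array([[0.0, 0, 0], [r0, 0, 0]]))
    topo.contacts = np.array([[0, 1]])
    topo.contact_r0 = np.array([r0])
    topo.contact_labels = ["other"]
    return topo


class TestLocal:
    def test_zero_at_native(self, hairpin10, params):
        _, topo, _ = hairpin10
        s = SystemState(coords=topo.native_coords.copy(),
                        theta=np.zeros(len(topo.phosphate_idx)))
        assert energy_local(s, topo, params) == pytest.approx(0.0, abs=1e-9)

    def test_single_bond_stretch_closed_form(self, params):
        topo = point_topology(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        topo.bonds = np.array([[0, 1]])
        topo.bond_r0 = np.array([5.0])
        delta = 0.05
        s = SystemState(coords=np.array([[0.0, 0, 0], [5.0 + delta, 0, 0]]))
        assert energy_local(s, topo, params) == pytest.approx(
            0.5 * params.k_bond * delta ** 2, rel=1e-9)

    def test_matches_independent_term_oracle(self, hairpin10, params):
        """Naive per-term recomputation agrees with the vectorised path."""
        _, topo, _ = hairpin10
        rng = np.random.default_rng(4)
        x = topo.native_coords + 0.03 * rng.standard_normal(
            (topo.n_atoms, 3))
        s = SystemState(coords=x, theta=np.zeros(len(topo.phosphate_idx)))

        def angle(a, b, c):
            u, v = x[a] - x[b], x[c] - x[b]
            return np.arccos(np.clip(
                u @ v / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))

        def dihedral(a, b, c, d):
            b1, b2, b3 = x[b] - x[a], x[c] - x[b], x[d] - x[c]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2))
            return np.arctan2(m1 @ n2, n1 @ n2)

        e = 0.0
        for (i, j), r0 in zip(topo.bonds, topo.bond_r0):
            e += 0.5 * params.k_bond * (
                np.linalg.norm(x[i] - x[j]) - r0) ** 2
        for (a, b, c), t0 in zip(topo.angles, topo.angle_t0):
            e += 0.5 * params.k_angle * (angle(a, b, c) - t0) ** 2
        for quad, p0 in zip(topo.dihedrals, topo.dihedral_p0):
            d = dihedral(*quad) - p0
            e += params.k_dihedral * ((1 - np.cos(d))
                                      + 0.5 * (1 - np.cos(3 * d)))
        for quad, p0 in zip(topo.impropers, topo.improper_p0):
            d = (dihedral(*quad) - p0 + np.pi) % (2 * np.pi) - np.pi
            e += 0.5 * params.k_improper * d ** 2
        assert energy_local(s, topo, params) == pytest.approx(e, abs=1e-9)

    def test_nan_coordinates_rejected(self, hairpin10, params):
        _, topo, _ = hairpin10
        x = topo.native_coords.copy()
        x[0, 0] = np.nan
        s = SystemState(coords=x, theta=np.zeros(len(topo.phosphate_idx)))
        with pytest.raises(ValueError):
            energy_local(s, topo, params)


class TestContacts:
    def test_well_depth_at_native_distance(self, params):
        topo = contact_topology(4.0)
        s = SystemState(coords=topo.native_coords.copy())
        assert energy_contacts(s, topo, params) == pytest.approx(-1.0)

    def test_vanishes_at_large_separation(self, params):
        topo = contact_topology(4.0)
        s = SystemState(coords=np.array([[0.0, 0, 0], [400.0, 0, 0]]))
        assert abs(energy_contacts(s, topo, params)) < 1e-10

    def test_minimum_location_by_derivative(self, params):
        """dU/dr vanishes at r0 and changes sign around it (12-6 form)."""
        topo = contact_topology(4.0)

        def u(r):
            s = SystemState(coords=np.array([[0.0, 0, 0], [r, 0, 0]]))
            return energy_contacts(s, topo, params)

        h = 1e-6
        assert (u(4.0 + h) - u(4.0 - h)) / (2 * h) == pytest.approx(
            0.0, abs=1e-6)
        assert u(3.9) > u(4.0) < u(4.1)

    def test_coincident_atoms_error(self, params):
        topo = contact_topology(4.0)
        s = SystemState(coords=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="hard-core"):
            energy_contacts(s, topo, params)


class TestMgSize:
    def test_zero_without_ions(self, params):
        topo = point_topology(np.zeros((1, 3)))
        s = SystemState(coords=topo.native_coords)
        assert energy_mg_size(s, params) == 0.0

    def test_two_mg_at_contact_distance(self, params):
        s = SystemState(coords=np.empty((0, 3)),
                        mg=np.array([[0.0, 0, 0], [2 * params.r_mg, 0, 0]]))
        # truncated-shifted r^-12: eps * (1 - cutoff_factor^-12)
        expect = params.eps_mg * (1 - params.rep_cutoff_factor ** -12)
        assert energy_mg_size(s, params) == pytest.approx(expect, rel=1e-12)

    def test_matches_double_loop_oracle(self, hairpin10, params):
        _, topo, _ = hairpin10
        rng = np.random.default_rng(7)
        mg = topo.native_coords.mean(0) + rng.uniform(-8, 8, (10, 3))
        s = SystemState(coords=topo.native_coords.copy(), mg=mg,
                        theta=np.zeros(len(topo.phosphate_idx)))
        sig_ma = params.r_mg + 0.5 * params.sigma_rep
        e = 0.0
        for sigma, pairs in (
                (sig_ma, [(m, a) for m in range(10)
                          for a in range(topo.n_atoms)]),
                (2 * params.r_mg, [(i, j) for i in range(10)
                                   for j in range(i + 1, 10)])):
            rc = params.rep_cutoff_factor * sigma
            for p, q_ in pairs:
                r = np.linalg.norm(
                    (mg[p] - topo.native_coords[q_]) if sigma == sig_ma
                    else (mg[p] - mg[q_]))
                if r < rc:
                    e += params.eps_mg * ((sigma / r) ** 12
                                          - (sigma / rc) ** 12)
        assert energy_mg_size(s, params) == pytest.approx(e, rel=1e-10)


class TestCondensedDensity:
    def test_zero_theta_zero_density(self):
        rng = np.random.default_rng(0)
        xp = rng.standard_normal((5, 3))
        rho = condensed_density(np.zeros(5), xp, rng.standard_normal((20, 3)))
        assert np.all(rho == 0.0)

    def test_peak_value_closed_form(self):
        s1, s2 = 3.0, 6.0
        rho = condensed_density(np.array([1.0]), np.zeros((1, 3)),
                                np.zeros((1, 3)), sigma=(s1, s2))
        expect = 0.5 * ((2 * np.pi * s1 ** 2) ** -1.5
                        + (2 * np.pi * s2 ** 2) ** -1.5)
        assert rho[0] == pytest.approx(expect, rel=1e-12)

    def test_normalisation_by_quadrature(self):
        """Radial quadrature of one cloud integrates to theta."""
        theta = 0.63
        r = np.linspace(1e-4, 40.0, 4000)
        pts = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        rho = condensed_density(np.array([theta]), np.zeros((1, 3)), pts)
        integral = np.trapezoid(4 * np.pi * r ** 2 * rho, r)
        assert integral == pytest.approx(theta, abs=1e-4)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            condensed_density(np.array([1.0]), np.zeros((1, 3)),
                              np.zeros((1, 3)), sigma=(0.0, 3.0))


class TestIonEffect:
    def two_phosphates(self, r=10.0, theta=0.0):
        topo = point_topology(np.array([[0.0, 0, 0], [r, 0, 0]]),
                              phosphate_idx=[0, 1])
        s = SystemState(coords=topo.native_coords.copy(),
                        theta=np.full(2, theta))
        return topo, s

    def manning_terms(self, params, theta, temperature=1.0):
        inv_r = _cloud_inv_r(params)
        self_e = -params.bjerrum * params.q_phos ** 2 * inv_r * theta.sum()
        tref = params.theta_ref
        th = np.clip(theta, 1e-8, 1 - 1e-8)
        ent = float(np.sum(th * np.log(th / tref)
                           + (1 - th) * np.log((1 - th) / (1 - tref))))
        return self_e + params.entropy_scale * temperature * ent

    def test_unscreened_bare_coulomb(self, params):
        p0 = params.replace(c_mono_mm=0.0)   # kappa = 0
        topo, s = self.two_phosphates(r=10.0, theta=0.0)
        pair = energy_ion_effect(s, topo, p0) - self.manning_terms(
            p0, s.theta)
        assert pair == pytest.approx(p0.bjerrum * p0.q_phos ** 2 / 10.0,
                                     rel=1e-12)

    def test_full_condensation_neutralises_pair(self, params):
        topo, s = self.two_phosphates(r=10.0, theta=1.0)
        pair = energy_ion_effect(s, topo, params) - self.manning_terms(
            params, s.theta)
        assert pair == pytest.approx(0.0, abs=1e-12)

    def test_five_charges_match_pairwise_oracle(self, params):
        rng = np.random.default_rng(3)
        xp = rng.uniform(0, 15, (3, 3))
        mg = rng.uniform(0, 15, (2, 3))
        theta = rng.uniform(0.1, 0.9, 3)
        topo = point_topology(xp, phosphate_idx=[0, 1, 2])
        s = SystemState(coords=xp.copy(), mg=mg, theta=theta, box=None)
        kappa = debye_kappa(params)
        qs = np.concatenate([-params.q_phos * (1 - theta),
                             np.full(2, params.z_mg)])
        pos = np.vstack([xp, mg])
        e = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.linalg.norm(pos[i] - pos[j])
                e += params.bjerrum * qs[i] * qs[j] * np.exp(-kappa * r) / r
        got = energy_ion_effect(s, topo, params) - self.manning_terms(
            params, theta)
        assert got == pytest.approx(e, abs=1e-10)

    def test_screening_monotone_in_salt(self, params):
        """Higher kappa weakens every pair magnitude (fixed geometry)."""
        topo, s = self.two_phosphates(r=8.0, theta=0.0)
        prev = None
        for c in (0.0, 50.0, 200.0, 1000.0):
            p = params.replace(c_mono_mm=c)
            pair = energy_ion_effect(s, topo, p) - self.manning_terms(
                p, s.theta)
            if prev is not None:
                assert abs(pair) < abs(prev)
            prev = pair

    def test_condensation_weakens_pair_terms(self, params):
        topo, _ = self.two_phosphates()
        prev = None
        for th in (0.0, 0.3, 0.6, 0.9):
            s = SystemState(coords=topo.native_coords.copy(),
                            theta=np.array([th, 0.2]))
            pair = energy_ion_effect(s, topo, params) - self.manning_terms(
                params, s.theta)
            if prev is not None:
                assert abs(pair) <= abs(prev) + 1e-12
            prev = pair

    def test_overlapping_charges_error(self, params):
        topo = point_topology(np.zeros((2, 3)), phosphate_idx=[0, 1])
        s = SystemState(coords=topo.native_coords, theta=np.zeros(2))
        with pytest.raises(ValueError, match="overlapping"):
            energy_ion_effect(s, topo, params)


class TestKappa:
    def test_debye_length_100mM(self, params):
        # 1/kappa at 100 mM 1:1 salt in water is ~9.6 A
        assert 1.0 / debye_kappa(params) == pytest.approx(9.65, rel=0.02)

    def test_excluded_volume_correction_lowers_kappa(self, params):
        full = debye_kappa(params)
        corrected = debye_kappa(params, box=50.0, n_rna_atoms=5000)
        assert corrected < full


class TestTotals:
    def test_total_is_sum_of_components(self, perturbed_state, hairpin10,
                                        params):
        _, topo, _ = hairpin10
        s = perturbed_state
        total = total_energy(s, topo, params)
        parts = (energy_local(s, topo, params)
                 + energy_contacts(s, topo, params)
                 + energy_mg_size(s, params)
                 + energy_ion_effect(s, topo, params))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_forces_match_finite_differences(self, perturbed_state,
                                             hairpin10, params):
        _, topo, _ = hairpin10
        s = perturbed_state
        e, f = energy_and_forces(s, topo, params)
        h = 1e-5
        rng = np.random.default_rng(0)
        for _ in range(12):    # random spot checks over all DOF kinds
            kind = rng.integers(0, 3)
            if kind == 0:
                i, d = rng.integers(0, topo.n_atoms), rng.integers(0, 3)
                s1, s2 = s.copy(), s.copy()
                s1.coords[i, d] += h
                s2.coords[i, d] -= h
                analytic = f.atoms[i, d]
            elif kind == 1:
                i, d = rng.integers(0, s.n_mg), rng.integers(0, 3)
                s1, s2 = s.copy(), s.copy()
                s1.mg[i, d] += h
                s2.mg[i, d] -= h
                analytic = f.mg[i, d]
            else:
                i = rng.integers(0, len(s.theta))
                s1, s2 = s.copy(), s.copy()
                s1.theta[i] += h
                s2.theta[i] -= h
                analytic = f.theta[i]
            numeric = -(total_energy(s1, topo, params)
                        - total_energy(s2, topo, params)) / (2 * h)
            assert analytic == pytest.approx(
                numeric, rel=2e-5, abs=2e-5 * max(1.0, abs(numeric)))

    def test_translation_invariance(self, perturbed_state, hairpin10,
                                    params):
        _, topo, _ = hairpin10
        s = perturbed_state
        e0, f = energy_and_forces(s, topo, params)
        s2 = s.copy()
        s2.coords += np.array([3.1, -2.2, 0.7])
        s2.mg += np.array([3.1, -2.2, 0.7])
        assert total_energy(s2, topo, params) == pytest.approx(e0, rel=1e-9)
        net = f.atoms.sum(axis=0) + f.mg.sum(axis=0)
        assert np.abs(net).max() < 1e-8

    def test_rotation_invariance(self, perturbed_state, hairpin10, params):
        from scipy.spatial.transform import Rotation
        _, topo, _ = hairpin10
        s = perturbed_state
        e0 = total_energy(s, topo, params)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        s2 = s.copy()
        center = s.coords.mean(axis=0)
        s2.coords = (s.coords - center) @ rot.T + center
        s2.mg = (s.mg - center) @ rot.T + center
        assert total_energy(s2, topo, params) == pytest.approx(e0, rel=1e-9)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        EnergyParams(eps_contact=-1.0)
    with pytest.raises(ValueError):
        EnergyParams(sigma_cond=(0.0, 6.0))
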