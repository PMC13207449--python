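"""Voxel finite elements: element matrix, patch tests, solves, homogenization."""

import numpy as np
import pytest

from tpmsbone import fe
from tpmsbone.geometry import PhaseLabel, VoxelRVE
from tpmsbone.io import make_homogeneous_cube, make_series_laminate
from tpmsbone.simulate import initial_state


class TestElementStiffness:
    def test_symmetry_and_equilibrium(self):
        K = fe.hex_element_stiffness(1350.0, 0.3, 0.02)
        np.testing.assert_allclose(K, K.T, atol=1e-9)
        # rigid translation in each direction produces zero force
        for d in range(3):
            t = np.zeros(24)
            t[d::3] = 1.0
            np.testing.assert_allclose(K @ t, 0.0, atol=1e-9)

    def test_linearity_in_modulus(self):
        K1 = fe.hex_element_stiffness(100.0, 0.3, 0.02)
        K2 = fe.hex_element_stiffness(200.0, 0.3, 0.02)
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-13)

    def test_exactly_six_zero_energy_modes(self):
        K = fe.hex_element_stiffness(1.0, 0.25, 1.0)
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-10) == 6
        assert np.all(eig[6:] > 1e-8)

    def test_invalid_material_rejected(self):
        with pytest.raises(ValueError):
            fe.hex_element_stiffness(-1.0, 0.3, 0.02)
        with pytest.raises(ValueError):
            fe.hex_element_stiffness(1.0, 0.6, 0.02)
        with pytest.raises(ValueError):
            fe.hex_element_stiffness(1.0, 0.3, 0.0)


class TestAssembly:
    def test_single_element_system_equals_element_matrix(self):
        fix = make_homogeneous_cube(1, E=123.0, nu=0.3)
        K = fe.assemble(fix.rve, fix.modulus, fix.nu)
        Ke = fe.hex_element_stiffness(123.0, 0.3, fix.rve.spacing)
        ed = fe.element_dofs(1)[0]
        np.testing.assert_allclose(K.toarray()[np.ix_(ed, ed)], Ke, atol=1e-9)

    def test_global_stiffness_symmetric_psd(self, rng):
        fix = make_homogeneous_cube(3, E=10.0, nu=0.3)
        K = fe.assemble(fix.rve, fix.modulus, fix.nu)
        dense = K.toarray()
        np.testing.assert_allclose(dense, dense.T, atol=1e-10)
        u = rng.standard_normal(K.shape[0])
        assert u @ (K @ u) >= -1e-9

    def test_patch_affine_field_reproduced_exactly(self):
        """Boundary-driven affine displacement is exact on a homogeneous grid."""
        n = 3
        fix = make_homogeneous_cube(n, E=50.0, nu=0.3)
        K = fe.assemble(fix.rve, fix.modulus, fix.nu)
        coords = fe.node_coordinates(n, fix.rve.spacing)
        A = np.array([[1e-3, 2e-4, 0.0],
                      [2e-4, -5e-4, 1e-4],
                      [0.0, 1e-4, 3e-4]])
        u_affine = (coords @ A.T).ravel()
        nn = n + 1
        idx = np.arange(nn**3).reshape(nn, nn, nn)
        surf = np.ones((nn, nn, nn), dtype=bool)
        surf[1:-1, 1:-1, 1:-1] = False
        surf_nodes = idx[surf].ravel()
        fixed = (3 * surf_nodes[:, None] + np.arange(3)).ravel()
        u = fe.solve_dirichlet(K, fixed, u_affine[fixed], rtol=1e-12)
        np.testing.assert_allclose(u, u_affine, atol=1e-10)
        # and the recovered stress is uniform at the closed-form value
        stress = fe.recover_stress(u, fix.rve, fix.modulus, fix.nu)
        C = fe.elastic_matrix(50.0, 0.3)
        eps = np.array([A[0, 0], A[1, 1], A[2, 2],
                        2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]])
        np.testing.assert_allclose(
            stress, np.tile(C @ eps, (len(stress), 1)), atol=1e-8)


class TestUniaxial:
    def test_homogeneous_cube_nu0_closed_form(self):
        fix = make_homogeneous_cube(4, E=1350.0, nu=0.3)
        res = fe.solve_uniaxial(fix.rve, fix.modulus, nu=0.0,
                                applied_strain=0.10)
        # with nu=0 the confined solution is exact uniaxial: sigma_zz = -E*eps
        np.testing.assert_allclose(res.stress[:, 2], -135.0, rtol=1e-8)
        assert res.apparent_modulus == pytest.approx(1350.0, rel=1e-8)

    def test_series_laminate_reuss_mean(self):
        fix = make_series_laminate(4, E1=10.0, E2=1350.0)
        res = fe.solve_uniaxial(fix.rve, fix.modulus, nu=fix.nu,
                                applied_strain=0.05)
        assert fix.expected_modulus == pytest.approx(19.85, abs=0.01)
        assert res.apparent_modulus == pytest.approx(fix.expected_modulus,
                                                     rel=1e-6)

    def test_modulus_linear_in_material_and_strain_invariant(self, s_rve_small,
                                                             s_state_small):
        res1 = fe.solve_uniaxial(s_rve_small, s_state_small.E, 0.3, 0.10,
                                 rtol=1e-10)
        res2 = fe.solve_uniaxial(s_rve_small, 2.0 * s_state_small.E, 0.3, 0.10,
                                 rtol=1e-10)
        assert res2.apparent_modulus == pytest.approx(
            2.0 * res1.apparent_modulus, rel=1e-6)
        res3 = fe.solve_uniaxial(s_rve_small, s_state_small.E, 0.3, 0.05,
                                 rtol=1e-10)
        assert res3.apparent_modulus == pytest.approx(res1.apparent_modulus,
                                                      rel=1e-6)

    def test_apparent_modulus_within_reuss_voigt_bounds(self, s_rve_small,
                                                        s_state_small):
        lo, hi = fe.reuss_voigt_bounds(s_state_small.E)
        res = fe.solve_uniaxial(s_rve_small, s_state_small.E, 0.3, 0.10)
        assert lo <= res.apparent_modulus <= hi

    def test_zero_strain_rejected(self, s_rve_small, s_state_small):
        with pytest.raises(ValueError):
            fe.solve_uniaxial(s_rve_small, s_state_small.E, 0.3, 0.0)


class TestStressRecovery:
    def test_rigid_translation_zero_stress(self):
        fix = make_homogeneous_cube(2, E=10.0, nu=0.3)
        u = np.tile([1.0, -2.0, 0.5], (fix.rve.resolution + 1) ** 3)
        stress = fe.recover_stress(u, fix.rve, fix.modulus, fix.nu)
        np.testing.assert_allclose(stress, 0.0, atol=1e-10)

    def test_against_finite_difference_strain_oracle(self, rng):
        """Quadrature-averaged strain equals central differences of a random
        trilinear-compatible field on a 2-element grid."""
        fix = make_homogeneous_cube(2, E=7.0, nu=0.2)
        nn = 3
        u = rng.standard_normal(3 * nn**3) * 1e-3
        stress = fe.recover_stress(u, fix.rve, fix.modulus, fix.nu)
        h = fix.rve.spacing
        U = u.reshape(nn, nn, nn, 3)
        # brute-force: average corner-difference gradients per element
        for e, (i, j, k) in enumerate(np.ndindex(2, 2, 2)):
            blk = U[i:i + 2, j:j + 2, k:k + 2]
            grad = np.zeros((3, 3))
            grad[:, 0] = (blk[1] - blk[0]).mean(axis=(0, 1)) / h
            grad[:, 1] = (blk[:, 1] - blk[:, 0]).mean(axis=(0, 1)) / h
            grad[:, 2] = (blk[:, :, 1] - blk[:, :, 0]).mean(axis=(0, 1)) / h
            eps = np.array([
                grad[0, 0], grad[1, 1], grad[2, 2],
                grad[0, 1] + grad[1, 0],
                grad[1, 2] + grad[2, 1],
                grad[0, 2] + grad[2, 0],
            ])
            C = fe.elastic_matrix(7.0, 0.2)
            np.testing.assert_allclose(stress[e], C @ eps, atol=1e-10)


class TestVonMises:
    @pytest.mark.parametrize(
        "principal, expected",
        [((10.0, 0.0, 0.0), 10.0),
         ((5.0, 5.0, 5.0), 0.0),
         ((3.0, 1.0, -2.0), np.sqrt(19.0))],
    )
    def test_closed_form_values(self, principal, expected):
        assert fe.von_mises(np.array(principal)) == pytest.approx(expected)

    def test_voigt_form_matches_principal_form(self, rng):
        s = rng.standard_normal((20, 6)) * 10
        p = fe.principal_stresses(s)
        assert np.all(np.diff(p, axis=1) <= 1e-9)  # sorted descending
        np.testing.assert_allclose(fe.von_mises(p), fe.von_mises_voigt(s),
                                   rtol=1e-9, atol=1e-9)


class TestHomogenization:
    def test_homogeneous_grid_recovers_material_constants(self):
        E, nu = 1350.0, 0.3
        fix = make_homogeneous_cube(4, E=E, nu=nu)
        hom = fe.homogenize_pbc(fix.rve, fix.modulus, nu, cases="full",
                                rtol=1e-10)
        for val in hom.moduli:
            assert val == pytest.approx(E, rel=1e-3)
        G = E / (2 * (1 + nu))
        for val in (hom.G12, hom.G13, hom.G23):
            assert val == pytest.approx(G, rel=1e-3)

    def test_tpms_grid_is_numerically_isotropic(self, s_rve_small,
                                                s_state_small):
        hom = fe.homogenize_pbc(s_rve_small, s_state_small.E, 0.3)
        assert abs(hom.E11 - hom.E33) / hom.E11 < 0.01
        assert abs(hom.E22 - hom.E33) / hom.E11 < 0.01

    def test_pbc_modulus_within_bounds_and_linear(self, s_rve_small,
                                                  s_state_small):
        lo, hi = fe.reuss_voigt_bounds(s_state_small.E)
        hom = fe.homogenize_pbc(s_rve_small, s_state_small.E, 0.3)
        assert lo <= hom.E33 <= hi
        hom2 = fe.homogenize_pbc(s_rve_small, 2 * s_state_small.E, 0.3)
        assert hom2.E33 == pytest.approx(2 * hom.E33, rel=1e-6)
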