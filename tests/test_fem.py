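"""Axisymmetric Ogden forward model: constitutive law, mesh, contact solve."""

import numpy as np
import pytest

from indentfit.fem import (
    MeshSpec,
    OgdenParams,
    build_mesh,
    hertz_force,
    interpolate_state,
    ogden_stress,
    small_strain_moduli,
    solve_indentation,
    strain_energy_density,
)
from indentfit.fem.solver import FEModel


class TestConstitutiveLaw:
    P = OgdenParams(7.0, 12.0)

    def test_stress_free_reference(self):
        assert np.abs(ogden_stress(self.P, np.eye(3))).max() == 0.0

    def test_pure_volumetric_response(self):
        J = 1.002
        sigma = ogden_stress(self.P, J ** (1 / 3) * np.eye(3))
        pressure = np.trace(sigma) / 3
        assert pressure == pytest.approx(self.P.kappa_mpa * np.log(J) / J, rel=1e-9)
        assert np.abs(sigma - pressure * np.eye(3)).max() < 1e-12

    def test_uniaxial_matches_energy_derivative(self):
        """Cauchy stress difference equals the closed-form energy derivative."""
        lam, h = 1.3, 1e-6

        def F(la):
            return np.diag([la, la**-0.5, la**-0.5])

        sigma = ogden_stress(self.P, F(lam))
        fd = lam * (
            strain_energy_density(self.P, F(lam + h))
            - strain_energy_density(self.P, F(lam - h))
        ) / (2 * h)
        assert sigma[0, 0] - sigma[1, 1] == pytest.approx(fd, rel=1e-5)

    def test_small_strain_shear_modulus_is_c_over_two(self):
        mod = small_strain_moduli(self.P)
        assert mod["mu"] == pytest.approx(self.P.c_mpa / 2, rel=1e-4)
        assert mod["nu"] == pytest.approx(0.4998, abs=1e-3)

    def test_inverted_deformation_rejected(self):
        with pytest.raises(ValueError):
            ogden_stress(self.P, -np.eye(3))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            OgdenParams(-1.0, 10.0)
        with pytest.raises(ValueError):
            OgdenParams(5.0, 0.5)
        assert OgdenParams(5.0, 10.0).kappa_kpa == 10000.0


class TestMesh:
    def test_production_mesh_element_counts(self):
        mesh = build_mesh(MeshSpec(N=3))
        assert mesh.n_elems == 450
        assert mesh.spec.n_radial == 30 and mesh.spec.n_axial == 15

    def test_unbiased_spacing_is_uniform(self):
        mesh = build_mesh(MeshSpec(N=2, bias_radial=1.0, bias_axial=1.0))
        widths = np.diff(mesh.r_breaks)
        np.testing.assert_allclose(widths, widths[0], rtol=1e-12)

    def test_radius_partition(self):
        for N in (1, 3):
            mesh = build_mesh(MeshSpec(N=N))
            assert np.sum(np.diff(mesh.r_breaks)) == pytest.approx(110.0, abs=1e-9)
            assert mesh.nodes[:, 0].max() == pytest.approx(110.0)

    def test_state_transfer_reproduces_quadratic_field(self):
        """A global quadratic field lies in the Q8 space: transfer is exact.

        The field is chosen to satisfy the hard boundary conditions by
        construction (u_r ~ r z vanishes on the axis, u_z ~ z^2 at the
        clamped bottom), so the transfer must reproduce it at every node.
        """
        coarse = build_mesh(MeshSpec(N=1))
        fine = build_mesh(MeshSpec(N=2))

        def field(nodes):
            r, z = nodes[:, 0], nodes[:, 1]
            return np.stack([1e-4 * r * z, -1e-5 * z**2], axis=1)

        uf = interpolate_state(coarse, field(coarse.nodes).ravel(), fine)
        np.testing.assert_allclose(
            uf.reshape(-1, 2), field(fine.nodes), atol=1e-10
        )


class TestForwardSolve:
    def test_reaction_scales_exactly_with_c(self, fe_model_n1):
        """Doubling c (kappa in proportion) doubles the reaction exactly."""
        a = fe_model_n1.solve(OgdenParams(5.0, 12.0), 10.0, n_steps=5, snapshots=[10.0])
        b = fe_model_n1.solve(OgdenParams(10.0, 12.0), 10.0, n_steps=5, snapshots=[10.0])
        assert b.reaction_at(10.0) == pytest.approx(2 * a.reaction_at(10.0), rel=1e-9)
        np.testing.assert_allclose(
            a.snapshot(10.0)["uz"], b.snapshot(10.0)["uz"], atol=1e-10
        )

    def test_energy_consistency(self, fe_model_n1):
        """The reaction equals dW/d(delta) of the elastic energy within 2 %."""
        sol = fe_model_n1.solve(OgdenParams(7.0, 12.0), 10.0, n_steps=10, snapshots=[10.0])
        d, f, w = sol.delta_history, sol.reaction_history, sol.energy_history
        sel = f[1:] > 0.1 * f.max()  # skip the tiny-force toe
        dW = np.diff(w) / np.diff(d)
        f_mid = 0.5 * (f[1:] + f[:-1])
        np.testing.assert_allclose(dW[sel], f_mid[sel], rtol=0.02)

    def test_reaction_monotone_and_zero_at_zero(self, solution_r3_n3):
        assert solution_r3_n3.reaction_history[0] == 0.0
        assert np.all(np.diff(solution_r3_n3.reaction_history) > -1e-9)

    def test_near_incompressibility(self, solution_r3_n3):
        jmin, jmax = solution_r3_n3.diagnostics["J_range_final"]
        assert max(abs(jmin - 1), abs(jmax - 1)) < 0.01

    def test_zero_penetration(self, solution_r3_n3):
        assert solution_r3_n3.diagnostics["max_penetration_mm"] <= 1e-3 * 10.0

    def test_edge_uplift_below_bound(self, solution_r3_n3):
        """Outer-edge uplift stays below 0.35 mm at full indentation."""
        snap = solution_r3_n3.snapshot(25.0)
        assert abs(snap["uz"][-1]) < 0.35

    def test_contact_edge_moves_down_profile_monotone(self, solution_r3_n3):
        snap = solution_r3_n3.snapshot(25.0)
        r, uz = snap["r"], snap["uz"]
        near = (r > 10.0) & (r < 12.0)
        assert np.all(uz[near] < 0)
        concave = (r > 12.0) & (r < 45.0)
        assert np.all(np.diff(uz[concave]) > -1e-6)  # |u| decreasing outward

    def test_hertz_small_strain_agreement(self):
        """Sub-mm indentation matches Hertz with the measured moduli within 10 %."""
        p = OgdenParams(7.0, 12.0)
        sol = solve_indentation(MeshSpec(N=3), p, 0.5, n_steps=5, snapshots=[0.5])
        assert sol.reaction_at(0.5) == pytest.approx(hertz_force(p, 0.5), rel=0.10)


class TestMeshConvergenceProperties:
    def test_errors_decrease_monotonically_with_refinement(self, convergence_report):
        rep = convergence_report
        for k in range(len(rep.material_sets)):
            ef = [rep.E_F[(N, k)] for N in (1, 2, 3)]
            eu = [rep.E_u[(N, k)] for N in (1, 2, 3)]
            assert ef[0] > ef[1] > ef[2]
            assert eu[0] > eu[1] > eu[2]

    def test_force_error_formula_identity(self):
        from indentfit.fem.convergence import force_error

        assert force_error(101.0, 100.0) == pytest.approx(
            abs((101.0 - 100.0) / 100.0) * 100.0, abs=1e-12
        )
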