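"""Neo-Hookean plane-strain FEM: moduli, energies, solver, inverse problem."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bctsim.phantom import FAT
from bctsim.mesh import build_mesh
from bctsim.mechanics import (GRAVITY_PRONE, GRAVITY_SEATED, LoadCase,
                              Material, MechanicsError, derive_moduli,
                              estimate_unloaded, evaluate_state,
                              material_table, normalized_stress,
                              outer_contour, p2_coordinates, solve_equilibrium,
                              solve_linear, strain_energy)


class TestModuli:
    @pytest.mark.parametrize("E,nu,mu,K", [
        (3.7, 0.49, 1.2416, 61.667),      # fitted fat stiffness
        (80.0, 0.49, 26.846, 1333.3),     # inflamed tissue
        (1.0, 0.0, 0.5, 1.0 / 3.0),
    ])
    def test_closed_form(self, E, nu, mu, K):
        got_mu, got_K = derive_moduli(E, nu)
        assert got_mu == pytest.approx(mu, rel=1e-3)
        assert got_K == pytest.approx(K, rel=1e-3)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            derive_moduli(5.0, 0.5)
        with pytest.raises(ValueError):
            derive_moduli(-1.0, 0.3)


class TestStrainEnergy:
    def test_undeformed_is_exactly_zero(self):
        assert strain_energy(3.0, 1.0, 1.7, 80.0) == 0.0

    def test_isochoric_stretch_value(self):
        # diag(1.1, 1/1.1, 1): J = 1, I1 = 1.1^2 + 1.1^-2 + 1
        lam = 1.1
        I1 = lam ** 2 + lam ** -2 + 1.0
        got = strain_energy(I1, 1.0, mu=1.0, K=37.0)
        assert got == pytest.approx(0.5 * (I1 - 3.0), rel=1e-12)

    def test_pure_dilation_volumetric_term(self):
        J = 1.01
        I1 = 3.0 * J ** (2.0 / 3.0)
        got = strain_energy(I1, J, mu=0.0, K=2.0)
        assert got == pytest.approx(1e-4, rel=1e-9)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            strain_energy(3.0, -0.1, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(lam=st.floats(0.5, 2.0), J=st.floats(0.8, 1.25))
    def test_energy_nonnegative(self, lam, J):
        # plane-strain kinematics F = diag(a, b) with ab = J, a/b = lam^2
        a = lam * np.sqrt(J)
        b = np.sqrt(J) / lam
        I1 = a ** 2 + b ** 2 + 1.0
        assert strain_energy(I1, J, 1.3, 60.0) >= -1e-12


@pytest.fixture(scope="module")
def block_mesh(block_map):
    return build_mesh(block_map, 2.5)


@pytest.fixture(scope="module")
def block_mats():
    return {FAT: Material(E=5.0, nu=0.49, rho=1.0)}


@pytest.fixture(scope="module")
def block_gravity_state(block_mesh, block_mats):
    return solve_equilibrium(block_mesh, block_mats,
                             LoadCase(gravity=GRAVITY_SEATED))


class TestEquilibrium:
    def test_zero_load_zero_displacement(self, block_mesh, block_mats):
        s = solve_equilibrium(block_mesh, block_mats,
                              LoadCase(gravity=(0.0, 0.0)))
        assert np.abs(s.u).max() == 0.0
        assert normalized_stress(s).max() == 0.0

    def test_small_load_matches_linear_oracle(self, block_mesh, block_mats):
        tiny = LoadCase(gravity=(0.0, -9.81e-3))
        s = solve_equilibrium(block_mesh, block_mats, tiny)
        u_lin = solve_linear(block_mesh, block_mats, tiny)
        err = np.linalg.norm(s.u - u_lin) / np.linalg.norm(u_lin)
        assert err < 0.01

    def test_mesh_refinement_convergence(self, block_map, block_mats):
        tips = []
        for h in (2.5, 1.25):          # 4x element count
            m = build_mesh(block_map, h)
            s = solve_equilibrium(m, block_mats,
                                  LoadCase(gravity=GRAVITY_SEATED))
            tip = m.nodes[:, 0].argmax()
            tips.append(s.u[tip, 1])
        assert abs(tips[1] - tips[0]) / abs(tips[1]) < 0.02

    def test_energy_balance_at_equilibrium(self, block_mesh, block_mats,
                                           block_gravity_state):
        # the converged residual certifies internal = external virtual work
        s = block_gravity_state
        assert s.residual < 1e-6
        assert (s.J > 0).all()

    def test_objectivity_rigid_rotation_has_zero_energy(self, block_mesh,
                                                        block_mats):
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        X = p2_coordinates(block_mesh)
        u = X @ R.T - X
        s = evaluate_state(block_mesh, block_mats, u)
        assert np.abs(s.W).max() < 1e-12
        np.testing.assert_allclose(s.J, 1.0, atol=1e-12)

    def test_stiffer_tissue_sags_less(self, block_map):
        drops = []
        for scale in (1.0, 1.8):
            m = build_mesh(block_map, 2.5)
            mats = {FAT: Material(E=5.0 * scale, nu=0.49, rho=1.0)}
            s = solve_equilibrium(m, mats, LoadCase(gravity=GRAVITY_SEATED))
            tip = m.nodes[:, 0].argmax()
            drops.append(-s.u[tip, 1])
        assert drops[1] < drops[0]

    def test_normalized_stress_peaks_at_clamped_root(self, block_mesh,
                                                     block_gravity_state):
        ehat = normalized_stress(block_gravity_state)
        assert ehat.max() == 1.0
        cent = block_mesh.nodes[block_mesh.tris].mean(axis=1)
        x_peak = cent[ehat.argmax(), 0]
        assert x_peak < np.median(cent[:, 0])    # near the clamped edge


class TestCavityPressure:
    def test_pressure_inflates_the_cavity(self, lumpectomy_mesh):
        mats = material_table(3.7, 9.5, 25.0)
        s0 = solve_equilibrium(lumpectomy_mesh, mats,
                               LoadCase(gravity=(0, 0), pressure=0.0))
        s1 = solve_equilibrium(lumpectomy_mesh, mats,
                               LoadCase(gravity=(0, 0), pressure=200.0))
        ids = lumpectomy_mesh.boundary_nodes("cavity_wall")
        c = lumpectomy_mesh.nodes[ids].mean(axis=0)
        r0 = np.linalg.norm(s0.deformed_nodes[ids] - c, axis=1).mean()
        r1 = np.linalg.norm(s1.deformed_nodes[ids] - c, axis=1).mean()
        assert np.abs(s0.u).max() < 1e-10
        assert r1 > r0 + 0.05


class TestPhantomMechanics:
    def test_quasi_incompressibility_under_seated_gravity(self, breast_mesh):
        mats = material_table(3.7, 9.5, 25.0)
        s = solve_equilibrium(breast_mesh, mats, LoadCase())
        assert np.abs(s.J - 1.0).max() <= 0.05
        contour = outer_contour(s)
        assert len(contour) > 50

    def test_unloaded_round_trip(self, breast_mesh):
        mats = material_table(3.7, 9.5, 25.0)
        load = LoadCase(gravity=GRAVITY_PRONE)
        unloaded = estimate_unloaded(breast_mesh, mats, load, tol=0.05)
        s = solve_equilibrium(unloaded, mats, load)
        err = np.abs(s.deformed_nodes - breast_mesh.nodes).max()
        assert err < 0.1

    def test_zero_observed_load_is_identity(self, breast_mesh):
        mats = material_table(3.7, 9.5, 25.0)
        un = estimate_unloaded(breast_mesh, mats,
                               LoadCase(gravity=(0.0, 0.0)), tol=0.01)
        np.testing.assert_allclose(un.nodes, breast_mesh.nodes, atol=1e-9)

    def test_linear_small_load_signflip_inverse(self, block_mesh, block_mats):
        # in the linear regime the unloaded shape equals the sign-flipped
        # load solution
        tiny = LoadCase(gravity=(0.0, -9.81e-2))
        un = estimate_unloaded(block_mesh, block_mats, tiny, tol=1e-4)
        u_lin = solve_linear(block_mesh, block_mats, tiny)
        shift = un.nodes - block_mesh.nodes
        err = np.linalg.norm(shift + u_lin[:len(block_mesh.nodes)]) \
            / np.linalg.norm(u_lin[:len(block_mesh.nodes)])
        assert err < 0.01
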