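"""Mooney-Rivlin material law and the hyperelastic wall solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from coroflow import (DeformationState, MooneyRivlinParams, VesselSpec,
                      build_vessel, strain_energy, solve_wall)
from coroflow.meshing import mesh_wall
from coroflow.wall import (_pk2_iso, _pk2_vol, interface_load_vector,
                           radial_displacement)

PARAMS = MooneyRivlinParams()


class TestStrainEnergy:
    def test_undeformed_state_has_zero_energy(self):
        assert strain_energy(DeformationState(np.eye(3)), PARAMS) == 0.0

    def test_incompressible_uniaxial_stretch(self):
        # lambda = 1.2, J = 1: I1b = 3.10667, I2b = 3.09444;
        # W = 0.07*x + 3.2*x^2 + 0.0716*x^2*y with x, y the excess
        # invariants = 0.0439525 MPa
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        state = DeformationState(F)
        assert state.J == pytest.approx(1.0, abs=1e-12)
        x = state.I1_bar - 3.0
        y = state.I2_bar - 3.0
        expected = 0.07 * x + 3.2 * x**2 + 0.0716 * x**2 * y
        assert expected == pytest.approx(0.0439525, abs=2e-6)
        assert strain_energy(state, PARAMS) == pytest.approx(expected,
                                                             rel=1e-12)
        assert strain_energy(state, PARAMS) == pytest.approx(0.04395,
                                                             abs=5e-6)

    def test_small_shear_limit_gives_shear_modulus(self):
        # W/gamma^2 -> c10 + c01 as gamma -> 0, i.e. mu = 2(c10+c01)
        gam = 1e-4
        F = np.eye(3)
        F[0, 1] = gam
        w = strain_energy(DeformationState(F), PARAMS)
        mu = 2.0 * w / gam**2
        assert mu == pytest.approx(PARAMS.shear_modulus, rel=1e-2)
        assert PARAMS.shear_modulus == pytest.approx(0.14)

    def test_frame_indifference(self):
        rng = np.random.default_rng(3)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        w0 = strain_energy(DeformationState(F), PARAMS)
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(A)
            w = strain_energy(DeformationState(Q @ F), PARAMS)
            assert w == pytest.approx(w0, rel=1e-10)

    def test_stress_free_reference(self):
        C = np.eye(3)[None, :, :]
        S = _pk2_iso(C, PARAMS) + _pk2_vol(C, PARAMS)
        assert np.abs(S).max() < 1e-14

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            DeformationState(np.diag([-1.0, 1.0, 1.0]))

    def test_compressibility_parameter_is_two_over_k(self):
        assert PARAMS.d == pytest.approx(2.0 / PARAMS.bulk_modulus)


def _principal_cauchy(lam_r, lam_t, params):
    """Cauchy stresses of a principal stretch state (plane strain)."""
    F = np.diag([lam_r, lam_t, 1.0])[None, :, :]
    C = F.transpose(0, 2, 1) @ F
    S = _pk2_iso(C, params) + _pk2_vol(C, params)
    J = lam_r * lam_t
    sig = (F @ S @ F.transpose(0, 2, 1))[0] / J
    return sig[0, 0], sig[1, 1]


def _radial_ode_oracle(r_in, r_out, pressure_mpa, params):
    """Inflation of a thick-walled cylinder by 1D radial equilibrium.

    Shooting on the deformed inner radius; integrates
    d(sigma_rr)/dR = lam_r (sigma_tt - sigma_rr)/r with the same strain
    energy as the FE solver, plane strain, internal pressure applied at
    the inner face.  Returns the inner-radius displacement (mm).
    """

    def lam_r_from_sigma(sig_rr, lam_t):
        return brentq(
            lambda lr: _principal_cauchy(lr, lam_t, params)[0] - sig_rr,
            0.3, 3.0, xtol=1e-10)

    def rhs(R, y):
        r, sig = y
        lam_t = r / R
        lr = lam_r_from_sigma(sig, lam_t)
        s_rr, s_tt = _principal_cauchy(lr, lam_t, params)
        return [lr, lr * (s_tt - s_rr) / r]

    def outer_residual(a):
        sol = solve_ivp(rhs, (r_in, r_out), [a, -pressure_mpa],
                        rtol=1e-6, atol=1e-9, dense_output=False)
        return sol.y[1, -1]

    a = brentq(outer_residual, r_in * 1.0000001, r_in * 1.5,
               xtol=1e-7 * r_in)
    return a - r_in


@pytest.fixture(scope="module")
def wall_mesh():
    spec = VesselSpec(length=20.0, base_radius=1.5, stenosis_severity=0.0,
                      stenosis_center=10.0, stenosis_length=5.0,
                      wall_thickness=0.5)
    surf = build_vessel(spec)
    return mesh_wall(surf, face_size=0.4, n_layers=5, layer_thickness=0.1)


@pytest.fixture(scope="module")
def pressurized_state(wall_mesh):
    # 100 mmHg internal pressure, the physiologic reference load
    return solve_wall(wall_mesh, PARAMS, 13332.2)


class TestSolveWall:
    def test_zero_traction_gives_zero_displacement(self, wall_mesh):
        state = solve_wall(wall_mesh, PARAMS, 0.0)
        assert state.max_displacement() == 0.0

    def test_pressurized_cylinder_matches_radial_ode(self, pressurized_state):
        u_fe = radial_displacement(pressurized_state, 10.0)
        u_1d = _radial_ode_oracle(1.5, 2.0, 13332.2e-6, PARAMS)
        assert u_fe > 0
        assert u_fe == pytest.approx(u_1d, rel=0.05)

    def test_displacement_monotone_in_pressure(self, wall_mesh,
                                               pressurized_state):
        u = [radial_displacement(solve_wall(wall_mesh, PARAMS, p), 10.0)
             for p in (4000.0, 8000.0)]
        u.append(radial_displacement(pressurized_state, 10.0))
        assert 0 < u[0] < u[1] < u[2]

    def test_stiffness_scaling_is_linear_at_small_strain(self, wall_mesh):
        u1 = solve_wall(wall_mesh, PARAMS.scaled(100.0),
                        13332.2).max_displacement()
        u2 = solve_wall(wall_mesh, PARAMS.scaled(1000.0),
                        13332.2).max_displacement()
        assert u1 / u2 == pytest.approx(10.0, rel=0.02)

    def test_near_incompressibility_under_physiologic_load(
            self, wall_mesh, pressurized_state):
        # element volume change (the quantity the volumetric penalty
        # controls under selective reduced integration) stays below 1%
        from coroflow import hexfem

        x = wall_mesh.nodes + pressurized_state.displacement
        v_def = hexfem.element_volumes(x, wall_mesh.elements)
        v_ref = hexfem.element_volumes(wall_mesh.nodes, wall_mesh.elements)
        assert np.abs(v_def / v_ref - 1.0).max() < 0.01

    def test_ends_remain_fixed(self, wall_mesh, pressurized_state):
        ends = wall_mesh.patches["ends"].nodes
        assert np.abs(pressurized_state.displacement[ends]).max() < 1e-12

    def test_interface_load_is_outward_for_scalar_pressure(self, wall_mesh):
        f = interface_load_vector(wall_mesh, 1000.0).reshape(-1, 3)
        ifn = wall_mesh.patches["interface"].nodes
        ctr = wall_mesh.nodes[ifn].mean(axis=0)
        rad = wall_mesh.nodes[ifn] - ctr
        rad[:, 2] = 0.0
        rad /= np.linalg.norm(rad, axis=1)[:, None]
        assert np.einsum("ai,ai->a", f[ifn], rad).sum() > 0
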