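"""Incompressible Newtonian blood flow in the lumen.

Equal-order Q1-Q1 finite elements with SUPG/PSPG stabilization;
adaptively damped Picard iteration for the convective nonlinearity;
implicit time stepping (backward Euler by default, Crank-Nicolson
optionally) at the measurement time step of 0.05 s.  The inlet carries a
pressure (normal traction) boundary condition, the outlet a fully
developed Dirichlet velocity profile scaled to the prescribed mean
velocity, and the lumen wall is no-slip (moving-wall velocity in the
fluid-structure-coupled case).  Solvers run in SI units; geometry
arrives in mm and pressures are reported in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import hexfem
from .meshing import FluidMesh
from .units import MMHG_PA, MM_M, pa_to_mmhg
from .waveforms import Waveform, cycle_mean


class FlowSolverError(RuntimeError):
    """Solver failure; carries the residual history for diagnosis."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class BloodProperties:
    """Newtonian blood: density kg/m^3, dynamic viscosity Pa.s."""

    density: float = 1060.0
    dynamic_viscosity: float = 0.0035

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("blood density and viscosity must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


#: velocity-profile scenarios for mapping the wire-measured velocity to
#: the profile mean: measured-as-mean, the 0.76 Doppler correction, and
#: the generalized-Poiseuille 0.5 ratio.
DEFAULT_VELOCITY_RATIOS = (1.0, 0.76, 0.5)


@dataclass
class FlowBC:
    """Boundary data: inlet pressure, distal measured velocity, scenario.

    ``inlet_pressure`` is a scalar in mmHg (steady) or a pressure
    Waveform (transient); ``outlet_velocity_measured`` a scalar in m/s
    or a velocity Waveform.  ``velocity_ratio`` maps the measured
    velocity to the mean of the fully developed outlet profile.
    """

    inlet_pressure: Union[float, Waveform] = 100.0
    outlet_velocity_measured: Union[float, Waveform] = 0.2
    velocity_ratio: float = 1.0
    outlet_profile: Union[str, Callable] = "parabolic"
    profile_normalize: bool = True

    def __post_init__(self):
        if not (0.0 < self.velocity_ratio <= 1.0):
            raise ValueError(
                f"velocity_ratio must lie in (0, 1], got {self.velocity_ratio}"
            )

    def inlet_pressure_at(self, t: float) -> float:
        p = self.inlet_pressure
        return p.at(t) if isinstance(p, Waveform) else float(p)

    def outlet_velocity_at(self, t: float) -> float:
        v = self.outlet_velocity_measured
        return v.at(t) if isinstance(v, Waveform) else float(v)


@dataclass
class FlowSolution:
    """Nodal velocity/pressure fields plus derived scalar diagnostics."""

    time: float
    v: np.ndarray            # (N, 3) m/s
    p: np.ndarray            # (N,) Pa
    mesh: FluidMesh
    outlet_pressure_mmhg: float = 0.0
    inlet_pressure_mmhg: float = 0.0
    flow_in: float = 0.0     # m^3/s, signed with outward normal
    flow_out: float = 0.0
    iterations: int = 0
    residual: float = 0.0
    residual_history: list = field(default_factory=list)


def outlet_mean_velocity(v_measured: float, ratio: float) -> float:
    """Mean profile velocity from the wire-measured value."""
    if v_measured < 0:
        raise ValueError("measured velocity must be >= 0")
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must lie in (0, 1]")
    return ratio * v_measured


def mass_flow_rate(blood: BloodProperties, v_mean: float,
                   area: float) -> float:
    """Outlet mass flow rate rho*v*A (kg/s)."""
    if area <= 0:
        raise ValueError("area must be > 0")
    return blood.density * v_mean * area


def reynolds(blood: BloodProperties, v_mean: float, diameter: float) -> float:
    """Reynolds number rho*v*D/mu."""
    return blood.density * v_mean * diameter / blood.dynamic_viscosity


class _Discretization:
    """Cached FE operators for a fluid mesh (SI coordinates)."""

    def __init__(self, mesh: FluidMesh, nodes_mm: Optional[np.ndarray] = None):
        self.mesh = mesh
        nodes_mm = mesh.nodes if nodes_mm is None else nodes_mm
        self.x = nodes_mm * MM_M
        self.elements = mesh.elements
        self.n_nodes = len(self.x)
        self.n_dof = 4 * self.n_nodes
        self.dNdx, self.detJ = hexfem.geometry_ops(self.x, self.elements)
        edges = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7),
                 (7, 4), (0, 4), (1, 5), (2, 6), (3, 7)]
        X = self.x[self.elements]
        self.h_min = np.min(
            [np.linalg.norm(X[:, a] - X[:, b], axis=1) for a, b in edges],
            axis=0,
        )
        # velocity dofs (node i -> 3i..3i+2), pressure dofs 3N + i
        e = self.elements
        self.vdof = (3 * e[:, :, None] + np.arange(3)).reshape(len(e), 24)
        self.pdof = 3 * self.n_nodes + e
        self.N3 = hexfem._N3  # (ngp, 8)
        # lumped pressure mass (SI volume weights) for the Schur preconditioner
        mp = np.zeros(self.n_nodes)
        np.add.at(mp, e, np.einsum("ga,eg->ea", self.N3, self.detJ))
        self.mp_lumped = mp
        self._lp_lu = None  # lazy pressure-Laplacian factorization
        # boundary quadrature per patch
        self.face = {
            name: hexfem.face_ops(self.x, patch.faces)
            for name, patch in mesh.patches.items()
        }

    def pressure_laplacian_solve(self, r: np.ndarray) -> np.ndarray:
        """Solve the (pure-Neumann) pressure Laplacian, constant deflated."""
        if self._lp_lu is None:
            L = np.einsum("egai,egbi,eg->eab", self.dNdx, self.dNdx,
                          self.detJ)
            Lp = hexfem.assemble_csr(L, self.elements, self.elements,
                                     self.n_nodes)
            Lp = Lp + sp.diags(1e-6 * Lp.diagonal())
            self._lp_lu = spla.splu(Lp.tocsc())
        # project the right-hand side off the constant nullspace
        w = self.mp_lumped
        r0 = r - r.sum() * w / w.sum()
        x = self._lp_lu.solve(r0)
        return x - (w @ x) / w.sum()

    def patch_area(self, name: str) -> float:
        _, _, _, dA = self.face[name]
        return float(dA.sum())

    def patch_flux(self, name: str, v: np.ndarray) -> float:
        NQ, _, nrm, dA = self.face[name]
        vq = np.einsum("ga,fai->fgi", NQ, v[self.mesh.patches[name].faces])
        return float(np.einsum("fgi,fgi,fg->", vq, nrm, dA))

    def patch_mean_scalar(self, name: str, s: np.ndarray) -> float:
        NQ, _, _, dA = self.face[name]
        sq = np.einsum("ga,fa->fg", NQ, s[self.mesh.patches[name].faces])
        return float((sq * dA).sum() / dA.sum())

    def outlet_normal(self) -> np.ndarray:
        _, _, nrm, dA = self.face["outlet"]
        n = np.einsum("fgi,fg->i", nrm, dA)
        return n / np.linalg.norm(n)


def _outlet_profile_values(disc: _Discretization, bc: FlowBC, v_mean: float,
                           t: float) -> np.ndarray:
    """Nodal Dirichlet velocity vectors on the outlet patch (m/s).

    The raw profile (parabolic by default, or a user callable of the
    radial fraction and time) is scaled so that its area-weighted mean
    over the discrete outlet equals ``v_mean`` unless
    ``profile_normalize`` is off.
    """
    mesh = disc.mesh
    onodes = mesh.patches["outlet"].nodes
    s = mesh.aux["radial_fraction"][onodes]
    if bc.outlet_profile == "parabolic":
        raw_nodal = 1.0 - s**2
    else:
        raw_nodal = np.array([bc.outlet_profile(si, t) for si in s])
    raw_full = np.zeros(disc.n_nodes)
    raw_full[onodes] = raw_nodal
    if bc.profile_normalize:
        mean_raw = disc.patch_mean_scalar("outlet", raw_full)
        scale = 0.0 if v_mean == 0 else v_mean / mean_raw
    else:
        scale = 1.0
    n_out = disc.outlet_normal()
    return scale * raw_nodal[:, None] * n_out[None, :], onodes


def _assemble_system(disc: _Discretization, blood: BloodProperties,
                     a_nodal: np.ndarray, w_nodal: Optional[np.ndarray],
                     u_old: Optional[np.ndarray], dt: Optional[float],
                     p_inlet: float, theta: float = 1.0,
                     r_old: Optional[np.ndarray] = None):
    """One Picard-linearized system (matrix, rhs) at advection ``a_nodal``.

    Momentum: rho du/dt + rho (a - w).grad u - div(-pI + mu grad u) = 0,
    stabilized with SUPG; continuity with PSPG; LSIC grad-div term.
    ``r_old`` is the explicit momentum residual of the previous step for
    the Crank-Nicolson (theta = 0.5) variant; pressure and continuity
    are always implicit.
    """
    rho, mu = blood.density, blood.dynamic_viscosity
    nu = mu / rho
    el = disc.elements
    E = len(el)
    dNdx, detJ, N3 = disc.dNdx, disc.detJ, disc.N3

    arel = a_nodal if w_nodal is None else a_nodal - w_nodal
    a_gp = np.einsum("ga,eai->egi", N3, arel[el])
    adN = np.einsum("egi,egai->ega", a_gp, dNdx)  # (E,g,8) a.grad(N)
    amag = np.linalg.norm(a_gp, axis=2)
    # conservative (min-edge) element length: keeps the stabilization
    # parameter small on anisotropic cells, where a streamline-based h
    # would inject a noticeable consistency error into pressure-driven
    # flow (the trilinear residual carries no viscous term)
    h = disc.h_min[:, None]
    inv_tau2 = (2.0 * amag / h) ** 2 + (4.0 * nu / h**2) ** 2
    if dt is not None:
        inv_tau2 = inv_tau2 + (2.0 / dt) ** 2
    tau = 1.0 / np.sqrt(np.maximum(inv_tau2, 1e-300))

    w_detJ = detJ
    # scalar velocity blocks (E, 8, 8)
    Kvis = mu * np.einsum("egai,egbi,eg->eab", dNdx, dNdx, w_detJ)
    Conv = rho * np.einsum("ga,egb,eg->eab", N3, adN, w_detJ)
    Supg = rho * np.einsum("ega,egb,eg->eab", adN, adN, tau * w_detJ)
    Kuu_scalar = theta * (Kvis + Conv) + Supg
    rhs = np.zeros(disc.n_dof)
    if dt is not None:
        Mass = rho / dt * np.einsum("ga,gb,eg->eab", N3, N3, w_detJ)
        Msupg = rho / dt * np.einsum("ega,gb,eg->eab", adN, N3, tau * w_detJ)
        Kuu_scalar = Kuu_scalar + Mass + Msupg
        uo = u_old[el]  # (E, 8, 3)
        fm = np.einsum("eab,ebi->eai", Mass + Msupg, uo)
        np.add.at(rhs, disc.vdof, fm.reshape(E, 24))

    # the scalar operator is shared by the three velocity components
    Kuu = np.zeros((E, 24, 24))
    idx = np.arange(8)
    for i in range(3):
        Kuu[:, 3 * idx[:, None] + i, 3 * idx[None, :] + i] += Kuu_scalar

    # momentum-pressure block: -p div(phi) + SUPG tau (a.grad phi) grad p
    Gp = -np.einsum("gb,egai,eg->eaib", N3, dNdx, w_detJ) \
        + np.einsum("ega,egbi,eg->eaib", adN, dNdx, tau * w_detJ)
    Gp = Gp.reshape(E, 24, 8)

    # continuity rows: q div(u) + PSPG
    Dq = np.einsum("ga,egbj,eg->eabj", N3, dNdx, w_detJ) \
        + np.einsum("egaj,egb,eg->eabj", dNdx, adN, tau * w_detJ)
    if dt is not None:
        Dm = np.einsum("egaj,gb,eg->eabj", dNdx, N3, tau * w_detJ) / dt
        Dq = Dq + Dm
        fp = np.einsum("eabj,ebj->ea", Dm, uo)
        np.add.at(rhs, disc.pdof, fp)
    Dq = Dq.reshape(E, 8, 24)
    Spp = np.einsum("egai,egbi,eg->eab", dNdx, dNdx, tau / rho * w_detJ)

    n_dof = disc.n_dof
    A = (
        hexfem.assemble_csr(Kuu, disc.vdof, disc.vdof, n_dof)
        + hexfem.assemble_csr(Gp, disc.vdof, disc.pdof, n_dof)
        + hexfem.assemble_csr(Dq, disc.pdof, disc.vdof, n_dof)
        + hexfem.assemble_csr(Spp, disc.pdof, disc.pdof, n_dof)
    )
    # scalar velocity block (shared by the three components) and the
    # pressure convection-diffusion operator for the block preconditioner
    Ks = hexfem.assemble_csr(Kuu_scalar, disc.elements, disc.elements,
                             disc.n_nodes)
    Fp_el = mu * np.einsum("egai,egbi,eg->eab", dNdx, dNdx, w_detJ) \
        + rho * np.einsum("ga,egb,eg->eab", N3, adN, w_detJ)
    if dt is not None:
        Fp_el = Fp_el + rho / dt * np.einsum("ga,gb,eg->eab", N3, N3, w_detJ)
    Fp = hexfem.assemble_csr(Fp_el, disc.elements, disc.elements,
                             disc.n_nodes)

    # inlet normal traction -p_in n
    NQ, _, nrm, dA = disc.face["inlet"]
    faces = disc.mesh.patches["inlet"].faces
    ftr = -theta * p_inlet * np.einsum("ga,fgi,fg->fai", NQ, nrm, dA)
    np.add.at(rhs, 3 * faces[:, :, None] + np.arange(3), ftr)
    # tangential directional-do-nothing term on the inlet: damps the
    # transverse inflow modes that a pure traction condition leaves
    # unconstrained, and vanishes identically for axial flow (so the
    # imposed pressure is not biased)
    a_face = np.einsum("ga,fai->fgi", NQ, arel[faces])
    an = np.einsum("fgi,fgi->fg", a_face, nrm)
    coef = rho * np.maximum(-an, 0.0) * dA  # >= 0 on inflow
    Mf = np.einsum("ga,gb,fg->fab", NQ, NQ, coef)
    nbar = nrm.mean(axis=1)
    nbar /= np.linalg.norm(nbar, axis=1)[:, None]
    proj = np.eye(3)[None] - np.einsum("fi,fj->fij", nbar, nbar)
    Kf = np.einsum("fab,fij->faibj", Mf, proj).reshape(-1, 12, 12)
    fdof = (3 * faces[:, :, None] + np.arange(3)).reshape(-1, 12)
    A = A + hexfem.assemble_csr(Kf, fdof, fdof, n_dof)
    # matching scalar contribution keeps the preconditioner aligned
    Ks = Ks + hexfem.assemble_csr(Mf, faces, faces, disc.n_nodes)
    if r_old is not None and theta != 1.0:
        rhs -= (1.0 - theta) * r_old
    return A, rhs, Ks, Fp


def _momentum_residual_explicit(disc, blood, u, p_inlet):
    """Explicit (old-time) momentum terms of the theta-scheme.

    Viscous, convective and inlet-traction contributions only: the
    pressure and the continuity constraint stay fully implicit.
    """
    rho, mu = blood.density, blood.dynamic_viscosity
    el = disc.elements
    dNdx, detJ, N3 = disc.dNdx, disc.detJ, disc.N3
    u_el = u[el]
    a_gp = np.einsum("ga,eai->egi", N3, u_el)
    gradu = np.einsum("egaj,eai->egij", dNdx, u_el)
    conv = rho * np.einsum("egj,egij->egi", a_gp, gradu)
    r = np.zeros(disc.n_dof)
    fe = np.einsum("ga,egi,eg->eai", N3, conv, detJ)
    fe += mu * np.einsum("egaj,egij,eg->eai", dNdx, gradu, detJ)
    np.add.at(r, disc.vdof, fe.reshape(len(el), 24))
    NQ, _, nrm, dA = disc.face["inlet"]
    faces = disc.mesh.patches["inlet"].faces
    ftr = -p_inlet * np.einsum("ga,fgi,fg->fai", NQ, nrm, dA)
    np.add.at(r, (3 * faces[:, :, None] + np.arange(3)), ftr)
    return r


def _apply_dirichlet(A: sp.csr_matrix, rhs: np.ndarray, dofs: np.ndarray,
                     values: np.ndarray):
    keep = np.ones(A.shape[0])
    keep[dofs] = 0.0
    Dk = sp.diags(keep)
    fix = np.zeros(A.shape[0])
    fix[dofs] = 1.0
    A = Dk @ A + sp.diags(fix)
    rhs = keep * rhs
    rhs[dofs] = values
    return A, rhs


class _BlockPreconditioner:
    """Block upper-triangular preconditioner for the stabilized system.

    The velocity block is solved by its (component-shared) scalar
    convection-diffusion operator; the pressure Schur complement by a
    pressure-convection-diffusion (PCD) approximation
    S^-1 ~ M_p^-1 F_p L_p^-1 built from the lumped pressure mass, the
    pressure convection-diffusion operator and the pressure Laplacian.
    Velocity Dirichlet rows are made identity so prescribed values pass
    through unchanged.
    """

    def __init__(self, disc: _Discretization, Ks: sp.csr_matrix,
                 Fp: sp.csr_matrix, A: sp.csr_matrix,
                 dir_nodes: np.ndarray, mu: float):
        n = disc.n_nodes
        keep = np.ones(n)
        keep[dir_nodes] = 0.0
        fix = 1.0 - keep
        Ks = sp.diags(keep) @ Ks + sp.diags(fix)
        self.lu = spla.splu(Ks.tocsc())
        self.disc = disc
        self.A = A.tocsr()
        self.Fp = Fp
        self.mp = disc.mp_lumped
        self.mu = mu

    def _schur(self, rp: np.ndarray) -> np.ndarray:
        # constant pressure mode (set by the traction BC, outside the
        # Laplacian's range) is handled by viscous mass scaling
        c = rp.sum() / self.mp.sum()
        rp0 = rp - c * self.mp
        p = (self.Fp @ self.disc.pressure_laplacian_solve(rp0)) / self.mp
        return p + self.mu * c

    def __call__(self, r: np.ndarray) -> np.ndarray:
        n = self.disc.n_nodes
        ru, rp = r[: 3 * n], r[3 * n:]
        p = self._schur(rp)
        # subtract the pressure-gradient coupling from the momentum rows
        z = np.concatenate([np.zeros(3 * n), p])
        ru = ru - (self.A @ z)[: 3 * n]
        u = self.lu.solve(ru.reshape(-1, 3))
        return np.concatenate([u.ravel(), p])


def _solve_linear(disc, A, rhs, Ks, Fp, dir_nodes, mu, x0=None,
                  rtol: float = 1e-10, restarts: int = 6):
    M = _BlockPreconditioner(disc, Ks, Fp, A, dir_nodes, mu)
    Mop = spla.LinearOperator(A.shape, M)
    bnorm = np.linalg.norm(rhs)
    sol, info = spla.gmres(A.tocsr(), rhs, x0=x0, M=Mop, rtol=rtol, atol=0.0,
                           restart=250, maxiter=restarts)
    if info != 0:
        res = np.linalg.norm(A @ sol - rhs) / max(bnorm, 1e-300)
        if res > 1e-8:
            raise FlowSolverError(
                f"linear solver stagnated (GMRES info={info}, "
                f"relative residual {res:.2e})")
    return sol


def _dirichlet_sets(disc: _Discretization, bc: FlowBC, v_mean: float,
                    t: float, wall_velocity: Optional[np.ndarray]):
    """Outlet profile + wall no-slip dofs/values (wall wins at corners)."""
    prof, onodes = _outlet_profile_values(disc, bc, v_mean, t)
    wnodes = disc.mesh.patches["wall_interface"].nodes
    wvals = (np.zeros((len(wnodes), 3)) if wall_velocity is None
             else wall_velocity[wnodes])
    nodes = np.concatenate([onodes, wnodes])
    vals = np.vstack([prof, wvals])
    # later entries override earlier ones at duplicated nodes
    order = {}
    for i, nd in enumerate(nodes):
        order[nd] = i
    uniq = np.array(list(order.keys()))
    vv = vals[np.array(list(order.values()))]
    dofs = (3 * uniq[:, None] + np.arange(3)).ravel()
    return dofs, vv.ravel()


def _finalize(disc: _Discretization, u: np.ndarray, p: np.ndarray, t: float,
              iters: int, res: float, history) -> FlowSolution:
    return FlowSolution(
        time=t,
        v=u,
        p=p,
        mesh=disc.mesh,
        outlet_pressure_mmhg=pa_to_mmhg(disc.patch_mean_scalar("outlet", p)),
        inlet_pressure_mmhg=pa_to_mmhg(disc.patch_mean_scalar("inlet", p)),
        flow_in=disc.patch_flux("inlet", u),
        flow_out=disc.patch_flux("outlet", u),
        iterations=iters,
        residual=res,
        residual_history=list(history),
    )


def _picard_solve(disc, blood, bc, v_mean, p_in_pa, t, dt=None, u_old=None,
                  u_init=None, wall_velocity=None, mesh_velocity=None,
                  theta=1.0, r_old=None, tol=1e-6, max_iter=60):
    dofs, vals = _dirichlet_sets(disc, bc, v_mean, t, wall_velocity)
    u = np.zeros((disc.n_nodes, 3)) if u_init is None else u_init.copy()
    p = np.zeros(disc.n_nodes)
    history = []
    scale = max(abs(v_mean), 1e-12)
    dir_nodes = dofs.reshape(-1, 3)[:, 0] // 3
    x_prev = None
    omega = 1.0
    for it in range(1, max_iter + 1):
        A, rhs, Ks, Fp = _assemble_system(disc, blood, u, mesh_velocity,
                                          u_old, dt, p_in_pa, theta=theta,
                                          r_old=r_old)
        A, rhs = _apply_dirichlet(A, rhs, dofs, vals)
        sol = _solve_linear(disc, A, rhs, Ks, Fp, dir_nodes,
                            blood.dynamic_viscosity, x0=x_prev)
        x_prev = sol
        u_new = sol[: 3 * disc.n_nodes].reshape(-1, 3)
        p = sol[3 * disc.n_nodes:]
        change = np.abs(u_new - u).max() / max(np.abs(u_new).max(), scale)
        # adaptive damping: stenotic jets can limit-cycle under plain
        # Picard; damp when contraction stalls, release when it is fast
        if history and change > 0.7 * history[-1]:
            omega = max(0.4, 0.6 * omega)
        elif history and change < 0.3 * history[-1]:
            omega = min(1.0, 1.3 * omega)
        history.append(change)
        u = u + omega * (u_new - u)
        if change < tol:
            # one deep warm-started solve so the discrete continuity rows
            # (hence global mass conservation) hold to near machine level
            sol = _solve_linear(disc, A, rhs, Ks, Fp, dir_nodes,
                                blood.dynamic_viscosity, x0=sol,
                                rtol=1e-13, restarts=8)
            u = sol[: 3 * disc.n_nodes].reshape(-1, 3)
            p = sol[3 * disc.n_nodes:]
            return _finalize(disc, u, p, t, it, change, history)
    raise FlowSolverError(
        f"Picard iteration did not converge in {max_iter} iterations "
        f"(last relative change {history[-1]:.3e})", history)


def solve_steady(mesh: FluidMesh, blood: BloodProperties, bc: FlowBC,
                 tol: float = 1e-6, max_iter: int = 60,
                 nodes_mm: Optional[np.ndarray] = None,
                 wall_velocity: Optional[np.ndarray] = None,
                 _disc: Optional[_Discretization] = None) -> FlowSolution:
    """Steady rigid-wall flow under scalar boundary values.

    Inlet pressure (mmHg) enters as a normal traction; the outlet
    Dirichlet profile is scaled so its area mean equals
    ``velocity_ratio * outlet_velocity_measured``.
    """
    if isinstance(bc.inlet_pressure, Waveform) or isinstance(
            bc.outlet_velocity_measured, Waveform):
        raise ValueError("solve_steady expects scalar boundary values")
    disc = _disc if _disc is not None else _Discretization(mesh, nodes_mm)
    v_mean = outlet_mean_velocity(bc.outlet_velocity_at(0.0),
                                  bc.velocity_ratio)
    area = disc.patch_area("outlet")
    dia = 2.0 * np.sqrt(area / np.pi)
    re = reynolds(blood, v_mean, dia)
    if re >= 2000.0:
        raise ValueError(f"outlet Reynolds number {re:.0f} outside the "
                         "laminar regime (< 2000)")
    p_in = bc.inlet_pressure_at(0.0) * MMHG_PA
    return _picard_solve(disc, blood, bc, v_mean, p_in, 0.0, tol=tol,
                         max_iter=max_iter, wall_velocity=wall_velocity)


def solve_transient(mesh: FluidMesh, blood: BloodProperties, bc: FlowBC,
                    dt: float = 0.05, theta: float = 1.0,
                    n_cycles: int = 1, tol: float = 1e-6,
                    max_iter: int = 60) -> List[FlowSolution]:
    """Rigid-wall pulsatile flow over full cardiac cycles.

    Starts from the steady solution at cycle-mean boundary values (to
    avoid multi-cycle spin-up), then advances with an implicit
    theta-scheme (theta=1 backward Euler, 0.5 Crank-Nicolson) at time
    step ``dt``.  Returns one solution per step, the initial state
    included.
    """
    pw, vw = bc.inlet_pressure, bc.outlet_velocity_measured
    if not isinstance(pw, Waveform) or not isinstance(vw, Waveform):
        raise ValueError("solve_transient expects Waveform boundary values")
    if not np.isclose(pw.period, vw.period, rtol=1e-9):
        raise ValueError("inlet and outlet waveforms must share the period")
    period = pw.period
    n_steps = int(round(period / dt))
    if not np.isclose(n_steps * dt, period, rtol=1e-9):
        raise ValueError("dt must divide the waveform period")

    disc = _Discretization(mesh)
    bc0 = FlowBC(cycle_mean(pw), cycle_mean(vw), bc.velocity_ratio,
                 bc.outlet_profile, bc.profile_normalize)
    sols = [solve_steady(mesh, blood, bc0, tol=tol, max_iter=max_iter,
                         _disc=disc)]
    r_old = None
    if theta != 1.0:
        r_old = _momentum_residual_explicit(
            disc, blood, sols[0].v, bc.inlet_pressure_at(0.0) * MMHG_PA)
    for k in range(1, n_cycles * n_steps + 1):
        t = k * dt
        v_mean = outlet_mean_velocity(bc.outlet_velocity_at(t),
                                      bc.velocity_ratio)
        p_in = bc.inlet_pressure_at(t) * MMHG_PA
        sol = _picard_solve(disc, blood, bc, v_mean, p_in, t, dt=dt,
                            u_old=sols[-1].v, u_init=sols[-1].v,
                            theta=theta, r_old=r_old, tol=tol,
                            max_iter=max_iter)
        if theta != 1.0:
            r_old = _momentum_residual_explicit(disc, blood, sol.v, p_in)
        sols.append(sol)
    return sols


def outlet_pressure_waveform(sols: List[FlowSolution]) -> Waveform:
    """Computed outlet pressure series of a transient run (mmHg)."""
    t = np.array([s.time for s in sols])
    p = np.array([s.outlet_pressure_mmhg for s in sols])
    return Waveform(t, p, float(t[-1] - t[0]), "pressure")


def compute_wss(sol: FlowSolution, section: float,
                blood: Optional[BloodProperties] = None) -> float:
    """Average wall shear stress (Pa) on the wall ring nearest ``section``.

    ``section`` is the arclength along the centerline in mm.  WSS is the
    magnitude of the tangential viscous traction mu (grad v + grad v^T) n
    on the wall-interface faces of the owning slice, area-averaged.
    """
    mesh = sol.mesh
    mu = (blood.dynamic_viscosity if blood is not None else 0.0035)
    z = mesh.aux["z"]
    if not (z[0] - 1e-9 <= section <= z[-1] + 1e-9):
        raise ValueError(
            f"section {section} mm outside the vessel [0, {z[-1]}] mm")
    zmid = 0.5 * (z[:-1] + z[1:])
    k = int(np.argmin(np.abs(zmid - section)))
    patch = mesh.patches["wall_interface"]
    n_theta = len(patch.faces) // (len(z) - 1)
    sel = slice(k * n_theta, (k + 1) * n_theta)
    faces = patch.faces[sel]
    elems = patch.elems[sel]

    x = mesh.nodes * MM_M
    dNdx, detJ = hexfem.geometry_ops(x, mesh.elements[elems])
    gradu = hexfem.grad_at_gp(sol.v, mesh.elements[elems], dNdx)
    gradu = gradu.mean(axis=1)  # element-average gradient (e, i, j)
    _, _, nrm, dA = hexfem.face_ops(x, faces)
    n = np.einsum("fgi,fg->fi", nrm, dA)
    n /= np.linalg.norm(n, axis=1)[:, None]
    strain2 = gradu + gradu.transpose(0, 2, 1)
    trac = mu * np.einsum("fij,fj->fi", strain2, n)
    tn = np.einsum("fi,fi->f", trac, n)
    tt = trac - tn[:, None] * n
    w = dA.sum(axis=1)
    return float((np.linalg.norm(tt, axis=1) * w).sum() / w.sum())
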