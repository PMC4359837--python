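"""Partitioned fluid-structure coupling with moving-mesh (ALE) flow.

Dirichlet-Neumann fixed-point iteration per step: solve the flow on the
current fluid domain, hand the interface traction to the wall solver,
relax the returned interface displacement with Aitken's dynamic
under-relaxation, extend it harmonically into the fluid mesh, and
repeat until displacement compatibility and traction equilibrium hold
to tolerance.  Fluid and wall meshes are node-matched at the interface
by construction (``mesh_vessel``); the transfer maps are built once by
nearest-neighbour projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import hexfem
from .flow import (BloodProperties, FlowBC, FlowSolution, FlowSolverError,
                   _Discretization, _picard_solve, outlet_mean_velocity)
from .meshing import FluidMesh, MeshError, WallMesh
from .units import MMHG_PA, MM_M
from .waveforms import Waveform, cycle_mean
from .wall import MooneyRivlinParams, WallState, solve_wall


@dataclass
class CouplingConfig:
    """Outer-loop controls of the partitioned scheme."""

    max_outer_iterations: int = 25
    tolerance: float = 1e-6       # relative interface-displacement residual
    relaxation: float = 0.5       # initial Aitken factor
    dt: float = 0.05              # s, transient stepping

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation factor must lie in (0, 1]")


@dataclass
class InterfaceState:
    """Converged interface fields of one coupling step."""

    traction: np.ndarray          # (F, 3) Pa, fluid-side, per wall face
    displacement_fluid: np.ndarray  # (n_if, 3) mm on fluid interface nodes
    displacement_solid: np.ndarray  # (n_if, 3) mm mapped from the wall
    mesh_velocity: np.ndarray     # (N, 3) m/s on the fluid mesh
    residual: float = 0.0
    iterations: int = 0
    residual_history: list = field(default_factory=list)


class _MeshMotion:
    """Harmonic (Laplacian) extension of interface displacement."""

    def __init__(self, mesh: FluidMesh):
        self.mesh = mesh
        self.ref_nodes = mesh.nodes.copy()
        el = mesh.elements
        dNdx, detJ = hexfem.geometry_ops(self.ref_nodes, el)
        K = np.einsum("egai,egbi,eg->eab", dNdx, dNdx, detJ)
        n = len(self.ref_nodes)
        self.K = hexfem.assemble_csr(K, el, el, n)
        self.if_nodes = mesh.patches["wall_interface"].nodes
        fixed0 = np.unique(np.concatenate(
            [mesh.patches["inlet"].nodes, mesh.patches["outlet"].nodes]))
        self.fixed0 = np.setdiff1d(fixed0, self.if_nodes)
        dir_nodes = np.concatenate([self.if_nodes, self.fixed0])
        keep = np.ones(n)
        keep[dir_nodes] = 0.0
        fix = 1.0 - keep
        import scipy.sparse as sp

        A = sp.diags(keep) @ self.K + sp.diags(fix)
        self.lu = spla.splu(A.tocsc())
        self.keep = keep

    def extend(self, d_iface: np.ndarray) -> np.ndarray:
        """Full-mesh displacement (mm) from interface values (n_if, 3)."""
        n = len(self.ref_nodes)
        out = np.empty((n, 3))
        for c in range(3):
            rhs = np.zeros(n)
            rhs[self.if_nodes] = d_iface[:, c]
            out[:, c] = self.lu.solve(rhs)
        return out


def move_mesh(mesh: FluidMesh, interface_displacement: np.ndarray,
              dt: float = 0.05,
              _motion: Optional[_MeshMotion] = None
              ) -> Tuple[FluidMesh, np.ndarray]:
    """Displace the fluid mesh by a smooth extension of the interface field.

    ``interface_displacement`` (mm): either per interface node
    (aligned with ``patches['wall_interface'].nodes``) or a full (N, 3)
    array whose interface rows are used.  Returns the moved mesh and the
    nodal mesh velocity w = dx/dt (m/s).  Raises if any element inverts.
    """
    motion = _motion if _motion is not None else _MeshMotion(mesh)
    d = np.asarray(interface_displacement, dtype=float)
    if d.shape == (len(mesh.nodes), 3):
        d = d[motion.if_nodes]
    if d.shape != (len(motion.if_nodes), 3):
        raise ValueError("interface_displacement has wrong shape")
    disp = motion.extend(d)
    new_nodes = motion.ref_nodes + disp
    moved = FluidMesh(nodes=new_nodes, elements=mesh.elements,
                      patches=mesh.patches, aux=mesh.aux)
    detJ = hexfem.geometry_ops(new_nodes, mesh.elements)[1]
    if detJ.min() <= 0:
        worst = int(np.argmin(detJ.min(axis=1)))
        raise MeshError(
            f"mesh motion inverts element {worst} "
            f"(min detJ {detJ.min():.3e}); displacement too large for the "
            "local element size")
    w = disp * MM_M / dt
    return moved, w


def fluid_interface_traction(sol: FlowSolution,
                             blood: BloodProperties) -> np.ndarray:
    """Load the blood exerts on the wall surface, per wall face (Pa).

    The fluid Cauchy stress (-pI + mu(grad v + grad v^T)) contracted
    with the *solid-side* outward normal n_s = -n_f, so a positive lumen
    pressure pushes the wall outward.
    """
    mesh = sol.mesh
    mu = blood.dynamic_viscosity
    patch = mesh.patches["wall_interface"]
    x = mesh.nodes * MM_M
    dNdx, _ = hexfem.geometry_ops(x, mesh.elements[patch.elems])
    gradu = hexfem.grad_at_gp(sol.v, mesh.elements[patch.elems], dNdx)
    gradu = gradu.mean(axis=1)  # element-mean velocity gradient
    NQ, _, nrm, _ = hexfem.face_ops(x, patch.faces)
    # pressure at the face quadrature points, normals per point: the
    # traction is returned per (face, quadrature point) so curved faces
    # (stenosis shoulders) transfer without facet-averaging error
    p_gp = np.einsum("ga,fa->fg", NQ, sol.p[patch.faces])
    strain2 = gradu + gradu.transpose(0, 2, 1)
    visc = np.einsum("fij,fgj->fgi", strain2, nrm)
    return p_gp[..., None] * nrm - mu * visc


class _Coupler:
    """Shared machinery of the steady and transient coupling loops."""

    def __init__(self, fmesh: FluidMesh, wmesh: WallMesh,
                 blood: BloodProperties, params: MooneyRivlinParams,
                 config: CouplingConfig):
        self.fmesh, self.wmesh = fmesh, wmesh
        self.blood, self.params, self.config = blood, params, config
        self.motion = _MeshMotion(fmesh)
        f_if = fmesh.patches["wall_interface"].nodes
        w_if = wmesh.patches["interface"].nodes
        tree = cKDTree(wmesh.nodes[w_if])
        dist, idx = tree.query(fmesh.nodes[f_if])
        if dist.max() > 1e-6:
            raise MeshError(
                f"fluid/wall interfaces are not matched (max gap "
                f"{dist.max():.3e} mm); build meshes with mesh_vessel")
        self.f_if = f_if
        self.w_if_mapped = w_if[idx]

    def solid_to_fluid(self, wstate: WallState) -> np.ndarray:
        return wstate.displacement[self.w_if_mapped]

    def step(self, solve_flow, d_iface, wall_kwargs=None):
        """One coupled solve: fixed-point loop with Aitken relaxation.

        ``solve_flow(moved_mesh, mesh_velocity)`` -> FlowSolution.
        Returns (FlowSolution, WallState, InterfaceState, d_iface).
        """
        cfg = self.config
        omega = cfg.relaxation
        r_prev = None
        history = []
        wall_kwargs = wall_kwargs or {}
        for it in range(1, cfg.max_outer_iterations + 1):
            moved, w = move_mesh(self.fmesh, d_iface, cfg.dt,
                                 _motion=self.motion)
            fsol = solve_flow(moved, w)
            trac = fluid_interface_traction(fsol, self.blood)
            wstate = solve_wall(self.wmesh, self.params, trac, **wall_kwargs)
            d_new = self.solid_to_fluid(wstate)
            r = d_new - d_iface
            scale = max(np.abs(d_new).max(), 1e-12)
            res = np.abs(r).max() / scale
            history.append(res)
            if res < cfg.tolerance:
                iface = InterfaceState(
                    traction=trac, displacement_fluid=d_iface,
                    displacement_solid=d_new, mesh_velocity=w,
                    residual=res, iterations=it, residual_history=history)
                return fsol, wstate, iface, d_new
            if r_prev is not None:
                dr = r - r_prev
                denom = float(np.vdot(dr, dr))
                if denom > 0:
                    omega = -omega * float(np.vdot(r_prev, dr)) / denom
                    omega = min(max(omega, 0.05), 1.0)
            d_iface = d_iface + omega * r
            r_prev = r
        raise FlowSolverError(
            f"FSI coupling did not converge in {cfg.max_outer_iterations} "
            f"outer iterations (residual {history[-1]:.3e})", history)


def couple_steady(fmesh: FluidMesh, wmesh: WallMesh,
                  blood: BloodProperties, params: MooneyRivlinParams,
                  bc: FlowBC, config: Optional[CouplingConfig] = None,
                  tol: float = 1e-6
                  ) -> Tuple[FlowSolution, WallState, InterfaceState]:
    """Steady flow coupled to the hyperelastic wall."""
    config = config or CouplingConfig()
    coupler = _Coupler(fmesh, wmesh, blood, params, config)

    def solve_flow(moved, w):
        from .flow import solve_steady

        return solve_steady(moved, blood, bc, tol=tol)

    d0 = np.zeros((len(coupler.f_if), 3))
    fsol, wstate, iface, _ = coupler.step(solve_flow, d0)
    return fsol, wstate, iface


def couple_transient(fmesh: FluidMesh, wmesh: WallMesh,
                     blood: BloodProperties, params: MooneyRivlinParams,
                     bc: FlowBC, config: Optional[CouplingConfig] = None,
                     n_cycles: int = 1, theta: float = 1.0,
                     tol: float = 1e-6, quasi_static: bool = True
                     ) -> List[Tuple[FlowSolution, WallState]]:
    """Pulsatile flow coupled to the wall over full cardiac cycles.

    Starts from the converged steady coupling at cycle-mean boundary
    values; each step repeats the steady coupling post-conditions with
    the ALE convective correction from the mesh velocity.
    """
    config = config or CouplingConfig()
    pw, vw = bc.inlet_pressure, bc.outlet_velocity_measured
    if not isinstance(pw, Waveform) or not isinstance(vw, Waveform):
        raise ValueError("couple_transient expects Waveform boundary values")
    if not np.isclose(pw.period, vw.period, rtol=1e-9):
        raise ValueError("inlet and outlet waveforms must share the period")
    dt = config.dt
    n_steps = int(round(pw.period / dt))
    if not np.isclose(n_steps * dt, pw.period, rtol=1e-9):
        raise ValueError("dt must divide the waveform period")

    bc0 = FlowBC(cycle_mean(pw), cycle_mean(vw), bc.velocity_ratio,
                 bc.outlet_profile, bc.profile_normalize)
    coupler = _Coupler(fmesh, wmesh, blood, params, config)

    def steady_flow(moved, w):
        from .flow import solve_steady

        return solve_steady(moved, blood, bc0, tol=tol)

    d_iface = np.zeros((len(coupler.f_if), 3))
    fsol, wstate, iface, d_iface = coupler.step(steady_flow, d_iface)
    out = [(fsol, wstate)]
    x_prev = coupler.motion.ref_nodes + coupler.motion.extend(d_iface)
    d_hist = [wstate.displacement.copy(), wstate.displacement.copy()]

    for k in range(1, n_cycles * n_steps + 1):
        t = k * dt
        v_mean = outlet_mean_velocity(bc.outlet_velocity_at(t),
                                      bc.velocity_ratio)
        p_in = bc.inlet_pressure_at(t) * MMHG_PA
        u_old = out[-1][0].v

        def solve_flow(moved, w_ext, _t=t, _v=v_mean, _p=p_in, _uo=u_old):
            disc = _Discretization(moved)
            w_step = (moved.nodes - x_prev) * MM_M / dt
            wall_vel = w_step
            return _picard_solve(disc, blood, bc, _v, _p, _t, dt=dt,
                                 u_old=_uo, u_init=_uo,
                                 wall_velocity=wall_vel,
                                 mesh_velocity=w_step, theta=1.0, tol=tol)

        wall_kwargs = {}
        if not quasi_static:
            wall_kwargs = dict(quasi_static=False, d_old=d_hist[-1],
                               d_older=d_hist[-2], dt=dt)
        fsol, wstate, iface, d_iface = coupler.step(solve_flow, d_iface,
                                                    wall_kwargs=wall_kwargs)
        x_prev = coupler.motion.ref_nodes + coupler.motion.extend(d_iface)
        d_hist = [d_hist[-1], wstate.displacement.copy()]
        out.append((fsol, wstate))
    return out
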