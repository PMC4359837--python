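"""Arterial wall mechanics: nine-parameter Mooney-Rivlin hyperelasticity.

The strain energy is a third-order polynomial in the deviatoric
invariants (I1bar - 3) and (I2bar - 3) plus a volumetric penalty
(1/d)(J - 1)^2 with d = 2/K.  The wall momentum balance is solved with
total-Lagrangian hex8 elements; the volumetric term is integrated with a
single central quadrature point (selective reduced integration) to avoid
locking at near-incompressibility, and the tangent is obtained by
differencing the element residual.  Units: mm / MPa / N; interface
tractions arrive in Pa and are converted.

The wall is isotropic and homogeneous; ends are fully fixed; the
traction load is applied as a dead load on the reference configuration,
adequate for the small wall strains of a pressurized coronary segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import hexfem
from .meshing import WallMesh
from .units import PA_MPA


class WallSolverError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class MooneyRivlinParams:
    """Coefficients (MPa) of the nine-parameter Mooney-Rivlin model.

    ``bulk_modulus`` K sets the volumetric penalty through d = 2/K; the
    default 70 MPa makes the response nearly incompressible (Poisson
    ratio ~0.499 against the model's small-strain shear modulus
    2*(c10 + c01) = 0.14 MPa).
    """

    c10: float = 0.07
    c01: float = 0.0
    c20: float = 3.2
    c11: float = 0.0
    c02: float = 0.0
    c30: float = 0.0
    c21: float = 0.0716
    c12: float = 0.0
    c03: float = 0.0
    bulk_modulus: float = 70.0  # MPa

    def __post_init__(self):
        if self.bulk_modulus <= 0:
            raise ValueError("bulk modulus must be > 0")

    @property
    def d(self) -> float:
        """Compressibility parameter d = 2/K (MPa^-1)."""
        return 2.0 / self.bulk_modulus

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus 2*(c10 + c01), MPa."""
        return 2.0 * (self.c10 + self.c01)

    def scaled(self, factor: float) -> "MooneyRivlinParams":
        """All stiffness coefficients (c_ij and K) scaled by ``factor``."""
        kw = {k: getattr(self, k) * factor
              for k in ("c10", "c01", "c20", "c11", "c02", "c30", "c21",
                        "c12", "c03", "bulk_modulus")}
        return MooneyRivlinParams(**kw)


@dataclass
class DeformationState:
    """Deformation gradient and derived invariants at a material point."""

    F: np.ndarray  # (3, 3)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.J <= 0:
            raise ValueError(f"inverted element: J = {self.J:.3g} <= 0")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def I1_bar(self) -> float:
        return float(np.trace(self.C)) * self.J ** (-2.0 / 3.0)

    @property
    def I2_bar(self) -> float:
        C = self.C
        I1 = np.trace(C)
        I2 = 0.5 * (I1**2 - np.trace(C @ C))
        return float(I2) * self.J ** (-4.0 / 3.0)


@dataclass
class WallState:
    """Converged wall displacement field (mm) and bookkeeping."""

    displacement: np.ndarray      # (N, 3) mm
    mesh: WallMesh
    density: float = 1120.0       # kg/m^3
    body_force: float = 0.0
    iterations: int = 0
    residual: float = 0.0
    residual_history: list = field(default_factory=list)

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=1).max())


def strain_energy(state: DeformationState,
                  params: MooneyRivlinParams) -> float:
    """Strain-energy density W (MPa) of the nine-parameter model."""
    x = state.I1_bar - 3.0
    y = state.I2_bar - 3.0
    p = params
    W = (p.c10 * x + p.c01 * y + p.c20 * x**2 + p.c11 * x * y
         + p.c02 * y**2 + p.c30 * x**3 + p.c21 * x**2 * y
         + p.c12 * x * y**2 + p.c03 * y**3)
    W += (1.0 / p.d) * (state.J - 1.0) ** 2
    return float(W)


def _inv3(A):
    """Inverse of (..., 3, 3) arrays via the adjugate (fast, vectorized)."""
    a = A[..., 0, 0]; b = A[..., 0, 1]; c = A[..., 0, 2]
    d = A[..., 1, 0]; e = A[..., 1, 1]; f = A[..., 1, 2]
    g = A[..., 2, 0]; h = A[..., 2, 1]; i = A[..., 2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    inv = np.empty_like(A)
    inv[..., 0, 0] = e * i - f * h
    inv[..., 0, 1] = c * h - b * i
    inv[..., 0, 2] = b * f - c * e
    inv[..., 1, 0] = f * g - d * i
    inv[..., 1, 1] = a * i - c * g
    inv[..., 1, 2] = c * d - a * f
    inv[..., 2, 0] = d * h - e * g
    inv[..., 2, 1] = b * g - a * h
    inv[..., 2, 2] = a * e - b * d
    return inv / det[..., None, None], det


def _pk2_iso(C: np.ndarray, p: MooneyRivlinParams):
    """Deviatoric second Piola-Kirchhoff stress for (..., 3, 3) C."""
    I = np.eye(3)
    Cinv, detC = _inv3(C)
    if np.any(detC <= 0):
        raise WallSolverError("inverted element (det C <= 0)")
    J = np.sqrt(detC)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    C2 = np.einsum("...ij,...jk->...ik", C, C)
    I2 = 0.5 * (I1**2 - np.trace(C2, axis1=-2, axis2=-1))
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = Jm23**2
    x = Jm23 * I1 - 3.0
    y = Jm43 * I2 - 3.0
    W1 = (p.c10 + 2 * p.c20 * x + p.c11 * y + 3 * p.c30 * x**2
          + 2 * p.c21 * x * y + p.c12 * y**2)
    W2 = (p.c01 + p.c11 * x + 2 * p.c02 * y + p.c21 * x**2
          + 2 * p.c12 * x * y + 3 * p.c03 * y**2)
    dI1b = Jm23[..., None, None] * (
        I - (I1 / 3.0)[..., None, None] * Cinv)
    dI2b = Jm43[..., None, None] * (
        I1[..., None, None] * I - C
        - (2.0 * I2 / 3.0)[..., None, None] * Cinv)
    return 2.0 * (W1[..., None, None] * dI1b + W2[..., None, None] * dI2b)


def _pk2_vol(C: np.ndarray, p: MooneyRivlinParams):
    Cinv, detC = _inv3(C)
    J = np.sqrt(detC)
    return ((2.0 / p.d) * (J - 1.0) * J)[..., None, None] * Cinv


class _WallDiscretization:
    """Reference-configuration operators for the wall mesh (mm units)."""

    def __init__(self, mesh: WallMesh):
        self.mesh = mesh
        self.X = mesh.nodes
        self.el = mesh.elements
        self.dNdX, self.detJ = hexfem.geometry_ops(self.X, self.el)
        # single central point for the volumetric term
        _, dN0 = hexfem.shape_hex8(np.zeros((1, 3)))
        Xe = self.X[self.el]
        J0 = np.einsum("gak,eai->egik", dN0, Xe)
        det0 = np.linalg.det(J0)
        J0inv = np.linalg.inv(J0)
        self.dNdX0 = np.einsum("gak,egki->egai", dN0, J0inv)[:, 0]
        self.vol0 = 8.0 * det0[:, 0]  # centroid weight = full ref volume
        self.vdof = (3 * self.el[:, :, None] + np.arange(3)).reshape(-1, 24)

    def internal_force(self, u_el: np.ndarray,
                       params: MooneyRivlinParams) -> np.ndarray:
        """Element internal force (E, 24) at element displacements (E,8,3)."""
        I = np.eye(3)
        F = I + np.einsum("egaj,eai->egij", self.dNdX, u_el)
        C = np.einsum("egki,egkj->egij", F, F)
        S = _pk2_iso(C, params)
        P = np.einsum("egik,egkj->egij", F, S)
        fe = np.einsum("egij,egaj,eg->eai", P, self.dNdX, self.detJ)
        # volumetric part, one central point
        F0 = I + np.einsum("eaj,eai->eij", self.dNdX0, u_el)
        C0 = np.einsum("eki,ekj->eij", F0, F0)
        S0 = _pk2_vol(C0, params)
        P0 = np.einsum("eik,ekj->eij", F0, S0)
        fe += np.einsum("eij,eaj,e->eai", P0, self.dNdX0, self.vol0)
        return fe.reshape(-1, 24)


def interface_load_vector(mesh: WallMesh,
                          traction: Union[float, np.ndarray]) -> np.ndarray:
    """Consistent nodal load (N) from an interface traction field (Pa).

    A scalar is interpreted as a lumen pressure acting against the
    interface normal (which points into the lumen), i.e. pushing the
    wall outward; an array gives traction vectors per interface face
    (F, 3) or per face quadrature point (F, 4, 3).
    """
    patch = mesh.patches["interface"]
    NQ, _, nrm, dA = hexfem.face_ops(mesh.nodes, patch.faces)
    if np.isscalar(traction):
        tq = -float(traction) * PA_MPA * nrm  # (F, g, 3), MPa
    else:
        tfc = np.asarray(traction, dtype=float) * PA_MPA
        if tfc.ndim == 2:
            tfc = tfc[:, None, :]
        tq = np.broadcast_to(tfc, nrm.shape)
    fe = np.einsum("ga,fgi,fg->fai", NQ, tq, dA)
    f = np.zeros(3 * len(mesh.nodes))
    np.add.at(f, 3 * patch.faces[:, :, None] + np.arange(3), fe)
    return f


def solve_wall(mesh: WallMesh, params: MooneyRivlinParams,
               interface_traction: Union[float, np.ndarray],
               quasi_static: bool = True,
               density: float = 1120.0,
               d_old: Optional[np.ndarray] = None,
               d_older: Optional[np.ndarray] = None,
               dt: float = 0.05,
               tol: float = 1e-8, max_iter: int = 40,
               fd_step: float = 1e-6) -> WallState:
    """Wall momentum balance under interface traction with fixed ends.

    Newton iteration with a finite-difference consistent tangent; ends
    fully fixed; optional inertia (``quasi_static=False``) uses a
    second-order backward difference of the two previous displacement
    fields.  ``interface_traction`` in Pa (scalar lumen pressure or
    per-face vectors).
    """
    disc = _WallDiscretization(mesh)
    n = len(mesh.nodes)
    if len(mesh.patches["ends"].nodes) == 0:
        raise WallSolverError("ends patch is empty; the wall is unsupported")
    f_ext = interface_load_vector(mesh, interface_traction)

    mass_fac = 0.0
    accel_rhs = np.zeros(3 * n)
    if not quasi_static:
        if d_old is None or d_older is None:
            raise ValueError("inertial solve needs d_old and d_older")
        # rho [kg/m^3] * a [mm/s^2] * V [mm^3] -> N needs a factor 1e-12
        mass_fac = density * 1e-12 / dt**2
        accel_rhs = mass_fac * (2 * d_old - d_older).ravel()

    fixed = mesh.patches["ends"].nodes
    fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(3 * n), fixed_dofs)

    # lumped mass (consistent enough for the BDF inertia term)
    if mass_fac:
        vol_n = np.zeros(n)
        np.add.at(vol_n, disc.el, np.repeat(disc.detJ.sum(axis=1)[:, None] / 8,
                                            8, axis=1))
        m_diag = np.repeat(vol_n, 3) * mass_fac

    u = np.zeros((n, 3))
    history = []
    scale = max(np.abs(f_ext).max(), 1e-12)
    for it in range(1, max_iter + 1):
        u_el = u[disc.el]
        fe = disc.internal_force(u_el, params)
        r = np.zeros(3 * n)
        np.add.at(r, disc.vdof, fe)
        r -= f_ext
        if mass_fac:
            r += m_diag * u.ravel() - accel_rhs
        rnorm = np.abs(r[free]).max() / scale
        history.append(rnorm)
        if rnorm < tol:
            return WallState(displacement=u, mesh=mesh, density=density,
                             iterations=it - 1, residual=rnorm,
                             residual_history=history)
        # FD tangent: one forward difference per local dof
        h = fd_step
        Ke = np.empty((len(disc.el), 24, 24))
        for k in range(24):
            pert = u_el.copy().reshape(-1, 24)
            pert[:, k] += h
            fe_k = disc.internal_force(pert.reshape(-1, 8, 3), params)
            Ke[:, :, k] = (fe_k - fe) / h
        A = hexfem.assemble_csr(Ke, disc.vdof, disc.vdof, 3 * n)
        if mass_fac:
            A = A + sp.diags(m_diag)
        A, rhs = _zero_dirichlet(A, -r, fixed_dofs)
        du = spla.spsolve(A.tocsc(), rhs)
        u = u + du.reshape(-1, 3)
    raise WallSolverError(
        f"Newton did not converge in {max_iter} iterations "
        f"(residual {history[-1]:.3e})", history)


def _zero_dirichlet(A, rhs, dofs):
    keep = np.ones(A.shape[0])
    keep[dofs] = 0.0
    fix = np.zeros(A.shape[0])
    fix[dofs] = 1.0
    A = sp.diags(keep) @ A + sp.diags(fix)
    rhs = keep * rhs
    return A, rhs


def radial_displacement(state: WallState, section: float) -> float:
    """Mean outward radial displacement (mm) of the interface nodes
    nearest the arclength ``section`` (mm)."""
    mesh = state.mesh
    z = mesh.aux["z"]
    k = int(np.argmin(np.abs(z - section)))
    n_sec = mesh.aux["n_sec"]
    n_theta = mesh.aux["n_theta"]
    ids = k * n_sec + np.arange(n_theta)  # innermost ring of slice k
    x = mesh.nodes[ids]
    ctr = x.mean(axis=0)
    rad = x - ctr
    rad /= np.linalg.norm(rad, axis=1)[:, None]
    return float(np.einsum("ai,ai->a", state.displacement[ids], rad).mean())
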