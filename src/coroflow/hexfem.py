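"""Low-level trilinear hexahedral (hex8) finite-element kernels.

Vectorized over elements with numpy; sparse operators assembled in COO
form and converted to CSR/CSC for scipy's direct solvers.  Reference
element is [-1, 1]^3 with the usual bottom-quad/top-quad node ordering;
2x2x2 Gauss quadrature throughout, 2x2 on boundary quads.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

_G = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points, weights all 1
GP3 = np.array(
    [[sx * _G, sy * _G, sz * _G]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
GP2 = np.array([[sx * _G, sy * _G] for sy in (-1, 1) for sx in (-1, 1)])

_REF = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
    dtype=float,
)
_REFQ = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def shape_hex8(pts: np.ndarray):
    """Hex8 shape functions and reference gradients at points (n, 3).

    Returns ``N`` of shape (n, 8) and ``dN`` of shape (n, 8, 3).
    """
    pts = np.atleast_2d(pts)
    xi = pts[:, None, :]
    r = _REF[None, :, :]
    terms = 1.0 + xi * r  # (n, 8, 3)
    N = 0.125 * terms.prod(axis=2)
    dN = np.empty((len(pts), 8, 3))
    for d in range(3):
        others = [i for i in range(3) if i != d]
        dN[:, :, d] = 0.125 * r[:, :, d] * terms[:, :, others].prod(axis=2)
    return N, dN


def shape_quad4(pts: np.ndarray):
    pts = np.atleast_2d(pts)
    xi = pts[:, None, :]
    r = _REFQ[None, :, :]
    terms = 1.0 + xi * r
    N = 0.25 * terms.prod(axis=2)
    dN = np.empty((len(pts), 4, 2))
    dN[:, :, 0] = 0.25 * r[:, :, 0] * terms[:, :, 1]
    dN[:, :, 1] = 0.25 * r[:, :, 1] * terms[:, :, 0]
    return N, dN


_N3, _dN3 = shape_hex8(GP3)
_NQ, _dNQ = shape_quad4(GP2)


def geometry_ops(nodes: np.ndarray, elements: np.ndarray):
    """Physical shape-function gradients and weighted Jacobians.

    Returns ``dNdx`` (E, ngp, 8, 3), ``detJw`` (E, ngp) where ``detJw``
    already includes the Gauss weights (all 1 here).
    """
    X = nodes[elements]  # (E, 8, 3)
    # dx_i/dxi_k = sum_a dN_a/dxi_k * x_{a,i}
    J = np.einsum("gak,eai->egik", _dN3, X)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dNdx = np.einsum("gak,egki->egai", _dN3, Jinv)
    return dNdx, detJ


def element_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    _, detJ = geometry_ops(nodes, elements)
    return detJ.sum(axis=1)


def min_detJ(nodes: np.ndarray, elements: np.ndarray) -> float:
    _, detJ = geometry_ops(nodes, elements)
    return float(detJ.min())


def face_ops(nodes: np.ndarray, faces: np.ndarray):
    """Quadrature data on boundary quads.

    Returns ``N`` (ngp, 4), ``xq`` (F, ngp, 3) quadrature positions,
    ``nrm`` (F, ngp, 3) unit outward normals and ``dA`` (F, ngp) area
    weights (Gauss weights included).
    """
    X = nodes[faces]  # (F, 4, 3)
    xq = np.einsum("ga,fai->fgi", _NQ, X)
    t1 = np.einsum("ga,fai->fgi", _dNQ[:, :, 0], X)
    t2 = np.einsum("ga,fai->fgi", _dNQ[:, :, 1], X)
    cr = np.cross(t1, t2)
    dA = np.linalg.norm(cr, axis=2)
    nrm = cr / dA[:, :, None]
    return _NQ, xq, nrm, dA


def assemble_csr(ke: np.ndarray, rows_dof: np.ndarray, cols_dof: np.ndarray,
                 n_dof: int) -> sp.csr_matrix:
    """Assemble element matrices ``ke`` (E, a, b) into a CSR matrix.

    ``rows_dof``/``cols_dof`` give the global dof of each local row/col,
    shape (E, a) and (E, b).
    """
    E, a, b = ke.shape
    rows = np.repeat(rows_dof[:, :, None], b, axis=2).ravel()
    cols = np.repeat(cols_dof[:, None, :], a, axis=1).ravel()
    A = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return A.tocsr()


def scatter_vector(fe: np.ndarray, dofs: np.ndarray, n_dof: int) -> np.ndarray:
    out = np.zeros(n_dof)
    np.add.at(out, dofs.ravel(), fe.ravel())
    return out


def interp_at_gp(nodal: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Interpolate a nodal field (N, c) to Gauss points -> (E, ngp, c)."""
    vals = nodal[elements]  # (E, 8, c)
    return np.einsum("ga,ea...->eg...", _N3, vals)


def grad_at_gp(nodal: np.ndarray, elements: np.ndarray,
               dNdx: np.ndarray) -> np.ndarray:
    """Gradient of a nodal field at Gauss points.

    For nodal shape (N, c) returns (E, ngp, c, 3) with entry [..., i, j]
    = d(field_i)/dx_j; for (N,) returns (E, ngp, 3).
    """
    vals = nodal[elements]
    if vals.ndim == 2:
        return np.einsum("egaj,ea->egj", dNdx, vals)
    return np.einsum("egaj,eai->egij", dNdx, vals)
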