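"""Structured hexahedral meshing of the lumen and the arterial wall.

The lumen cross-section uses a butterfly (O-grid) layout: a central
square block surrounded by a body-fitted ring band with geometric
boundary-layer grading toward the wall, so that near-wall resolution is
increased where the shear layer lives.  The wall is an annular shell
meshed with structured brick layers at the lumen interface (matching the
fluid boundary nodes one-to-one) plus hexahedral cells filling the
remaining thickness.  Cross-sections are extruded along the centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .geometry import SurfaceModel

#: lumen face-size range (mm) used for final-resolution runs; the coarse
#: end of the sensitivity ladder is reached by passing larger values.
DEFAULT_FACE_SIZE = (0.09, 0.12)

FaceSize = Union[float, Tuple[float, float]]


class MeshError(ValueError):
    """Raised when a mesh cannot be built from the given sizes."""


@dataclass
class Patch:
    """Named boundary face set: quad connectivity + owning elements."""

    faces: np.ndarray  # (F, 4) node ids, outward-oriented
    elems: np.ndarray  # (F,) owning element ids

    @property
    def nodes(self) -> np.ndarray:
        return np.unique(self.faces)


@dataclass
class HexMesh:
    nodes: np.ndarray                  # (N, 3) mm
    elements: np.ndarray               # (E, 8) hex8 connectivity
    patches: Dict[str, Patch]
    aux: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def volume(self) -> float:
        from .hexfem import element_volumes

        return float(element_volumes(self.nodes, self.elements).sum())

    def patch_area(self, name: str) -> float:
        return float(_quad_areas(self.nodes, self.patches[name].faces).sum())

    def min_jacobian(self) -> float:
        from .hexfem import min_detJ

        return float(min_detJ(self.nodes, self.elements))


class FluidMesh(HexMesh):
    """Hex mesh of the lumen with {inlet, outlet, wall_interface} patches."""


class WallMesh(HexMesh):
    """Hex mesh of the wall with {interface, ends, outer} patches."""


def _quad_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = nodes[faces]  # (F,4,3)
    # split each quad in two triangles
    a1 = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    a2 = 0.5 * np.linalg.norm(
        np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]), axis=1
    )
    return a1 + a2


def _face_size_mid(face_size: FaceSize) -> float:
    if np.iterable(face_size):
        lo, hi = face_size
        if lo <= 0 or hi < lo:
            raise MeshError(f"invalid face_size range {face_size!r}")
        return 0.5 * (lo + hi)
    fs = float(face_size)
    if fs <= 0:
        raise MeshError(f"face_size must be > 0, got {fs}")
    return fs


def _bl_fractions(band_width: float, fs: float, ratio: float,
                  first_factor: float,
                  radial_factor: float = 0.5) -> np.ndarray:
    """Radial node fractions across the band [square edge .. wall].

    Cells grow geometrically away from the wall starting at
    ``first_factor*fs`` until they reach ``radial_factor*fs`` (the
    radial spacing cap; radial resolution controls how well the shear
    profile is resolved, so it is kept finer than the in-plane face
    size), the rest of the band is filled uniformly; fractions are then
    normalized to [0, 1].
    """
    fs_r = radial_factor * fs
    sizes = []
    h = min(first_factor * fs, fs_r)
    total = 0.0
    while total + h < band_width and h < fs_r:
        sizes.append(h)
        total += h
        h *= ratio
    rem = band_width - total
    if sizes and rem < 0.5 * fs_r:
        # avoid a sliver cell: stretch the geometric cells to fill the band
        sizes = [s * band_width / total for s in sizes]
    else:
        n_uni = max(1, int(round(rem / fs_r)))
        sizes.extend([rem / n_uni] * n_uni)
    sizes = np.array(sizes[::-1])  # inner (coarse) -> wall (fine)
    t = np.concatenate([[0.0], np.cumsum(sizes)]) / sizes.sum()
    return t


@dataclass
class _SectionLayout:
    """Shared cross-section template (unit lumen radius) + axial stations."""

    core_xy: np.ndarray      # (n_core, 2) core grid nodes incl. perimeter
    perim_idx: np.ndarray    # (n_theta,) core node ids on the square perimeter
    theta: np.ndarray        # (n_theta,) angles of the boundary rays
    band_t: np.ndarray       # radial fractions across the band, band_t[0]=0
    quads: np.ndarray        # (Q, 4) section quad connectivity (CCW)
    n_theta: int
    n_core: int              # nodes in the core block
    radial_fraction: np.ndarray  # (n_sec,) distance from center / local R
    z: np.ndarray            # axial stations (arclength, mm)

    @property
    def n_sec(self) -> int:
        return self.n_core + (len(self.band_t) - 1) * self.n_theta

    def node_xy(self) -> np.ndarray:
        """All section nodes in the unit-radius template, (n_sec, 2)."""
        sq = self.core_xy[self.perim_idx]
        circ = np.column_stack([np.cos(self.theta), np.sin(self.theta)])
        rings = [
            (1.0 - t) * sq + t * circ for t in self.band_t[1:]
        ]
        return np.vstack([self.core_xy] + rings)


def _build_section(surface: SurfaceModel, face_size: FaceSize,
                   axial_factor: float, bl_ratio: float,
                   bl_first_factor: float) -> _SectionLayout:
    fs = _face_size_mid(face_size)
    radii = surface.lumen_radii
    r_min, r_mean = radii.min(), radii.mean()
    if fs >= r_min:
        raise MeshError(
            f"face_size {fs:.3g} mm cannot resolve the stenosis throat "
            f"(min lumen radius {r_min:.3g} mm)"
        )
    # circumferential count from the mean perimeter, multiple of 4
    n_theta = max(8, 4 * int(np.ceil(2.0 * np.pi * r_mean / fs / 4.0)))
    nc = n_theta // 4
    half = 0.5 / np.sqrt(2.0)  # core corners at template radius 0.5
    g = np.linspace(-half, half, nc + 1)
    gx, gy = np.meshgrid(g, g, indexing="xy")
    core_xy = np.column_stack([gx.ravel(), gy.ravel()])

    def core_id(i, j):  # i: x index, j: y index
        return j * (nc + 1) + i

    # CCW perimeter starting at corner (+half, -half)
    perim = []
    for j in range(nc):
        perim.append(core_id(nc, j))
    for i in range(nc, 0, -1):
        perim.append(core_id(i, nc))
    for j in range(nc, 0, -1):
        perim.append(core_id(0, j))
    for i in range(nc):
        perim.append(core_id(i, 0))
    perim_idx = np.array(perim)
    theta = np.arctan2(core_xy[perim_idx, 1], core_xy[perim_idx, 0])

    band_width_phys = (1.0 - half) * r_mean  # representative, mm
    band_t = _bl_fractions(band_width_phys, fs, bl_ratio, bl_first_factor)
    n_r = len(band_t) - 1
    n_core = (nc + 1) ** 2

    # section quads: core cells, CCW in xy
    quads = []
    for j in range(nc):
        for i in range(nc):
            quads.append([core_id(i, j), core_id(i + 1, j),
                          core_id(i + 1, j + 1), core_id(i, j + 1)])

    def ring_id(k, jj):  # k: band ring 1..n_r, jj circumferential
        return n_core + (k - 1) * n_theta + (jj % n_theta)

    def layer_id(k, jj):
        return perim_idx[jj % n_theta] if k == 0 else ring_id(k, jj)

    for k in range(n_r):
        for jj in range(n_theta):
            quads.append([layer_id(k, jj), layer_id(k + 1, jj),
                          layer_id(k + 1, jj + 1), layer_id(k, jj + 1)])
    quads = np.array(quads, dtype=np.int64)

    # axial stations
    dz = axial_factor * fs
    n_slices = max(2, int(np.ceil(surface.spec.length / dz)))
    z = np.linspace(0.0, surface.spec.length, n_slices + 1)

    layout = _SectionLayout(
        core_xy=core_xy, perim_idx=perim_idx, theta=theta, band_t=band_t,
        quads=quads, n_theta=n_theta, n_core=n_core,
        radial_fraction=None, z=z,
    )
    xy = layout.node_xy()
    layout.radial_fraction = np.linalg.norm(xy, axis=1)
    return layout


def _interp_frames(surface: SurfaceModel, z: np.ndarray):
    """Interpolate centerline point, in-plane basis and radius at ``z``."""
    s = surface.arclengths
    radii = surface.lumen_radii
    centers = np.array([r.center for r in surface.rings])
    tangents = np.array([r.normal for r in surface.rings])
    rz = np.interp(z, s, radii)
    cz = np.column_stack([np.interp(z, s, centers[:, i]) for i in range(3)])
    tz = np.column_stack([np.interp(z, s, tangents[:, i]) for i in range(3)])
    tz /= np.linalg.norm(tz, axis=1)[:, None]
    e2 = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(np.tile(e2, (len(z), 1)), tz)
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    return cz, e1, np.tile(e2, (len(z), 1)), rz


def _extrude(section_xy: np.ndarray, quads: np.ndarray, centers, e1, e2,
             scale: np.ndarray):
    """Stack scaled copies of a 2D section along the centerline frames."""
    n_sec = len(section_xy)
    n_sl = len(centers)
    nodes = np.empty((n_sl * n_sec, 3))
    for k in range(n_sl):
        xy = section_xy * scale[k] if np.ndim(scale[k]) == 0 else scale[k]
        nodes[k * n_sec:(k + 1) * n_sec] = (
            centers[k] + xy[:, 0:1] * e1[k] + xy[:, 1:2] * e2[k]
        )
    q = quads
    elems = np.empty(((n_sl - 1) * len(q), 8), dtype=np.int64)
    for k in range(n_sl - 1):
        lo, hi = k * n_sec, (k + 1) * n_sec
        elems[k * len(q):(k + 1) * len(q)] = np.hstack([q + lo, q + hi])
    return nodes, elems


def _boundary_ring_edges(layout: _SectionLayout) -> np.ndarray:
    """CCW edges (a, b) of the outermost section ring."""
    n_r = len(layout.band_t) - 1
    base = layout.n_core + (n_r - 1) * layout.n_theta
    jj = np.arange(layout.n_theta)
    return np.column_stack([base + jj, base + (jj + 1) % layout.n_theta])


def mesh_lumen(surface: SurfaceModel, face_size: FaceSize = DEFAULT_FACE_SIZE,
               axial_factor: float = 2.0, bl_ratio: float = 1.2,
               bl_first_factor: float = 0.25) -> FluidMesh:
    """Discretize the lumen into a boundary-layer-graded O-grid hex mesh.

    ``face_size`` (mm, scalar or (lo, hi) range) controls the in-plane
    resolution; axial spacing is ``axial_factor * face_size``.  The
    boundary layer toward the wall interface is graded geometrically
    (ratio ``bl_ratio``, first cell ``bl_first_factor * face_size``).
    """
    layout = _build_section(surface, face_size, axial_factor, bl_ratio,
                            bl_first_factor)
    centers, e1, e2, rz = _interp_frames(surface, layout.z)
    xy = layout.node_xy()
    nodes, elems = _extrude(xy, layout.quads, centers, e1, e2, rz)

    n_sec, nq = layout.n_sec, len(layout.quads)
    n_sl = len(layout.z)
    # inlet: slice-0 quads flipped so the normal points upstream (-t)
    inlet_faces = layout.quads[:, ::-1].copy()
    inlet_elems = np.arange(nq)
    # outlet: last slice quads, outward (+t)
    off = (n_sl - 1) * n_sec
    outlet_faces = layout.quads + off
    outlet_elems = np.arange(nq) + (n_sl - 2) * nq
    # wall interface: extruded outer ring edges
    edges = _boundary_ring_edges(layout)
    n_band_start = nq - layout.n_theta  # ring-band quads come last per slice
    wall_faces, wall_elems = [], []
    for k in range(n_sl - 1):
        lo, hi = k * n_sec, (k + 1) * n_sec
        wf = np.column_stack(
            [edges[:, 0] + lo, edges[:, 1] + lo,
             edges[:, 1] + hi, edges[:, 0] + hi]
        )
        wall_faces.append(wf)
        wall_elems.append(k * nq + n_band_start + np.arange(layout.n_theta))
    patches = {
        "inlet": Patch(inlet_faces, inlet_elems),
        "outlet": Patch(outlet_faces, outlet_elems),
        "wall_interface": Patch(np.vstack(wall_faces),
                                np.concatenate(wall_elems)),
    }
    mesh = FluidMesh(nodes=nodes, elements=elems, patches=patches)
    mesh.aux.update(
        face_size=face_size,
        n_sec=n_sec,
        n_slices=n_sl,
        z=layout.z,
        radial_fraction=np.tile(layout.radial_fraction, n_sl),
        theta=layout.theta,
    )
    if mesh.min_jacobian() <= 0.0:
        raise MeshError("lumen mesh has non-positive Jacobians")
    return mesh


def mesh_wall(surface: SurfaceModel, face_size: FaceSize = 0.09,
              n_layers: int = 15, layer_thickness: float = 0.03,
              axial_factor: float = 2.0,
              _layout: Optional[_SectionLayout] = None) -> WallMesh:
    """Discretize the wall shell: brick layers at the interface + fill.

    ``n_layers`` structured layers of ``layer_thickness`` (mm) grow from
    the lumen interface outward; the remaining wall thickness is filled
    with hexahedral cells of roughly ``face_size`` extent.
    """
    t_wall = surface.spec.wall_thickness
    if n_layers < 1:
        raise MeshError(f"n_layers must be >= 1, got {n_layers}")
    if layer_thickness <= 0:
        raise MeshError("layer_thickness must be > 0")
    if n_layers * layer_thickness > t_wall * (1 + 1e-12):
        raise MeshError(
            f"{n_layers} layers x {layer_thickness} mm exceed the wall "
            f"thickness {t_wall} mm"
        )
    layout = _layout if _layout is not None else _build_section(
        surface, face_size, axial_factor, 1.2, 0.25)
    fs = _face_size_mid(face_size)

    # radial offsets from the lumen surface (mm, absolute)
    offs = [k * layer_thickness for k in range(n_layers + 1)]
    rem = t_wall - n_layers * layer_thickness
    if rem > 1e-9:
        n_outer = max(1, int(round(rem / fs)))
        offs.extend(offs[-1] + rem * (k + 1) / n_outer
                    for k in range(n_outer))
    offs = np.array(offs)
    n_rad = len(offs)

    centers, e1, e2, rz = _interp_frames(surface, layout.z)
    circ = np.column_stack([np.cos(layout.theta), np.sin(layout.theta)])
    n_theta = layout.n_theta
    n_sl = len(layout.z)
    n_sec = n_rad * n_theta

    nodes = np.empty((n_sl * n_sec, 3))
    for k in range(n_sl):
        # radius R(z) + absolute offset, along the shared boundary rays
        radii = rz[k] + offs
        xy = (circ[None, :, :] * radii[:, None, None]).reshape(-1, 2)
        nodes[k * n_sec:(k + 1) * n_sec] = (
            centers[k] + xy[:, 0:1] * e1[k] + xy[:, 1:2] * e2[k]
        )

    def sid(r, jj):  # section node id
        return r * n_theta + (jj % n_theta)

    quads = []
    for r in range(n_rad - 1):
        for jj in range(n_theta):
            quads.append([sid(r, jj), sid(r + 1, jj),
                          sid(r + 1, jj + 1), sid(r, jj + 1)])
    quads = np.array(quads, dtype=np.int64)
    _, elems = _extrude(np.zeros((n_sec, 2)), quads, centers, e1, e2,
                        np.zeros(n_sl))
    # _extrude ignored coordinates; recompute connectivity only
    nodes_final = nodes

    nq = len(quads)
    # interface: innermost ring extruded, normal pointing into the lumen
    jj = np.arange(n_theta)
    iface, ielems = [], []
    for k in range(n_sl - 1):
        lo, hi = k * n_sec, (k + 1) * n_sec
        f = np.column_stack([sid(0, jj + 1) + lo, sid(0, jj) + lo,
                             sid(0, jj) + hi, sid(0, jj + 1) + hi])
        iface.append(f)
        ielems.append(k * nq + jj)
    # outer surface
    oface, oelems = [], []
    for k in range(n_sl - 1):
        lo, hi = k * n_sec, (k + 1) * n_sec
        f = np.column_stack([sid(n_rad - 1, jj) + lo,
                             sid(n_rad - 1, jj + 1) + lo,
                             sid(n_rad - 1, jj + 1) + hi,
                             sid(n_rad - 1, jj) + hi])
        oface.append(f)
        oelems.append(k * nq + (n_rad - 2) * n_theta + jj)
    # ends: annulus faces at z=0 and z=L
    ends_f, ends_e = [], []
    for r in range(n_rad - 1):
        f0 = np.column_stack([sid(r, jj + 1), sid(r, jj),
                              sid(r + 1, jj), sid(r + 1, jj + 1)])
        ends_f.append(f0)
        ends_e.append(r * n_theta + jj)
    off_top = (n_sl - 1) * n_sec
    for r in range(n_rad - 1):
        fL = np.column_stack([sid(r, jj), sid(r, jj + 1),
                              sid(r + 1, jj + 1), sid(r + 1, jj)]) + off_top
        ends_f.append(fL)
        ends_e.append((n_sl - 2) * nq + r * n_theta + jj)

    patches = {
        "interface": Patch(np.vstack(iface), np.concatenate(ielems)),
        "outer": Patch(np.vstack(oface), np.concatenate(oelems)),
        "ends": Patch(np.vstack(ends_f), np.concatenate(ends_e)),
    }
    mesh = WallMesh(nodes=nodes_final, elements=elems, patches=patches)
    mesh.aux.update(
        face_size=face_size, n_layers=n_layers,
        layer_thickness=layer_thickness, n_sec=n_sec, n_slices=n_sl,
        z=layout.z, n_theta=n_theta,
    )
    if mesh.min_jacobian() <= 0.0:
        raise MeshError("wall mesh has non-positive Jacobians")
    return mesh


def mesh_vessel(surface: SurfaceModel,
                face_size: FaceSize = DEFAULT_FACE_SIZE,
                wall_face_size: float = 0.09, n_layers: int = 15,
                layer_thickness: float = 0.03, axial_factor: float = 2.0,
                **lumen_kw) -> Tuple[FluidMesh, WallMesh]:
    """Mesh lumen and wall with node-matched interfaces.

    Both meshes are built from the same cross-section layout, so the
    fluid ``wall_interface`` nodes coincide with the wall ``interface``
    nodes exactly.
    """
    fmesh = mesh_lumen(surface, face_size, axial_factor=axial_factor,
                       **lumen_kw)
    layout = _build_section(surface, face_size, axial_factor,
                            lumen_kw.get("bl_ratio", 1.2),
                            lumen_kw.get("bl_first_factor", 0.25))
    wmesh = mesh_wall(surface, wall_face_size, n_layers, layer_thickness,
                      axial_factor=axial_factor, _layout=layout)
    return fmesh, wmesh
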