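"""Minimal ASCII VTK XML writers (.vtu unstructured grids, .vtp polydata).

Only what the pipeline exports: hex meshes with nodal fields, and
boundary/contour surfaces with a patch-id cell array.  Readable by
ParaView and by meshio/pyvista where available.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

VTK_HEX = 12
VTK_QUAD = 9
VTK_POLYLINE = 4


def _da(name: str, data: np.ndarray, ncomp: int) -> str:
    flat = np.asarray(data).reshape(-1)
    if flat.dtype.kind in "iu":
        typ = "Int64"
        body = " ".join(str(int(v)) for v in flat)
    else:
        typ = "Float64"
        body = " ".join(f"{float(v):.12g}" for v in flat)
    return (f'<DataArray type="{typ}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}'
            f"</DataArray>")


def write_vtu(path, nodes: np.ndarray, elements: np.ndarray,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write a hexahedral mesh with optional nodal/cell fields."""
    n_pts, n_cells = len(nodes), len(elements)
    conn = elements.reshape(-1)
    offs = 8 * (np.arange(n_cells) + 1)
    types = np.full(n_cells, VTK_HEX)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>", _da("Points", nodes, 3), "</Points>",
        "<Cells>",
        _da("connectivity", conn, 1),
        _da("offsets", offs, 1),
        _da("types", types, 1),
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(_da(name, arr, ncomp))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(_da(name, arr, ncomp))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_boundary_vtp(path, mesh) -> None:
    """Write a mesh's boundary patches as polydata.

    The ``patch`` cell array holds the index of each face's patch in the
    sorted patch-name list (also written as a FieldData string array).
    """
    names = sorted(mesh.patches)
    faces = np.vstack([mesh.patches[n].faces for n in names])
    ids = np.concatenate([
        np.full(len(mesh.patches[n].faces), i) for i, n in enumerate(names)])
    n_pts, n_faces = len(mesh.nodes), len(faces)
    offs = 4 * (np.arange(n_faces) + 1)
    legend = ";".join(names)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "<PolyData>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfPolys="{n_faces}">',
        "<Points>", _da("Points", mesh.nodes, 3), "</Points>",
        "<Polys>",
        _da("connectivity", faces.reshape(-1), 1),
        _da("offsets", offs, 1),
        "</Polys>",
        "<CellData>", _da("patch", ids, 1), "</CellData>",
        "<FieldData>",
        f'<Array type="String" Name="patch_names">{legend}</Array>',
        "</FieldData>",
        "</Piece>", "</PolyData>", "</VTKFile>",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_surface_vtp(path, surface) -> None:
    """Write lumen and wall contour rings of a surface model as polylines."""
    pts, lines = [], []
    for ring in surface.rings:
        for contour in (ring.lumen, ring.wall):
            start = len(pts)
            pts.extend(contour)
            lines.append(list(range(start, start + len(contour))) + [start])
    pts = np.asarray(pts)
    conn = np.concatenate([np.asarray(l) for l in lines])
    offs = np.cumsum([len(l) for l in lines])
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "<PolyData>",
        f'<Piece NumberOfPoints="{len(pts)}" '
        f'NumberOfLines="{len(lines)}">',
        "<Points>", _da("Points", pts, 3), "</Points>",
        "<Lines>",
        _da("connectivity", conn, 1),
        _da("offsets", offs, 1),
        "</Lines>",
        "</Piece>", "</PolyData>", "</VTKFile>",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
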