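"""Mesh export/import: STL (via trimesh), VTK legacy, and VTU XML.

STL carries surfaces; VTK legacy handles both surfaces (cell type 5) and
tetrahedral volumes (cell type 10); VTU is the XML unstructured flavor for
volumes.  The readers for the VTK formats parse only what the writers here
emit — enough for round-trip validation and external inspection.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

import numpy as np
import trimesh

from .meshing import SurfaceMesh, VolumeMesh

__all__ = ["export_mesh", "read_stl_surface", "read_vtk_mesh", "read_vtu_mesh"]

_FORMATS = {"stl", "stl_ascii", "vtk", "vtu"}


def export_mesh(mesh, path, format: str, cell_data: dict | None = None) -> None:
    """Write a :class:`SurfaceMesh` or :class:`VolumeMesh` to ``path``.

    ``format`` is one of ``stl`` (binary), ``stl_ascii``, ``vtk`` (legacy
    ASCII) or ``vtu`` (XML unstructured, volumes only).  ``cell_data`` maps
    names to per-cell scalar or 3-vector arrays (``vtk`` format only),
    e.g. solver pressure/velocity fields for inspection.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown mesh format {format!r}; choose from {sorted(_FORMATS)}")
    if cell_data and format != "vtk":
        raise ValueError("cell_data is supported by the 'vtk' format only")
    if isinstance(mesh, SurfaceMesh):
        if format == "vtu":
            raise ValueError("vtu export is for volume meshes; use 'vtk' or 'stl'")
        if format in ("stl", "stl_ascii"):
            tm = mesh.to_trimesh()
            tm.export(path, file_type="stl_ascii" if format == "stl_ascii" else "stl")
        else:
            _write_vtk_legacy(path, mesh.vertices, mesh.triangles, 5, cell_data)
    elif isinstance(mesh, VolumeMesh):
        if format in ("stl", "stl_ascii"):
            raise ValueError("stl export is for surface meshes; use 'vtk' or 'vtu'")
        if format == "vtk":
            _write_vtk_legacy(path, mesh.vertices, mesh.tets, 10, cell_data)
        else:
            _write_vtu(path, mesh.vertices, mesh.tets)
    else:
        raise TypeError(f"cannot export object of type {type(mesh).__name__}")


def _write_vtk_legacy(
    path, points: np.ndarray, cells: np.ndarray, cell_type: int,
    cell_data: dict | None = None,
) -> None:
    n_pts, n_cells = len(points), len(cells)
    k = cells.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n_pts} double\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {n_cells} {n_cells * (k + 1)}\n")
        for c in cells:
            fh.write(f"{k} " + " ".join(str(int(v)) for v in c) + "\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        fh.write("\n".join([str(cell_type)] * n_cells) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {n_cells}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")


def _write_vtu(path, points: np.ndarray, tets: np.ndarray) -> None:
    n_pts, n_cells = len(points), len(tets)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write(
            '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        )
        fh.write("  <UnstructuredGrid>\n")
        fh.write(f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n')
        fh.write("      <Points>\n")
        fh.write('        <DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        for p in points:
            fh.write(f"          {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write("        </DataArray>\n      </Points>\n      <Cells>\n")
        fh.write('        <DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for c in tets:
            fh.write("          " + " ".join(str(int(v)) for v in c) + "\n")
        fh.write("        </DataArray>\n")
        fh.write('        <DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(
            "          " + " ".join(str(4 * (i + 1)) for i in range(n_cells)) + "\n"
        )
        fh.write("        </DataArray>\n")
        fh.write('        <DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write("          " + " ".join(["10"] * n_cells) + "\n")
        fh.write("        </DataArray>\n      </Cells>\n")
        fh.write("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")


def read_stl_surface(path) -> trimesh.Trimesh:
    """Load an STL file (ascii or binary) as a trimesh."""
    return trimesh.load(path, file_type="stl", process=False)


def read_vtk_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """(points, cells) from a legacy ASCII VTK unstructured grid."""
    with open(path) as fh:
        text = fh.read()
    mp = re.search(r"POINTS\s+(\d+)\s+\w+\n", text)
    n_pts = int(mp.group(1))
    tokens = text[mp.end() :].split()
    points = np.array(tokens[: 3 * n_pts], dtype=float).reshape(n_pts, 3)
    mc = re.search(r"CELLS\s+(\d+)\s+(\d+)\n", text)
    n_cells, total = int(mc.group(1)), int(mc.group(2))
    ctoks = text[mc.end() :].split()[:total]
    cells, i = [], 0
    for _ in range(n_cells):
        k = int(ctoks[i])
        cells.append([int(v) for v in ctoks[i + 1 : i + 1 + k]])
        i += k + 1
    return points, np.array(cells, dtype=int)


def read_vtu_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """(points, tets) from an ASCII VTU file as written by :func:`export_mesh`."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    points = np.array(pts.text.split(), dtype=float).reshape(-1, 3)
    conn = piece.find("Cells/DataArray[@Name='connectivity']")
    cells = np.array(conn.text.split(), dtype=int).reshape(-1, 4)
    return points, cells
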