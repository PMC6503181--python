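"""Minimal VRML97 IndexedFaceSet reader/writer.

Reconstruction workstations export lumen surfaces as VRML97 scene files; only
the geometry is of interest here, so the reader extracts every
``IndexedFaceSet`` (``Coordinate point`` + ``coordIndex``), fans polygons
into triangles, and applies at most one top-level ``Transform``
(translation / scale / axis-angle rotation).  Units are assumed to be mm.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .meshing import STRIP_UNKNOWN, SurfaceMesh

__all__ = ["read_vrml_surface", "write_vrml_surface", "VrmlError"]


class VrmlError(ValueError):
    """Raised when a VRML file contains no usable IndexedFaceSet."""


_FLOAT = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def _strip_comments(text: str) -> str:
    return re.sub(r"#[^\n]*", "", text)


def _find_bracket_block(text: str, keyword: str, start: int = 0) -> tuple[str, int] | None:
    m = re.compile(rf"\b{keyword}\b\s*\[", re.S).search(text, start)
    if not m:
        return None
    depth, i = 1, m.end()
    while depth and i < len(text):
        if text[i] == "[":
            depth += 1
        elif text[i] == "]":
            depth -= 1
        i += 1
    return text[m.end() : i - 1], i


def _parse_transform(text: str) -> np.ndarray:
    """4x4 matrix from the first top-level Transform, else identity."""
    mat = np.eye(4)
    m = re.search(r"\bTransform\b\s*{", text)
    if not m:
        return mat
    head = text[m.end() : m.end() + 2000]  # fields precede children in practice
    scale = np.ones(3)
    trans = np.zeros(3)
    rot = None
    ms = re.search(rf"\bscale\s+({_FLOAT})\s+({_FLOAT})\s+({_FLOAT})", head)
    if ms:
        scale = np.array([float(g) for g in ms.groups()])
    mt = re.search(rf"\btranslation\s+({_FLOAT})\s+({_FLOAT})\s+({_FLOAT})", head)
    if mt:
        trans = np.array([float(g) for g in mt.groups()])
    mr = re.search(
        rf"\brotation\s+({_FLOAT})\s+({_FLOAT})\s+({_FLOAT})\s+({_FLOAT})", head
    )
    if mr:
        axis = np.array([float(g) for g in mr.groups()[:3]])
        angle = float(mr.groups()[3])
        n = np.linalg.norm(axis)
        if n > 0 and angle != 0.0:
            axis = axis / n
            k = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    r = rot if rot is not None else np.eye(3)
    mat[:3, :3] = r * scale[None, :]
    mat[:3, 3] = trans
    return mat


def read_vrml_surface(path) -> SurfaceMesh:
    """Read a VRML97 file into a :class:`SurfaceMesh` (triangulated by fanning)."""
    with open(path) as fh:
        text = _strip_comments(fh.read())

    transform = _parse_transform(text)

    all_verts: list[np.ndarray] = []
    all_tris: list[np.ndarray] = []
    offset = 0
    pos = 0
    while True:
        m = re.compile(r"\bIndexedFaceSet\b").search(text, pos)
        if not m:
            break
        pt = _find_bracket_block(text, "point", m.end())
        ci = _find_bracket_block(text, "coordIndex", m.end())
        if pt is None or ci is None:
            pos = m.end()
            continue
        coords = np.array(
            [float(v) for v in re.split(r"[,\s]+", pt[0].strip()) if v], dtype=float
        ).reshape(-1, 3)
        idx = [int(v) for v in re.split(r"[,\s]+", ci[0].strip()) if v]
        faces: list[list[int]] = []
        cur: list[int] = []
        for k in idx:
            if k == -1:
                if len(cur) >= 3:
                    faces.append(cur)
                cur = []
            else:
                cur.append(k)
        if len(cur) >= 3:
            faces.append(cur)
        tris = []
        for face in faces:
            for a, b in zip(face[1:-1], face[2:]):
                tris.append((face[0] + offset, a + offset, b + offset))
        all_verts.append(coords)
        all_tris.append(np.array(tris, dtype=int))
        offset += len(coords)
        pos = max(pt[1], ci[1])

    if not all_verts:
        raise VrmlError(f"{path}: no IndexedFaceSet with coordIndex found")

    vertices = np.vstack(all_verts)
    vertices = (transform[:3, :3] @ vertices.T).T + transform[:3, 3]
    triangles = np.vstack(all_tris)

    edges = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        warnings.warn(
            f"{path}: non-manifold surface ({int((counts > 2).sum())} edges shared "
            "by >2 triangles)",
            stacklevel=2,
        )
    return SurfaceMesh(
        vertices=vertices,
        triangles=triangles,
        strip_of_triangle=np.full(len(triangles), STRIP_UNKNOWN),
        n_stations=0,
        capped=False,
    )


def write_vrml_surface(mesh: SurfaceMesh, path) -> None:
    """Write a triangle surface as a VRML97 IndexedFaceSet."""
    with open(path, "w") as fh:
        fh.write("#VRML V2.0 utf8\n")
        fh.write("Shape {\n  geometry IndexedFaceSet {\n    coord Coordinate {\n")
        fh.write("      point [\n")
        for v in mesh.vertices:
            fh.write(f"        {v[0]:.9g} {v[1]:.9g} {v[2]:.9g},\n")
        fh.write("      ]\n    }\n    coordIndex [\n")
        for t in mesh.triangles:
            fh.write(f"      {t[0]}, {t[1]}, {t[2]}, -1,\n")
        fh.write("    ]\n  }\n}\n")
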