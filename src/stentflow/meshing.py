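"""Lumen meshing: triangle-strip surfaces and swept tetrahedral volumes.

The lumen surface is built by discretizing every cross-section as a ring of
points in the plane normal to the local tangent, using rotation-minimizing
frames (double reflection) so strips do not twist, and joining consecutive
rings with triangle strips — 2 * n_circumferential triangles per strip, i.e.
128 per strip at the default circumferential resolution of 64.

The volume mesh is a structured sweep: each cross-section carries a 2D disk
triangulation (a center fan plus concentric rings, with geometrically graded
boundary inflation layers near the wall), consecutive disks are joined into
prisms, and each prism is split into 3 tetrahedra with an index-ordering rule
that guarantees conforming diagonals between neighboring prisms.

Also here: fitting cross-sections back onto a tubular surface (the inverse
of surface generation, used to ingest externally reconstructed surfaces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import VesselGeometry, resample_vessel, validate_vessel

__all__ = [
    "SurfaceMesh",
    "VolumeMesh",
    "build_surface_mesh",
    "build_volume_mesh",
    "fit_cross_sections",
    "rotation_minimizing_frames",
    "MeshingError",
]

#: default circumferential resolution: 64 quads -> 128 triangles per strip
DEFAULT_N_CIRC = 64

STRIP_INLET_CAP = -1
STRIP_OUTLET_CAP = -2
STRIP_UNKNOWN = -3

WALL, INLET, OUTLET = 0, 1, 2


class MeshingError(ValueError):
    """Raised when a mesh cannot be built from the given geometry."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle lumen surface.

    ``strip_of_triangle[t]`` is the inter-station strip index of triangle
    ``t`` (0-based, strip i lies between stations i and i+1); cap triangles
    carry the sentinels ``STRIP_INLET_CAP`` / ``STRIP_OUTLET_CAP`` and
    imported meshes ``STRIP_UNKNOWN``.
    """

    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (T, 3) int
    strip_of_triangle: np.ndarray  # (T,) int
    n_stations: int = 0
    capped: bool = False

    @property
    def wall_triangles(self) -> np.ndarray:
        return self.triangles[self.strip_of_triangle >= 0]

    @property
    def n_strips(self) -> int:
        strips = self.strip_of_triangle[self.strip_of_triangle >= 0]
        return int(strips.max()) + 1 if len(strips) else 0

    def triangles_per_strip(self) -> np.ndarray:
        return np.bincount(
            self.strip_of_triangle[self.strip_of_triangle >= 0],
            minlength=self.n_strips,
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.triangles.copy(), process=False
        )

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.triangles)

    def wall_area(self) -> float:
        tri = self.vertices[self.wall_triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


@dataclass
class VolumeMesh:
    """Tetrahedral lumen volume from a structured sweep.

    Boundary faces are outward-oriented and labeled ``WALL``/``INLET``/
    ``OUTLET``.  ``vertex_layer`` tags each vertex with its inflation-layer
    index (1..n_layers counted inward from the wall; 0 = core).  The source
    vessel's per-station arc lengths and radii travel with the mesh so
    solvers can report section-averaged quantities along the vessel.
    """

    vertices: np.ndarray  # (V, 3) mm
    tets: np.ndarray  # (C, 4) int, positively oriented
    boundary_faces: np.ndarray  # (B, 3) int, outward
    boundary_labels: np.ndarray  # (B,) int in {WALL, INLET, OUTLET}
    vertex_layer: np.ndarray  # (V,) int
    vertex_station: np.ndarray  # (V,) int
    #: source prism of each tetrahedron (swept meshes split each prism into
    #: 3 tets); lets the flow solver agglomerate them back into well-shaped
    #: prismatic control volumes.  None for imported/unstructured meshes.
    prism_of_tet: np.ndarray | None = None
    station_s: np.ndarray = field(default_factory=lambda: np.empty(0))  # (n_st,) mm
    station_radius: np.ndarray = field(default_factory=lambda: np.empty(0))
    station_tangent: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    @property
    def vertex_s(self) -> np.ndarray:
        return self.station_s[self.vertex_station]

    def cell_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return (
            np.einsum(
                "ij,ij->i",
                v[:, 1] - v[:, 0],
                np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]),
            )
            / 6.0
        )

    def total_volume(self) -> float:
        return float(self.cell_volumes().sum())


# ---------------------------------------------------------------------------
# Rotation-minimizing frames (double reflection)
# ---------------------------------------------------------------------------


def rotation_minimizing_frames(
    centers: np.ndarray, tangents: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normals/binormals along a polyline with minimal twist.

    Double-reflection method: propagate the initial normal by reflecting
    through the chord bisector plane and then the new tangent plane.
    Returns (normals, binormals), each (n, 3), with ``b = t x n``.
    """
    n_pts = len(centers)
    t = tangents
    # seed normal: any unit vector orthogonal to t[0]
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, t[0])) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    n0 = seed - np.dot(seed, t[0]) * t[0]
    normals = np.empty_like(centers)
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(n_pts - 1):
        v1 = centers[i + 1] - centers[i]
        c1 = np.dot(v1, v1)
        rl = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tl = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tl
        c2 = np.dot(v2, v2)
        if c2 > 1e-30:
            normals[i + 1] = rl - (2.0 / c2) * np.dot(v2, rl) * v2
        else:
            normals[i + 1] = rl
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    binormals = np.cross(t, normals)
    return normals, binormals


def _check_no_plane_crossing(vessel: VesselGeometry) -> None:
    t = vessel.tangents()
    dots = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0)
    angles = np.arccos(dots)
    ds = np.diff(vessel.s)
    r = np.maximum(vessel.radii[:-1], vessel.radii[1:])
    bad = r * angles > ds
    if np.any(bad):
        i = int(np.argmax(bad))
        raise MeshingError(
            f"cross-section planes cross inside the lumen near s={vessel.s[i]:.2f} mm "
            f"(turn angle {np.degrees(angles[i]):.1f} deg over {ds[i]:.3f} mm at "
            f"radius {r[i]:.2f} mm); resample the vessel at a smaller step"
        )


# ---------------------------------------------------------------------------
# Surface mesh
# ---------------------------------------------------------------------------


def build_surface_mesh(
    vessel: VesselGeometry,
    n_circumferential: int = DEFAULT_N_CIRC,
    caps: bool = True,
) -> SurfaceMesh:
    """Discretize the lumen as rings joined by triangle strips.

    Each of the ``n_stations - 1`` strips contains ``2 * n_circumferential``
    triangles (128 at the default resolution).  With ``caps`` the inlet and
    outlet are closed by planar triangle fans, making the surface watertight.
    """
    if n_circumferential < 8 or n_circumferential % 2:
        raise ValueError("n_circumferential must be even and >= 8")
    validate_vessel(vessel)
    _check_no_plane_crossing(vessel)

    n_st = vessel.n_sections
    nc = n_circumferential
    t = vessel.tangents()
    normals, binormals = rotation_minimizing_frames(vessel.centers, t)

    theta = 2.0 * np.pi * np.arange(nc) / nc
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # ring vertices: station-major layout
    rings = (
        vessel.centers[:, None, :]
        + vessel.radii[:, None, None]
        * (cos_t[None, :, None] * normals[:, None, :] + sin_t[None, :, None] * binormals[:, None, :])
    )
    vertices = rings.reshape(-1, 3)

    j = np.arange(nc)
    jp = (j + 1) % nc
    tris = []
    strips = []
    for i in range(n_st - 1):
        a = i * nc + j
        b = i * nc + jp
        c = (i + 1) * nc + jp
        d = (i + 1) * nc + j
        tris.append(np.column_stack([a, b, c]))
        tris.append(np.column_stack([a, c, d]))
        strips.append(np.full(2 * nc, i))
    triangles = np.vstack(tris)
    strip_ids = np.concatenate(strips)

    if caps:
        c_in = len(vertices)
        c_out = c_in + 1
        vertices = np.vstack([vertices, vessel.centers[0], vessel.centers[-1]])
        inlet_tris = np.column_stack([np.full(nc, c_in), jp, j])
        base = (n_st - 1) * nc
        outlet_tris = np.column_stack([np.full(nc, c_out), base + j, base + jp])
        triangles = np.vstack([triangles, inlet_tris, outlet_tris])
        strip_ids = np.concatenate(
            [strip_ids, np.full(nc, STRIP_INLET_CAP), np.full(nc, STRIP_OUTLET_CAP)]
        )

    return SurfaceMesh(vertices, triangles, strip_ids, n_stations=n_st, capped=caps)


# ---------------------------------------------------------------------------
# Volume mesh
# ---------------------------------------------------------------------------


def _radial_fractions(
    n_layers: int, growth: float, first_layer_frac: float, target_edge: float, r_ref: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ring radii as fractions of the local radius, plus per-ring layer tags.

    Inflation-layer thicknesses grow geometrically away from the wall
    (first layer at the wall is ``first_layer_frac`` of the local radius);
    the core is subdivided uniformly at roughly ``target_edge`` spacing.
    """
    if n_layers > 0:
        thick = first_layer_frac * growth ** np.arange(n_layers)  # wall -> core
        if thick.sum() >= 0.6:
            raise ValueError("inflation layers occupy >60% of the radius")
        core_outer = 1.0 - thick.sum()
        infl = core_outer + np.cumsum(thick[::-1])  # ascending, last == 1
    else:
        core_outer = 1.0
        infl = np.empty(0)
    n_core = max(1, int(round(core_outer * r_ref / target_edge)))
    core = np.linspace(0.0, core_outer, n_core + 1)[1:]
    fracs = np.concatenate([core, infl])
    # layer tag per ring: 0 core; inflation rings numbered n_layers..1 toward wall
    tags = np.concatenate(
        [np.zeros(n_core, dtype=int), np.arange(n_layers, 0, -1)]
    )
    return fracs, tags


_PRISM_ROT = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (bottom 0-1-2, top 3-4-5, vertical edges i/i+3) into tets.

    The smallest global vertex index is rotated to position 0; the remaining
    quad face takes the diagonal through its smallest index.  Because the
    choice depends only on global indices, diagonals agree on quad faces
    shared by neighboring prisms, so the tetrahedralization conforms.
    """
    argmin = np.argmin(prisms, axis=1)
    rotated = np.take_along_axis(prisms, _PRISM_ROT[argmin], axis=1)
    v = rotated
    # quad face (1, 2, 5, 4): diagonal 1-5 or 2-4 by smallest index
    use_15 = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((len(prisms), 3, 4), dtype=prisms.dtype)
    a = v[use_15]
    tets[use_15, 0] = a[:, [0, 1, 2, 5]]
    tets[use_15, 1] = a[:, [0, 1, 5, 4]]
    tets[use_15, 2] = a[:, [0, 4, 5, 3]]
    b = v[~use_15]
    tets[~use_15, 0] = b[:, [0, 1, 2, 4]]
    tets[~use_15, 1] = b[:, [0, 4, 2, 5]]
    tets[~use_15, 2] = b[:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def _disk_triangulation(nc: int, n_rings: int) -> np.ndarray:
    """Triangles of the reference disk: center vertex 0, ring q at
    ``1 + q*nc .. nc`` points.  ``nc*(2*n_rings - 1)`` triangles."""
    j = np.arange(nc)
    jp = (j + 1) % nc
    tris = [np.column_stack([np.zeros(nc, dtype=int), 1 + j, 1 + jp])]
    for q in range(n_rings - 1):
        a = 1 + q * nc + j
        b = 1 + q * nc + jp
        c = 1 + (q + 1) * nc + jp
        d = 1 + (q + 1) * nc + j
        tris.append(np.column_stack([a, b, c]))
        tris.append(np.column_stack([a, c, d]))
    return np.vstack(tris)


def build_volume_mesh(
    vessel: VesselGeometry,
    n_circumferential: int = 32,
    n_layers: int = 3,
    growth: float = 1.2,
    first_layer_frac: float = 0.05,
    target_edge: float = 0.3,
    axial_step: float | None = None,
) -> VolumeMesh:
    """Structured-sweep tetrahedral mesh of the lumen with inflation layers.

    Each inter-station slab is filled with prisms (from the 2D disk
    triangulation of the cross-section) split into 3 tetrahedra each; near
    the wall the radial rings are geometrically graded (``n_layers`` layers,
    ``growth`` ratio, first layer ``first_layer_frac`` of the local radius).
    ``axial_step`` resamples the vessel axially first (defaults to the
    vessel's own stations).
    """
    if axial_step is not None:
        vessel = resample_vessel(vessel, axial_step)
    validate_vessel(vessel)
    _check_no_plane_crossing(vessel)
    if np.any(vessel.radii <= 0):
        raise MeshingError("degenerate (zero-radius) section")

    nc = n_circumferential
    n_st = vessel.n_sections
    r_ref = float(np.mean(vessel.radii))
    fracs, ring_tags = _radial_fractions(
        n_layers, growth, first_layer_frac, target_edge, r_ref
    )
    n_rings = len(fracs)
    m = 1 + n_rings * nc  # vertices per station

    t = vessel.tangents()
    normals, binormals = rotation_minimizing_frames(vessel.centers, t)
    theta = 2.0 * np.pi * np.arange(nc) / nc
    dirs = (
        np.cos(theta)[:, None, None] * normals[None]
        + np.sin(theta)[:, None, None] * binormals[None]
    )  # (nc, n_st, 3)

    verts = np.empty((n_st, m, 3))
    verts[:, 0] = vessel.centers
    # ring q occupies local slots 1 + q*nc .. 1 + (q+1)*nc
    offsets = (
        fracs[:, None, None, None] * vessel.radii[None, None, :, None] * dirs[None]
    )  # (n_rings, nc, n_st, 3)
    ring_pts = vessel.centers[None, None] + offsets  # (n_rings, nc, n_st, 3)
    verts[:, 1:] = ring_pts.transpose(2, 0, 1, 3).reshape(n_st, n_rings * nc, 3)
    vertices = verts.reshape(-1, 3)

    vertex_layer = np.tile(
        np.concatenate([[0], np.repeat(ring_tags, nc)]), n_st
    )
    vertex_station = np.repeat(np.arange(n_st), m)

    disk = _disk_triangulation(nc, n_rings)  # (ntri, 3) local indices
    slabs = np.arange(n_st - 1)
    bottom = (slabs[:, None, None] * m + disk[None]).reshape(-1, 3)
    top = bottom + m
    prisms = np.concatenate([bottom, top], axis=1)
    tets = _split_prisms(prisms)
    prism_of_tet = np.repeat(np.arange(len(prisms)), 3)

    # enforce positive orientation
    p = vertices[tets]
    vol6 = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    boundary_faces, boundary_labels = _boundary_faces(tets, vertex_station, n_st)

    return VolumeMesh(
        vertices=vertices,
        tets=tets,
        boundary_faces=boundary_faces,
        boundary_labels=boundary_labels,
        vertex_layer=vertex_layer,
        vertex_station=vertex_station,
        station_s=vessel.s.copy(),
        station_radius=vessel.radii.copy(),
        station_tangent=t,
        prism_of_tet=prism_of_tet,
    )


def _boundary_faces(
    tets: np.ndarray, vertex_station: np.ndarray, n_st: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extract outward-oriented boundary faces and label them."""
    # outward faces of a positively oriented tet
    face_idx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, face_idx].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    boundary = faces[counts[inverse] == 1]
    st = vertex_station[boundary]
    labels = np.full(len(boundary), WALL)
    labels[np.all(st == 0, axis=1)] = INLET
    labels[np.all(st == n_st - 1, axis=1)] = OUTLET
    return boundary, labels


# ---------------------------------------------------------------------------
# Cross-section fitting (surface -> vessel)
# ---------------------------------------------------------------------------


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Vertex loops of edges referenced by exactly one face."""
    edges = mesh.edges_sorted
    _, inverse, counts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
    open_edges = mesh.edges[counts[inverse] == 1]
    if len(open_edges) == 0:
        return []
    adj: dict[int, list[tuple[int, int]]] = {}
    for eid, (a, b) in enumerate(open_edges):
        adj.setdefault(int(a), []).append((int(b), eid))
        adj.setdefault(int(b), []).append((int(a), eid))
    loops = []
    used: set[int] = set()
    for eid, (a, b) in enumerate(open_edges):
        if eid in used:
            continue
        loop = [int(a)]
        used.add(eid)
        cur = int(b)
        while cur != loop[0]:
            loop.append(cur)
            step = next(((v, k) for v, k in adj[cur] if k not in used), None)
            if step is None:
                break
            used.add(step[1])
            cur = step[0]
        loops.append(np.array(loop))
    return loops


def _plane_section(
    mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray, near: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """(centroid, area) of the cut polygon nearest to ``near``, or None."""
    sec = mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return None
    planar, to_3d = sec.to_2D()
    polys = planar.polygons_full
    if not polys:
        return None
    best = None
    for poly in polys:
        c2 = np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
        c3 = (to_3d @ c2)[:3]
        d = np.linalg.norm(c3 - near)
        if best is None or d < best[0]:
            best = (d, c3, float(poly.area))
    return best[1], best[2]


def fit_cross_sections(surface, step: float = 0.5) -> VesselGeometry:
    """Recover a cross-section vessel model from a tubular surface.

    Sweeps cutting planes along a smoothed centroid path every ``step`` mm;
    each cut's radius is that of the equivalent-area circle,
    ``sqrt(area / pi)``.  The surface must be a single open tube with exactly
    two boundary loops (single-lumen; side branches are not supported).
    """
    mesh = surface.to_trimesh() if isinstance(surface, SurfaceMesh) else surface
    loops = _boundary_loops(mesh)
    if len(loops) != 2:
        raise MeshingError(
            f"expected a single tube with 2 boundary loops, found {len(loops)} "
            "(branched or capped surfaces are not supported)"
        )
    c0 = mesh.vertices[loops[0]].mean(axis=0)
    c1 = mesh.vertices[loops[1]].mean(axis=0)
    axis = c1 - c0
    length = float(np.linalg.norm(axis))
    axis /= length
    eps = min(0.25 * step, 0.05 * length)

    def sweep(path_pts: np.ndarray, path_s: np.ndarray, targets: np.ndarray):
        centers, radii, s_out = [], [], []
        tang = np.gradient(path_pts, path_s, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        for sk in targets:
            origin = np.column_stack(
                [np.interp(sk, path_s, path_pts[:, k]) for k in range(3)]
            )[0]
            nrm = np.column_stack(
                [np.interp(sk, path_s, tang[:, k]) for k in range(3)]
            )[0]
            nrm /= np.linalg.norm(nrm)
            hit = _plane_section(mesh, origin, nrm, origin)
            if hit is None:
                continue
            centroid, area = hit
            centers.append(centroid)
            radii.append(np.sqrt(area / np.pi))
            s_out.append(sk)
        return np.array(centers), np.array(radii), np.array(s_out)

    targets = np.arange(eps, length - eps / 2, step)
    if length - eps - targets[-1] > step / 2:
        targets = np.append(targets, length - eps)
    line = np.vstack([c0, c1])
    centers, radii, _ = sweep(line, np.array([0.0, length]), targets)
    if len(centers) < 3:
        raise MeshingError("could not section the surface along its axis")
    # refine once: re-slice along the smoothed centroid path
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(centers, axis=0), axis=1))]
    )
    targets2 = np.arange(0.0, chord[-1] + step / 4, step)
    centers2, radii2, _ = sweep(centers, chord, np.clip(targets2, 0, chord[-1]))
    chords = np.linalg.norm(np.diff(centers2, axis=0), axis=1)
    keep = np.concatenate([[True], chords > 1e-9])
    centers2, radii2 = centers2[keep], radii2[keep]
    s = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(centers2, axis=0), axis=1))]
    )
    vessel = VesselGeometry(centers2, radii2, s, name="fitted")
    validate_vessel(vessel)
    return vessel
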