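"""Surface strips, swept tet volumes, VRML I/O, mesh export, section fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

import stentflow as sf
from stentflow.meshfiles import export_mesh, read_stl_surface, read_vtk_mesh, read_vtu_mesh
from stentflow.meshing import INLET, OUTLET, WALL, MeshingError
from stentflow.vrml import VrmlError, read_vrml_surface, write_vrml_surface

from conftest import frustum_volume


class TestSurfaceMesh:
    def test_strip_contract_128_triangles(self):
        v = sf.make_synthetic_vessel(9.0, 1.5, [], step=1.0)  # 10 stations
        surf = sf.build_surface_mesh(v)
        assert surf.n_strips == 9
        assert np.all(surf.triangles_per_strip() == 128)
        assert len(surf.wall_triangles) == 9 * 128

    def test_capped_cylinder_is_closed_genus_zero(self, straight_tube):
        surf = sf.build_surface_mesh(straight_tube)
        assert surf.euler_characteristic() == 2
        tm = surf.to_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0  # consistently outward-oriented

    def test_wall_area_matches_cylinder_closed_form(self, straight_tube):
        surf = sf.build_surface_mesh(straight_tube)
        exact = 2 * np.pi * 1.5 * 50.0
        assert surf.wall_area() == pytest.approx(exact, rel=0.005)

    def test_curved_vessel_meshes_without_twist(self):
        v = sf.make_synthetic_vessel(40.0, 1.5, [], curvature=0.02, step=0.5)
        surf = sf.build_surface_mesh(v)
        tm = surf.to_trimesh()
        assert tm.is_watertight
        # no degenerate triangles from strip twist
        assert tm.area_faces.min() > 0

    def test_plane_crossing_rejected_with_advice(self):
        # turn angle per step (1 rad) times the lumen radius exceeds the
        # station spacing, so adjacent section planes cross inside the lumen
        v = sf.make_synthetic_vessel(40.0, 4.5, [], curvature=0.25, step=4.0)
        with pytest.raises(MeshingError, match="resample"):
            sf.build_surface_mesh(v)

    def test_odd_resolution_rejected(self, straight_tube):
        with pytest.raises(ValueError, match="even"):
            sf.build_surface_mesh(straight_tube, n_circumferential=31)


class TestVolumeMesh:
    def test_volume_matches_frustum_closed_form(self, stenosed_vessel):
        mesh = sf.build_volume_mesh(stenosed_vessel, axial_step=1.0)
        assert mesh.total_volume() == pytest.approx(
            frustum_volume(sf.resample_vessel(stenosed_vessel, 1.0)), rel=0.02
        )

    def test_all_tets_positive_and_boundary_closed(self, small_volume_mesh):
        mesh = small_volume_mesh
        assert mesh.cell_volumes().min() > 0
        # boundary faces close the surface: every tet face is shared by two
        # tets or is a boundary face
        assert {WALL, INLET, OUTLET} == set(np.unique(mesh.boundary_labels))

    def test_boundary_vertices_on_analytic_cylinder(self):
        v = sf.make_synthetic_vessel(10.0, 1.5, [], step=1.0)
        mesh = sf.build_volume_mesh(v, n_circumferential=16, target_edge=0.4)
        wall_faces = mesh.boundary_faces[mesh.boundary_labels == WALL]
        pts = mesh.vertices[np.unique(wall_faces)]
        radial = np.linalg.norm(pts[:, :2], axis=1)
        first_layer = 0.05 * 1.5
        assert np.abs(radial - 1.5).max() < first_layer / 2

    def test_zero_inflation_layers_valid(self):
        v = sf.make_synthetic_vessel(8.0, 1.5, [], step=1.0)
        mesh = sf.build_volume_mesh(v, n_circumferential=12, n_layers=0)
        assert mesh.cell_volumes().min() > 0
        assert np.all(mesh.vertex_layer == 0)

    def test_inflation_layer_tags_present(self, small_volume_mesh):
        layers = set(np.unique(small_volume_mesh.vertex_layer))
        assert layers == {0, 1, 2}

    def test_volume_convergence_second_order_in_axial_step(self):
        """Axial discretization error vs the exact profile volume ~ O(h^2)."""
        v_exact, _ = quad(
            lambda s: np.pi
            * (1.5 * (1.0 - 0.5 * sf.StenosisSpec(25.0, 20.0, 0.5).bump(np.array([s]))[0]))
            ** 2,
            0.0, 50.0, limit=200,
        )
        nc = 16
        polygon_ratio = nc / (2 * np.pi) * np.sin(2 * np.pi / nc)
        errs = []
        for step in (4.0, 2.0, 1.0):
            vessel = sf.make_synthetic_vessel(
                50.0, 1.5, [sf.StenosisSpec(25.0, 20.0, 0.5)], step=step
            )
            mesh = sf.build_volume_mesh(vessel, n_circumferential=nc, n_layers=0)
            errs.append(abs(mesh.total_volume() / polygon_ratio - v_exact))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] > 2.5  # ~4 for a clean second-order scheme
        assert errs[1] / errs[2] > 2.5


class TestCrossSectionFitting:
    def test_straight_tube_roundtrip_radius(self):
        v = sf.make_synthetic_vessel(30.0, 1.5, [], step=1.0)
        surf = sf.build_surface_mesh(v, caps=False)
        fitted = sf.fit_cross_sections(surf, step=1.0)
        np.testing.assert_allclose(fitted.radii, 1.5, rtol=0.01)
        assert fitted.length == pytest.approx(30.0, abs=1.5)

    def test_elliptical_sections_give_equivalent_area_radius(self):
        v = sf.make_synthetic_vessel(20.0, 1.0, [], step=1.0)
        surf = sf.build_surface_mesh(v, caps=False)
        verts = surf.vertices.copy()
        verts[:, 0] *= 1.6  # semi-axes a = 1.6, b = 1.0
        stretched = sf.SurfaceMesh(
            verts, surf.triangles, surf.strip_of_triangle,
            surf.n_stations, surf.capped,
        )
        fitted = sf.fit_cross_sections(stretched, step=1.0)
        np.testing.assert_allclose(fitted.radii, np.sqrt(1.6 * 1.0), rtol=0.02)

    def test_capped_surface_rejected(self, straight_tube):
        surf = sf.build_surface_mesh(straight_tube, caps=True)
        with pytest.raises(MeshingError, match="boundary loops"):
            sf.fit_cross_sections(surf)

    def test_extra_boundary_loop_rejected(self):
        v = sf.make_synthetic_vessel(30.0, 1.5, [], step=1.0)
        surf = sf.build_surface_mesh(v, caps=False)
        keep = np.ones(len(surf.triangles), dtype=bool)
        nc = 64
        keep[[2 * nc * 3 + 16, 2 * nc * 3 + nc + 16]] = False  # one quad hole
        holed = sf.SurfaceMesh(
            surf.vertices, surf.triangles[keep], surf.strip_of_triangle[keep],
            surf.n_stations, False,
        )
        with pytest.raises(MeshingError, match="boundary loops"):
            sf.fit_cross_sections(holed)


VRML_CUBE = """#VRML V2.0 utf8
Shape {
  geometry IndexedFaceSet {
    coord Coordinate {
      point [ 0 0 0, 1 0 0, 1 1 0, 0 1 0, 0 0 1, 1 0 1, 1 1 1, 0 1 1 ]
    }
    coordIndex [
      0, 3, 2, 1, -1,  4, 5, 6, 7, -1,  0, 1, 5, 4, -1,
      2, 3, 7, 6, -1,  1, 2, 6, 5, -1,  0, 4, 7, 3, -1
    ]
  }
}
"""


class TestVrml:
    def test_hand_written_cube(self, tmp_path):
        path = tmp_path / "cube.wrl"
        path.write_text(VRML_CUBE)
        surf = read_vrml_surface(path)
        assert len(surf.vertices) == 8
        assert len(surf.triangles) == 12  # 6 quads fanned into 2 each

    def test_cylinder_export_import_roundtrip_counts(self, tmp_path):
        v = sf.make_synthetic_vessel(10.0, 1.5, [], step=1.0)
        surf = sf.build_surface_mesh(v, n_circumferential=16, caps=False)
        path = tmp_path / "tube.wrl"
        write_vrml_surface(surf, path)
        back = read_vrml_surface(path)
        assert len(back.vertices) == len(surf.vertices)
        assert len(back.triangles) == len(surf.triangles)
        np.testing.assert_allclose(back.vertices, surf.vertices, atol=1e-6)

    def test_quad_strip_triangle_count(self, tmp_path):
        # 3x3 grid of quads -> 9 quads -> 18 triangles
        pts = [f"{x} {y} 0" for y in range(4) for x in range(4)]
        faces = []
        for j in range(3):
            for i in range(3):
                a = 4 * j + i
                faces.append(f"{a}, {a + 1}, {a + 5}, {a + 4}, -1")
        text = (
            "#VRML V2.0 utf8\nShape { geometry IndexedFaceSet {\n"
            "coord Coordinate { point [" + ", ".join(pts) + "] }\n"
            "coordIndex [" + " ".join(faces) + "]\n} }\n"
        )
        path = tmp_path / "grid.wrl"
        path.write_text(text)
        surf = read_vrml_surface(path)
        assert len(surf.triangles) == 18

    def test_top_level_transform_applied(self, tmp_path):
        text = VRML_CUBE.replace(
            "Shape {",
            "Transform { translation 10 0 0 scale 2 2 2 children [ Shape {",
        ) + "] }\n"
        path = tmp_path / "moved.wrl"
        path.write_text(text)
        surf = read_vrml_surface(path)
        assert surf.vertices[:, 0].min() == pytest.approx(10.0)
        assert surf.vertices[:, 0].max() == pytest.approx(12.0)

    def test_no_indexed_face_set_rejected(self, tmp_path):
        path = tmp_path / "empty.wrl"
        path.write_text("#VRML V2.0 utf8\nShape { geometry Sphere { radius 1 } }\n")
        with pytest.raises(VrmlError, match="IndexedFaceSet"):
            read_vrml_surface(path)


class TestExportImport:
    @pytest.fixture()
    def surf(self):
        v = sf.make_synthetic_vessel(8.0, 1.5, [], step=1.0)
        return sf.build_surface_mesh(v, n_circumferential=16)

    @pytest.fixture()
    def volmesh(self):
        v = sf.make_synthetic_vessel(8.0, 1.5, [], step=1.0)
        return sf.build_volume_mesh(v, n_circumferential=12, n_layers=0)

    @pytest.mark.parametrize("fmt", ["stl", "stl_ascii"])
    def test_stl_roundtrip_triangle_count(self, surf, tmp_path, fmt):
        path = tmp_path / "s.stl"
        export_mesh(surf, path, fmt)
        back = read_stl_surface(path)
        assert len(back.faces) == len(surf.triangles)

    def test_ascii_stl_facet_grammar(self, tmp_path):
        one = sf.SurfaceMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            np.array([[0, 1, 2]]), np.array([0]), 2, False,
        )
        path = tmp_path / "tri.stl"
        export_mesh(one, path, "stl_ascii")
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        facet = lines[1:8]  # the 7-line facet block
        assert facet[0].startswith("facet normal")
        assert facet[1] == "outer loop"
        assert all(v.startswith("vertex") for v in facet[2:5])
        assert facet[5] == "endloop"
        assert facet[6] == "endfacet"

    def test_vtk_surface_roundtrip(self, surf, tmp_path):
        path = tmp_path / "s.vtk"
        export_mesh(surf, path, "vtk")
        pts, cells = read_vtk_mesh(path)
        assert len(pts) == len(surf.vertices)
        assert len(cells) == len(surf.triangles)

    def test_vtk_and_vtu_volume_roundtrip(self, volmesh, tmp_path):
        for fmt, reader in (("vtk", read_vtk_mesh), ("vtu", read_vtu_mesh)):
            path = tmp_path / f"v.{fmt}"
            export_mesh(volmesh, path, fmt)
            pts, cells = reader(path)
            assert len(pts) == len(volmesh.vertices)
            assert len(cells) == volmesh.n_cells
            np.testing.assert_allclose(pts, volmesh.vertices, atol=1e-8)

    def test_unknown_format_rejected(self, surf, tmp_path):
        with pytest.raises(ValueError, match="unknown mesh format"):
            export_mesh(surf, tmp_path / "x.ply", "ply")

    def test_mismatched_kind_rejected(self, surf, volmesh, tmp_path):
        with pytest.raises(ValueError, match="volume"):
            export_mesh(surf, tmp_path / "s.vtu", "vtu")
        with pytest.raises(ValueError, match="surface"):
            export_mesh(volmesh, tmp_path / "v.stl", "stl")
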