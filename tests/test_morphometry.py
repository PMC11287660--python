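"""Morphometry oracles: analytic solids, an independent mesh library,
rotation/scaling invariances, and watertightness QC."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

import planktomesh as pm
from planktomesh.morphometry import NotWatertightError

from conftest import rotation_matrix, unit_cube


def as_trimesh(mesh: pm.TriangleMesh) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)


def fixture_meshes():
    yield "cube", unit_cube()
    yield "icosphere", pm.make_icosphere(5.0, 3)
    yield "capsule", pm.make_revolution(pm.capsule(2.0, 10.0), n_theta=64, n_z=48)
    yield "spheroid", pm.make_revolution(pm.prolate_spheroid(1.97, 8.135),
                                         n_theta=64, n_z=48)
    yield "drop", pm.make_preset_mesh("p-micans-like", n_theta=64, n_z=64)
    yield "jittered", pm.jitter_mesh(pm.make_icosphere(5.0, 3), 0.01, seed=42)


class TestSurfaceAreaAndVolume:
    def test_unit_cube_analytic(self, cube):
        assert pm.surface_area(cube) == pytest.approx(6.0, abs=1e-12)
        assert pm.biovolume(cube) == pytest.approx(1.0, abs=1e-12)

    def test_single_triangle_area(self):
        tri = pm.TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                              np.array([[0, 1, 2]]))
        assert pm.surface_area(tri) == pytest.approx(0.5, abs=1e-15)

    def test_icosphere_converges_to_analytic_sphere(self, icosphere_r5):
        assert pm.surface_area(icosphere_r5) == pytest.approx(4 * math.pi * 25, rel=0.002)
        assert pm.biovolume(icosphere_r5) == pytest.approx(4 / 3 * math.pi * 125, rel=0.003)

    def test_capsule_mesh_matches_closed_form(self):
        shape = pm.capsule(2.0, 10.0)
        mesh = pm.make_revolution(shape, n_theta=256, n_z=128)
        assert pm.biovolume(mesh) == pytest.approx(pm.shape_volume(shape), rel=0.005)
        assert pm.surface_area(mesh) == pytest.approx(pm.shape_surface_area(shape), rel=0.005)

    def test_volume_is_translation_invariant(self, cube):
        moved = pm.TriangleMesh(cube.vertices + 1000.0, cube.faces)
        assert pm.biovolume(moved) == pytest.approx(1.0, rel=1e-9)

    def test_globally_inverted_mesh_still_gives_positive_volume(self, cube):
        flipped = pm.TriangleMesh(cube.vertices, cube.faces[:, ::-1])
        assert pm.biovolume(flipped) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("name,mesh", list(fixture_meshes()))
    def test_agrees_with_independent_mesh_library(self, name, mesh):
        tm = as_trimesh(mesh)
        assert pm.surface_area(mesh) == pytest.approx(tm.area, rel=1e-9)
        assert pm.biovolume(mesh) == pytest.approx(abs(tm.volume), rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(s=st.floats(min_value=0.01, max_value=100.0,
                       allow_nan=False, allow_infinity=False))
    def test_scaling_law(self, s):
        """Scaling coordinates by s multiplies SA by s² and V by s³."""
        mesh = pm.make_icosphere(2.0, 1)
        scaled = mesh.scaled(s)
        assert pm.surface_area(scaled) == pytest.approx(s ** 2 * pm.surface_area(mesh), rel=1e-12)
        assert pm.biovolume(scaled) == pytest.approx(s ** 3 * pm.biovolume(mesh), rel=1e-12)


class TestEquivalentDiameters:
    @pytest.mark.parametrize("sa,vol,d_esa,d_esv", [
        (2341.26, 8714.20, 27.30, 25.53),  # large pyriform dinoflagellate
        (172.59, 137.96, 7.41, 6.41),  # small elongated diatom
    ])
    def test_published_morphometry_reproduced_to_2dp(self, sa, vol, d_esa, d_esv):
        got_esa, got_esv = pm.equivalent_diameters(sa, vol)
        assert round(got_esa, 2) == d_esa
        assert round(got_esv, 2) == d_esv

    def test_sphere_self_consistency(self):
        d_esa, d_esv = pm.equivalent_diameters(100 * math.pi, 500 / 3 * math.pi)
        assert d_esa == pytest.approx(10.0, rel=1e-12)
        assert d_esv == pytest.approx(10.0, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pm.equivalent_diameters(0.0, 1.0)
        with pytest.raises(ValueError):
            pm.equivalent_diameters(1.0, -1.0)

    @pytest.mark.parametrize("name,mesh", list(fixture_meshes()))
    def test_isoperimetric_inequality_on_every_watertight_fixture(self, name, mesh):
        d_esa, d_esv = pm.equivalent_diameters(pm.surface_area(mesh), pm.biovolume(mesh))
        assert d_esa >= d_esv

    def test_equality_approached_by_refined_icospheres(self):
        gaps = []
        for sub in (1, 2, 3, 4):
            s = pm.make_icosphere(5.0, sub)
            d_esa, d_esv = pm.equivalent_diameters(pm.surface_area(s), pm.biovolume(s))
            gaps.append(d_esa - d_esv)
        assert all(g > 0 for g in gaps)
        assert gaps == sorted(gaps, reverse=True)


class TestPrincipalExtents:
    def box(self, lx, ly, lz):
        cube = unit_cube()
        return pm.TriangleMesh(cube.vertices * [lx, ly, lz], cube.faces)

    def test_axis_aligned_box_extents_sorted_descending(self):
        # elongated diatom-like box: length/width/depth 16.27 x 3.94 x 3.24 μm
        mesh = self.box(3.94, 16.27, 3.24)
        l, w, d = pm.principal_extents(mesh)
        assert (l, w, d) == pytest.approx((16.27, 3.94, 3.24), abs=1e-9)

    def test_rotation_invariance(self):
        mesh = self.box(16.27, 3.94, 3.24)
        r = rotation_matrix([0, 0, 1], math.pi / 6)
        rotated = pm.TriangleMesh(mesh.vertices @ r.T, mesh.faces)
        assert pm.principal_extents(rotated) == pytest.approx(
            pm.principal_extents(mesh), abs=1e-6)

    def test_sphere_extents_approach_diameter(self, icosphere_r5):
        l, w, d = pm.principal_extents(icosphere_r5)
        assert (l, w, d) == pytest.approx((10, 10, 10), rel=0.01)
        assert l >= w >= d

    def test_flat_cloud_rejected(self):
        flat = pm.TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float),
            np.array([[0, 1, 2], [1, 3, 2]]))
        with pytest.raises(ValueError, match="degenerate"):
            pm.principal_extents(flat)

    def test_aabb_extents_use_as_posed_frame(self):
        mesh = self.box(3.94, 16.27, 3.24)
        assert pm.axis_aligned_extents(mesh) == pytest.approx((16.27, 3.94, 3.24))


class TestWatertightQC:
    def test_closed_cube(self, cube):
        assert pm.check_watertight(cube) == (True, True, 0)

    def test_cube_with_removed_facet_has_3_boundary_edges(self, cube):
        open_mesh = pm.TriangleMesh(cube.vertices, cube.faces[1:])
        watertight, oriented, boundary = pm.check_watertight(open_mesh)
        assert not watertight
        assert oriented
        assert boundary == 3

    def test_cube_with_flipped_facet_is_closed_but_misoriented(self, cube):
        faces = cube.faces.copy()
        faces[0] = faces[0, ::-1]
        mesh = pm.TriangleMesh(cube.vertices, faces)
        watertight, oriented, boundary = pm.check_watertight(mesh)
        assert watertight
        assert not oriented
        assert boundary == 0

    def test_volume_of_open_mesh_raises_with_boundary_count(self, cube):
        open_mesh = pm.TriangleMesh(cube.vertices, cube.faces[1:])
        with pytest.raises(NotWatertightError, match="3 boundary"):
            pm.biovolume(open_mesh)

    def test_misoriented_volume_requires_explicit_repair(self, cube):
        faces = cube.faces.copy()
        faces[0] = faces[0, ::-1]
        mesh = pm.TriangleMesh(cube.vertices, faces)
        with pytest.raises(NotWatertightError, match="winding"):
            pm.biovolume(mesh)
        assert pm.biovolume(mesh, auto_fix_orientation=True) == pytest.approx(1.0, abs=1e-12)

    def test_fix_orientation_restores_consistency(self, cube):
        rng = np.random.default_rng(7)
        faces = cube.faces.copy()
        flip = rng.random(12) < 0.5
        faces[flip] = faces[flip][:, ::-1]
        repaired = pm.fix_orientation(pm.TriangleMesh(cube.vertices, faces))
        assert pm.check_watertight(repaired) == (True, True, 0)


class TestMeasureReport:
    def test_full_report_on_cube(self, cube):
        report = pm.measure(cube)
        assert report.surface_area == pytest.approx(6.0)
        assert report.biovolume == pytest.approx(1.0)
        assert report.sa_to_v == pytest.approx(6.0)
        assert report.watertight and report.consistently_oriented
        assert report.d_esa >= report.d_esv
        assert report.length >= report.width >= report.depth > 0
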