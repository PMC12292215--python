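"""Geometry: implicit fields, shell membership, voxel descriptors, meshes."""

import numpy as np
import pytest
import trimesh

from tpmslat import geometry as g

SMALL = dict(cell_size_x=3.0, cell_size_y=3.0, cell_size_z=3.0,
             thickness=0.4, rotation_deg=0.0, height=4.0, diameter=4.0)


def small_design(**overrides):
    params = {**SMALL, **overrides}
    return g.LatticeDesign(surface_type=params.pop("surface_type", "gyroid"),
                           **params)


class TestImplicitField:
    @pytest.mark.parametrize("surface", ["gyroid", "diamond"])
    def test_zero_at_origin(self, surface):
        # every term of both expressions carries a sine of zero
        assert g.implicit_field(surface, [0.0, 0.0, 0.0], [3, 4, 5]) == 0.0

    def test_unknown_surface_rejected(self):
        with pytest.raises(g.UnsupportedSurfaceError):
            g.implicit_field("primitive", [0, 0, 0], [3, 3, 3])

    @pytest.mark.parametrize("surface", g.SURFACE_TYPES)
    def test_periodicity(self, surface, rng):
        cells = np.array([3.0, 4.0, 2.5])
        pts = rng.uniform(-10, 10, size=(50, 3))
        base = g.implicit_field(surface, pts, cells)
        for axis in range(3):
            shift = np.zeros(3)
            shift[axis] = cells[axis]
            shifted = g.implicit_field(surface, pts + shift, cells)
            np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_rotation_matches_rotated_points(self, rng):
        # evaluating with a rotation equals evaluating rotated coordinates
        pts = rng.uniform(-5, 5, size=(20, 3))
        theta = np.deg2rad(30.0)
        c, s = np.cos(theta), np.sin(theta)
        rotated = pts.copy()
        rotated[:, 1] = c * pts[:, 1] - s * pts[:, 2]
        rotated[:, 2] = s * pts[:, 1] + c * pts[:, 2]
        a = g.implicit_field("gyroid", pts, [3, 3, 3], rotation_deg=30.0)
        b = g.implicit_field("gyroid", rotated, [3, 3, 3])
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestDesignValidation:
    def test_thickness_must_fit_cells(self):
        with pytest.raises(ValueError, match="thickness"):
            small_design(thickness=3.5)

    def test_full_solid_override_allows_degenerate(self):
        d = small_design(thickness=3.5, full_solid=True)
        assert d.full_solid

    def test_rotation_range(self):
        with pytest.raises(ValueError, match="rotation"):
            small_design(rotation_deg=90.0)


class TestShellMembership:
    def test_outside_envelope_false(self):
        d = small_design()
        r = d.diameter / 2
        assert not g.signed_thickness_test(d, [r + 0.1, r + 0.1, 1.0])

    def test_on_level_set_true(self):
        # the origin lies on the gyroid level set and on the envelope boundary
        d = small_design()
        assert g.signed_thickness_test(d, [0.0, 0.0, 0.0])

    def test_membership_fraction_matches_rd(self):
        # fraction of solid voxel centers among in-envelope centers is the
        # same quantity compute_descriptors reports as RD
        d = small_design()
        desc = g.compute_descriptors(d, spacing=0.1)
        grid = g.voxelize(d, spacing=0.1)
        ax = [grid.origin[i] + (np.arange(grid.shape[i]) + 0.5) * grid.spacing
              for i in range(3)]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        in_env = g.envelope_distance(d, pts) <= 0
        frac = grid.occupancy.ravel()[in_env].mean()
        assert frac * 100 == pytest.approx(desc.relative_density, rel=1e-12)


class TestVoxelize:
    def test_spacing_above_half_thickness_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            g.voxelize(small_design(), spacing=0.25)

    def test_coarse_spacing_warns(self):
        with pytest.warns(UserWarning, match="thickness/4"):
            g.voxelize(small_design(), spacing=0.15)

    def test_memory_budget(self):
        d = small_design(height=20.0, diameter=20.0)
        with pytest.raises(g.ResolutionError, match="spacing"):
            g.voxelize(d, spacing=0.004)

    def test_occupancy_volume_identity(self):
        d = small_design()
        grid = g.voxelize(d, spacing=0.1)
        desc = g.compute_descriptors(d, spacing=0.1)
        envelope = np.pi * (d.diameter / 2) ** 2 * d.height
        assert grid.solid_volume == pytest.approx(
            envelope * desc.relative_density / 100, rel=0.05)


class TestSurfaceOracles:
    def test_sphere_area_closed_form(self):
        r = 1.0
        mesh = g.mesh_from_field(
            lambda p: np.linalg.norm(p, axis=-1) - r,
            ((-1.2, -1.2, -1.2), (1.2, 1.2, 1.2)), spacing=r / 50)
        assert mesh.area == pytest.approx(4 * np.pi * r**2, rel=0.02)

    def test_box_area_closed_form(self):
        mesh = g.mesh_from_field(
            lambda p: np.max(np.abs(p) - 0.5, axis=-1),
            ((-0.8, -0.8, -0.8), (0.8, 0.8, 0.8)), spacing=0.02)
        assert mesh.area == pytest.approx(6.0, rel=0.02)

    def test_empty_field_raises(self):
        with pytest.raises(g.EmptyMeshError):
            g.mesh_from_field(lambda p: np.ones(len(np.atleast_2d(p))),
                              ((0, 0, 0), (1, 1, 1)), spacing=0.1)


class TestDescriptors:
    def test_full_solid_rd_100(self):
        d = small_design(thickness=3.5, full_solid=True)
        desc = g.compute_descriptors(d, spacing=0.1)
        assert desc.relative_density == 100.0
        assert desc.porosity == 0.0

    def test_rd_porosity_complement_exact(self):
        desc = g.compute_descriptors(small_design(), spacing=0.1)
        assert desc.relative_density + desc.porosity == 100.0

    @pytest.mark.filterwarnings("ignore:spacing")
    def test_rd_monotone_in_thickness(self):
        rds = [g.compute_descriptors(small_design(thickness=t), 0.1
                                     ).relative_density
               for t in (0.2, 0.3, 0.4)]
        assert rds[0] < rds[1] < rds[2]

    def test_rd_convergence_under_halving(self):
        d = small_design()
        coarse = g.compute_descriptors(d, spacing=0.1).relative_density
        fine = g.compute_descriptors(d, spacing=0.05).relative_density
        assert abs(coarse - fine) / fine < 0.01


class TestStlExport:
    def _triangle(self):
        return trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                               faces=[[0, 1, 2]], process=False)

    def test_single_triangle_byte_count(self, tmp_path):
        path = tmp_path / "tri.stl"
        g.export_stl(self._triangle(), path)
        # binary STL: 80-byte header + 4-byte count + 50 bytes per triangle
        assert path.stat().st_size == 84 + 50

    def test_round_trip_triangle_count_and_area(self, tmp_path):
        d = small_design()
        mesh = g.extract_surface(d, spacing=0.1)
        path = tmp_path / "lattice.stl"
        g.export_stl(mesh, path)
        back = trimesh.load(path)
        assert len(back.faces) == len(mesh.faces)
        assert back.area == pytest.approx(mesh.area, rel=1e-6)

    def test_round_trip_vertices_within_float_tolerance(self, tmp_path):
        path = tmp_path / "tri.stl"
        tri = self._triangle()
        g.export_stl(tri, path)
        back = trimesh.load(path, process=False)
        np.testing.assert_allclose(np.sort(back.vertices, axis=0),
                                   np.sort(tri.vertices, axis=0), atol=1e-6)

    def test_empty_mesh_refused(self, tmp_path):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                faces=np.zeros((0, 3), dtype=int),
                                process=False)
        with pytest.raises(g.EmptyMeshError):
            g.export_stl(empty, tmp_path / "no.stl")
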