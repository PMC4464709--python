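import numpy as np
import pytest
import trimesh

from atriarecon.geometry import ImagePlane
from atriarecon.phantoms import SliceStrategy, generate_strategy, make_phantom
from atriarecon.reconstruct import (
    IndicatorGrid,
    ReconstructionConfig,
    ReconstructionError,
    TriangleMesh,
    build_plane_field,
    evaluate_grid,
    extract_zero_surface,
    interpolate_indicator,
    mesh_volume,
    reconstruct_cine,
    reconstruct_frame,
)
from tests.conftest import circle_contour


def make_plane(origin, u=(1, 0, 0), v=(0, 1, 0), spacing=(1.0, 1.0), plane_id="P"):
    return ImagePlane(origin=origin, u_dir=u, v_dir=v, spacing=spacing,
                      n_rows=101, n_cols=101, plane_id=plane_id)


class TestBuildPlaneField:
    def test_binary_inside_outside(self):
        plane = make_plane((0, 0, 0))
        c = circle_contour(10.0, center_rowcol=(50, 50), plane_id="P")
        f = build_plane_field(plane, c, mode="binary")
        assert f.sample(np.array([50.0, 50.0])) == 1.0
        assert f.sample(np.array([65.0, 50.0])) == -1.0

    def test_signed_distance_clamp(self):
        plane = make_plane((0, 0, 0))
        c = circle_contour(10.0, center_rowcol=(50, 50), plane_id="P")
        f = build_plane_field(plane, c, mode="signed_distance", tau_mm=3.0,
                              sample_step=0.5)
        # 1.5 mm inside the wall: clamp(1.5, +/-3)/3 = +0.5
        val = f.sample(np.array([58.5, 50.0]))
        assert val == pytest.approx(0.5, abs=0.05)

    def test_zero_on_contour(self):
        plane = make_plane((0, 0, 0))
        c = circle_contour(10.0, center_rowcol=(50, 50), plane_id="P")
        f = build_plane_field(plane, c, mode="signed_distance", sample_step=0.5)
        on = f.sample(np.array([60.0, 50.0]))
        assert abs(on) < 0.5 / f.tau_mm  # within one sampling step of zero

    def test_sample_step_exceeding_pixel_spacing_rejected(self):
        plane = make_plane((0, 0, 0), spacing=(1.0, 1.0))
        c = circle_contour(10.0, center_rowcol=(50, 50))
        with pytest.raises(ValueError, match="sample_step"):
            build_plane_field(plane, c, sample_step=2.0)


class TestInterpolateIndicator:
    def _parallel_fields(self, value_top):
        # two parallel unit-spacing planes at z=0 and z=10 with constant fields
        out = []
        for z, radius in [(0.0, 30.0), (10.0, 30.0)]:
            plane = make_plane((0, 0, z))
            c = circle_contour(radius, center_rowcol=(50, 50), plane_id=f"z{z}")
            out.append(build_plane_field(plane, c, mode="binary"))
        if value_top == -1:
            out[1].values[:] = -1.0
        return out

    def test_on_plane_reproduces_field(self):
        fields = self._parallel_fields(+1)
        p = np.array([50.0, 50.0, 0.0])  # on the z=0 plane, inside
        assert interpolate_indicator(fields, p) == 1.0

    def test_equal_fields_average_to_same_value(self):
        fields = self._parallel_fields(+1)
        p = np.array([50.0, 50.0, 4.0])
        assert interpolate_indicator(fields, p) == pytest.approx(1.0)

    def test_opposite_fields_cancel_at_midpoint(self):
        fields = self._parallel_fields(-1)
        p = np.array([50.0, 50.0, 5.0])
        assert interpolate_indicator(fields, p) == pytest.approx(0.0, abs=1e-9)

    def test_empty_field_list_rejected(self):
        with pytest.raises(ReconstructionError):
            interpolate_indicator([], np.zeros(3))


class TestEvaluateGrid:
    def test_boundary_forced_outside_and_centroid_inside(self, sphere_dataset):
        planes, cs = sphere_dataset.frame_set(0)
        fields = [build_plane_field(p, c) for p, c in zip(planes, cs)]
        grid = evaluate_grid(fields, spacing=3.0)
        v = grid.values
        assert (v[0] < 0).all() and (v[-1] < 0).all()
        assert (v[:, 0] < 0).all() and (v[:, -1] < 0).all()
        assert (v[:, :, 0] < 0).all() and (v[:, :, -1] < 0).all()
        assert v[tuple(s // 2 for s in v.shape)] > 0

    def test_oversized_spacing_rejected(self, sphere_dataset):
        planes, cs = sphere_dataset.frame_set(0)
        fields = [build_plane_field(p, c) for p, c in zip(planes, cs)]
        with pytest.raises(ReconstructionError):
            evaluate_grid(fields, spacing=500.0)

    def test_on_slice_nodes_reproduce_field_sign(self, sphere_dataset):
        # idw route: grid nodes on a slice plane inherit that plane's sign
        planes, cs = sphere_dataset.frame_set(0)
        fields = [build_plane_field(planes[0], cs[0])]
        plane = planes[0]
        rng = np.random.default_rng(0)
        rows = rng.uniform(5, 95, 300)
        cols = rng.uniform(5, 95, 300)
        pts = plane.pixel_to_patient(rows, cols)
        uv, _ = plane.patient_to_plane_arrays(pts)
        expected = fields[0].sample(uv)
        got = interpolate_indicator(fields, pts)
        far = np.abs(expected) > 1.0 / fields[0].tau_mm
        agree = np.sign(got[far]) == np.sign(expected[far])
        assert agree.mean() >= 0.99


def sphere_sdf_grid(radius=20.0, spacing=1.0, pad=5.0):
    ax = np.arange(-radius - pad, radius + pad + spacing, spacing)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    values = radius - np.sqrt(xx**2 + yy**2 + zz**2)
    return IndicatorGrid(x_axis=ax, y_axis=ax, z_axis=ax, spacing=spacing, values=values)


class TestExtractZeroSurface:
    def test_analytic_sphere_volume(self):
        grid = sphere_sdf_grid(radius=20.0, spacing=1.0)
        mesh = extract_zero_surface(grid)
        vol = mesh_volume(mesh)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 20**3 / 1000.0, rel=0.01)

    def test_single_sign_grid_rejected(self):
        grid = sphere_sdf_grid(radius=20.0, spacing=2.0)
        grid.values = -np.abs(grid.values) - 1.0
        with pytest.raises(ReconstructionError, match="no enclosed region"):
            extract_zero_surface(grid)

    def test_mesh_is_watertight(self):
        mesh = extract_zero_surface(sphere_sdf_grid(radius=15.0, spacing=2.0))
        tm = mesh.to_trimesh()
        assert tm.is_watertight
        # every edge shared by exactly two faces
        assert len(tm.edges_sorted) == 2 * len(tm.edges_unique)


class TestMeshVolume:
    def cube_mesh(self, edge=10.0):
        box = trimesh.creation.box(extents=(edge, edge, edge))
        return TriangleMesh(vertices=np.asarray(box.vertices), faces=np.asarray(box.faces))

    def test_cube_volume_exact(self):
        assert mesh_volume(self.cube_mesh(10.0)) == pytest.approx(1.0, rel=1e-12)

    def test_unit_tetrahedron(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        mesh = TriangleMesh(vertices=verts, faces=faces)
        assert mesh_volume(mesh) == pytest.approx(1.0 / 6.0 / 1000.0, rel=1e-12)

    def test_icosphere_underestimates_analytic(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = TriangleMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces))
        vol = mesh_volume(mesh)
        analytic = 4.0 / 3.0 * np.pi * 1000.0 / 1000.0
        assert analytic * 0.99 < vol < analytic  # inscribed polyhedron

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        mesh = self.cube_mesh(7.0)
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        moved = TriangleMesh(vertices=mesh.vertices @ R.T + np.array([5.0, -3.0, 11.0]),
                             faces=mesh.faces)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(mesh), rel=1e-12)

    def test_agrees_with_independent_implementation(self):
        # cross-check the divergence-theorem sum against trimesh's volume
        ico = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        mesh = TriangleMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces))
        assert mesh_volume(mesh) == pytest.approx(abs(ico.volume) / 1000.0, rel=1e-12)

    def test_non_watertight_rejected(self):
        mesh = self.cube_mesh(5.0)
        broken = TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[:-1])
        with pytest.raises(ReconstructionError):
            mesh_volume(broken)


class TestReconstructFrame:
    def test_sphere_volume_within_two_percent(self, sphere_dataset):
        planes, cs = sphere_dataset.frame_set(0)
        res = reconstruct_frame(planes, cs, ReconstructionConfig(grid_mm=1.5))
        assert abs(res.volume_ml - 55.0) / 55.0 < 0.02

    def test_orientation_invariance_sphere(self, sphere_phantom, sphere_dataset):
        config = ReconstructionConfig(grid_mm=2.0)
        ds3 = generate_strategy(sphere_phantom, SliceStrategy("D3"))
        v1 = reconstruct_frame(*sphere_dataset.frame_set(0), config).volume_ml
        v3 = reconstruct_frame(*ds3.frame_set(0), config).volume_ml
        assert abs(v1 - v3) / 55.0 < 0.01

    def test_single_plane_rejected(self, sphere_dataset):
        planes, cs = sphere_dataset.frame_set(0)
        with pytest.raises(ReconstructionError):
            reconstruct_frame(planes[:1], cs[:1])

    def test_mixed_frames_rejected(self, sphere_dataset):
        import dataclasses

        planes, cs = sphere_dataset.frame_set(0)
        bad = [cs[0]] + [dataclasses.replace(c, frame=1) for c in cs[1:]]
        with pytest.raises(ReconstructionError, match="frames"):
            reconstruct_frame(planes, bad)

    def test_deterministic(self, sphere_dataset):
        config = ReconstructionConfig(grid_mm=2.5)
        planes, cs = sphere_dataset.frame_set(0)
        v1 = reconstruct_frame(planes, cs, config).volume_ml
        v2 = reconstruct_frame(planes, cs, config).volume_ml
        assert v1 == v2

    def test_binary_idw_mode_runs(self, sphere_dataset):
        # the literal +/-1 carrier stays available; its projection blend
        # carries a known convexity bias, so only coarse agreement is asserted
        planes, cs = sphere_dataset.frame_set(0)
        res = reconstruct_frame(
            planes, cs, ReconstructionConfig(grid_mm=2.0, mode="binary")
        )
        assert res.mesh.is_watertight
        assert 0.7 * 55.0 < res.volume_ml < 1.3 * 55.0

    def test_rigid_invariance_of_reconstruction(self, sphere_phantom):
        from scipy.spatial.transform import Rotation

        config = ReconstructionConfig(grid_mm=2.0)
        base = generate_strategy(sphere_phantom, SliceStrategy("D1"))
        v0 = reconstruct_frame(*base.frame_set(0), config).volume_ml
        R = Rotation.from_euler("zyx", [33, 18, -41], degrees=True).as_matrix()
        moved = generate_strategy(
            sphere_phantom.transformed(R, (25.0, -40.0, 60.0)), SliceStrategy("D1")
        )
        v1 = reconstruct_frame(*moved.frame_set(0), config).volume_ml
        assert abs(v1 - v0) / 55.0 < 0.005

    def test_grid_refinement_convergence(self, sphere_dataset):
        # volume error decreases monotonically (0.2% slack) as the grid halves
        planes, cs = sphere_dataset.frame_set(0)
        errs = []
        for h in (4.0, 2.0, 1.0):
            v = reconstruct_frame(planes, cs, ReconstructionConfig(grid_mm=h)).volume_ml
            errs.append(abs(v - 55.0) / 55.0)
        assert errs[1] <= errs[0] + 0.002
        assert errs[2] <= errs[1] + 0.002


class TestReconstructCine:
    def _tiny_cine(self, n_frames=8):
        from atriarecon.phantoms import generate_cine_phantom

        ph = make_phantom("sphere", 55.0)
        return generate_cine_phantom(
            ph, v_max=60.0, v_min=50.0, v_pre_a=55.0, n_frames=n_frames, dt_ms=30.0
        )

    def test_constant_phantom_gives_flat_curve(self, sphere_phantom):
        from atriarecon.phantoms import slice_phantom, strategy_planes
        import dataclasses

        planes, _ = strategy_planes(sphere_phantom, SliceStrategy("D1"))
        contours = []
        for f in range(3):
            for pid, plane in planes.items():
                c = slice_phantom(sphere_phantom, plane)
                contours.append(dataclasses.replace(c, plane_id=pid, frame=f))
        curve = reconstruct_cine(planes, contours, ReconstructionConfig(grid_mm=2.5))
        v = curve.volumes_ml
        assert (v.max() - v.min()) / v.mean() < 0.01

    def test_missing_contours_flagged_not_interpolated(self, sphere_phantom):
        ds = self._tiny_cine()
        # drop one plane of frame 3
        contours = [c for c in ds.contours if not (c.frame == 3 and c.plane_id == "SAX2")]
        curve = reconstruct_cine(
            ds.planes, contours, ReconstructionConfig(grid_mm=3.0), dt_ms=30.0
        )
        assert curve.metadata["missing_frames"] == {3: ["SAX2"]}
        assert len(curve) == 7

    def test_empty_rejected(self, sphere_dataset):
        with pytest.raises(ReconstructionError):
            reconstruct_cine(sphere_dataset.planes, [])
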