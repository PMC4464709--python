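import numpy as np
import pytest

from atriarecon.contours import polygon_area
from atriarecon.geometry import ImagePlane, frame_from_normal
from atriarecon.phantoms import (
    STANDARD_PHANTOMS,
    PhantomError,
    SliceStrategy,
    generate_cine_phantom,
    generate_strategy,
    make_phantom,
    prescribe_curve,
    slice_phantom,
)


class TestCalibration:
    @pytest.mark.parametrize("shape", list(STANDARD_PHANTOMS))
    def test_analytic_volume_matches_target(self, shape):
        family, target = STANDARD_PHANTOMS[shape]
        ph = make_phantom(family, target)
        assert ph.volume_ml == pytest.approx(target, rel=1e-12)

    def test_sphere_radius_closed_form(self):
        ph = make_phantom("sphere", 55.0)
        assert ph.semi_axes[0] == pytest.approx((3 * 55000 / (4 * np.pi)) ** (1 / 3), rel=1e-12)
        assert ph.semi_axes[0] == pytest.approx(23.59, abs=0.005)

    @pytest.mark.parametrize("family,target", [("oblique_oval", 61.0), ("curved", 70.0)])
    def test_voxelisation_oracle_confirms_deformed_families(self, family, target):
        # shear has unit determinant and the bend maps each cross-section
        # slab to an equal-volume wedge; the brute-force voxel count must
        # agree with the closed-form calibration
        ph = make_phantom(family, target)
        assert ph.voxelized_volume_ml(step_mm=0.5) == pytest.approx(target, rel=0.002)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(PhantomError):
            make_phantom("sphere", -1.0)
        with pytest.raises(PhantomError):
            make_phantom("curved", 70.0, bend_radius_mm=5.0)


class TestSlicePhantom:
    def make_plane(self, z, size=120.0, spacing=1.0):
        n = int(size / spacing) + 1
        return ImagePlane(origin=(-size / 2, -size / 2, z), u_dir=(1, 0, 0),
                          v_dir=(0, 1, 0), spacing=(spacing, spacing),
                          n_rows=n, n_cols=n, plane_id=f"z{z}")

    def test_central_section_radius(self, sphere_phantom):
        R = sphere_phantom.semi_axes[0]
        c = slice_phantom(sphere_phantom, self.make_plane(0.0), sample_step=0.5)
        area = polygon_area(c, (1.0, 1.0))
        assert area == pytest.approx(np.pi * R**2, rel=0.005)

    def test_offset_section_radius(self, sphere_phantom):
        R = sphere_phantom.semi_axes[0]
        c = slice_phantom(sphere_phantom, self.make_plane(10.0), sample_step=0.5)
        r_expect = np.sqrt(R**2 - 100.0)
        assert polygon_area(c, (1.0, 1.0)) == pytest.approx(np.pi * r_expect**2, rel=0.005)

    def test_plane_missing_shape_returns_none(self, sphere_phantom):
        assert slice_phantom(sphere_phantom, self.make_plane(30.0)) is None

    def test_section_area_quadratic_convergence(self, sphere_phantom):
        R = sphere_phantom.semi_axes[0]
        exact = np.pi * R**2
        errs = []
        for step in (2.0, 1.0, 0.5):
            c = slice_phantom(sphere_phantom, self.make_plane(0.0), sample_step=step)
            errs.append(abs(polygon_area(c, (1.0, 1.0)) - exact))
        # O(step^2): each halving should cut the error by roughly 4
        assert errs[1] < errs[0] / 2.0
        assert errs[2] < errs[1] / 2.0


class TestStrategies:
    def test_row_flags(self):
        assert SliceStrategy("A1").long_axis_aligned
        assert SliceStrategy("A1").short_axis_perpendicular
        assert SliceStrategy("B2").long_axis_aligned
        assert not SliceStrategy("B2").short_axis_perpendicular
        assert not SliceStrategy("C3").long_axis_aligned
        assert SliceStrategy("C3").short_axis_perpendicular
        with pytest.raises(PhantomError):
            SliceStrategy("A4").row

    def test_five_planes_two_lax_three_sax(self, sphere_dataset):
        assert set(sphere_dataset.planes) == {"LAX1", "LAX2", "SAX1", "SAX2", "SAX3"}
        assert len(sphere_dataset.contours) == 5

    def test_lax_planes_are_orthogonal_and_contain_axis(self, sphere_dataset):
        p1 = sphere_dataset.planes["LAX1"]
        p2 = sphere_dataset.planes["LAX2"]
        assert abs(np.dot(p1.normal, p2.normal)) < 1e-9
        axis = np.array(sphere_dataset.metadata["acquired_axis"])
        assert abs(np.dot(p1.normal, axis)) < 1e-9
        assert abs(np.dot(p2.normal, axis)) < 1e-9

    def test_misaligned_axis_angle(self, sphere_phantom):
        ds1 = generate_strategy(sphere_phantom, SliceStrategy("D1"))
        ds3 = generate_strategy(sphere_phantom, SliceStrategy("D3"))
        a1 = np.array(ds1.metadata["acquired_axis"])
        a3 = np.array(ds3.metadata["acquired_axis"])
        angle = np.degrees(np.arccos(np.clip(np.dot(a1, a3), -1, 1)))
        assert angle == pytest.approx(25.0, abs=1e-6)

    def test_sax_tilt(self, sphere_phantom):
        ds2 = generate_strategy(sphere_phantom, SliceStrategy("D2"))
        axis = np.array(ds2.metadata["acquired_axis"])
        n = ds2.planes["SAX2"].normal
        angle = np.degrees(np.arccos(np.clip(abs(np.dot(axis, n)), -1, 1)))
        assert angle == pytest.approx(20.0, abs=1e-6)

    def test_same_seed_is_bit_identical(self, sphere_phantom):
        a = generate_strategy(sphere_phantom, SliceStrategy("D1"), noise_mm=0.5, seed=7)
        b = generate_strategy(sphere_phantom, SliceStrategy("D1"), noise_mm=0.5, seed=7)
        for ca, cb in zip(a.contours, b.contours):
            assert np.array_equal(ca.points, cb.points)

    def test_noise_is_seed_dependent(self, sphere_phantom):
        a = generate_strategy(sphere_phantom, SliceStrategy("D1"), noise_mm=0.5, seed=7)
        b = generate_strategy(sphere_phantom, SliceStrategy("D1"), noise_mm=0.5, seed=8)
        assert not np.array_equal(a.contours[0].points, b.contours[0].points)

    def test_ground_truth_carries_volume_and_landmarks(self, sphere_dataset):
        gt = sphere_dataset.ground_truth
        assert gt["volume_ml"] == pytest.approx(55.0)
        assert set(gt["mitral_uv"]) == {"LAX1", "LAX2"}


class TestCine:
    def test_prescribed_curve_hits_landmarks(self):
        t, v, marks = prescribe_curve(82.6, 43.6, 64.4, n_frames=34, dt_ms=30.0)
        assert v.max() == pytest.approx(82.6)
        assert v.min() == pytest.approx(43.6)
        assert v[marks["i_pre_a"]] == pytest.approx(64.4)
        assert v[0] == pytest.approx(43.6)
        assert len(t) == 34 and t[1] - t[0] == 30.0

    def test_frame_volumes_scale_exactly(self):
        ph = make_phantom("sphere", 55.0)
        ds = generate_cine_phantom(ph, 60.0, 50.0, 55.0, n_frames=8)
        v = np.array(ds.ground_truth["volumes_ml"])
        s = (v / 55.0) ** (1 / 3)
        for f, sf in enumerate(s):
            assert ph.scaled(sf).volume_ml == pytest.approx(v[f], rel=1e-12)

    def test_ground_truth_indices_match_prescription(self):
        ph = make_phantom("oval", 60.0)
        ds = generate_cine_phantom(ph, 82.6, 43.6, 64.4, n_frames=20)
        gt = ds.ground_truth["indices"]
        assert gt["total_emptying"] == pytest.approx(39.0)
        assert gt["passive_emptying"] == pytest.approx(18.2)
        assert gt["total_ef"] == pytest.approx(100 * 39.0 / 82.6)

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(PhantomError):
            prescribe_curve(60.0, -1.0, 30.0)
        with pytest.raises(PhantomError):
            prescribe_curve(60.0, 50.0, 55.0, n_frames=4)


class TestFrameFromNormalStability:
    def test_long_axis_points_into_shape(self):
        for shape, (family, target) in STANDARD_PHANTOMS.items():
            ph = make_phantom(family, target)
            axis = ph.long_axis
            u, v = frame_from_normal(axis)
            assert np.isclose(np.linalg.norm(axis), 1.0)
            assert abs(np.dot(u, axis)) < 1e-9 and abs(np.dot(v, axis)) < 1e-9
            # mitral point sits on the surface
            assert abs(ph.value(ph.mitral_point)) < 1e-9
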