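"""Shape-descriptor oracles: analytic solids, brute-force hulls, rotations."""

import math

import numpy as np
import pytest

from astrolayer.geometry import CortexGeometry
from astrolayer.morphometry import (
    FEATURE_NAMES,
    AstrocyteObject,
    VoxelVolume,
    convex_hull_metrics,
    extract_objects,
    fit_ellipsoid,
    morphometric_vector,
    orientation_2d,
    relative_orientation,
    shape_metrics,
    substructure_mask,
)

from conftest import digitized_ball, digitized_ellipsoid, rotation_about_z, single_object

# face counting over-reads smooth surfaces by the direction-averaged factor
# mean(|nx|+|ny|+|nz|) = 3/2, so a digitized ball scores sphericity ~= 2/3
FACE_BIAS_SPHERICITY = 2.0 / 3.0


class TestExtractObjects:
    def test_one_object_per_label(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[2:, 2:, 2:] = 2
        objs = extract_objects(VoxelVolume(labels, (1, 1, 1)))
        assert [o.label for o in objs] == [1, 2]
        assert objs[0].n_voxels == 1 and objs[1].n_voxels == 8

    def test_background_only_gives_empty_result(self):
        assert extract_objects(VoxelVolume(np.zeros((3, 3, 3), np.int32), (1, 1, 1))) == []

    def test_cube_volume_is_count_times_voxel_volume(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[1:11, 1:11, 1:11] = 1
        obj = single_object(VoxelVolume(labels, (1, 1, 1)))
        assert shape_metrics(obj)["volume"] == pytest.approx(1000.0)

    def test_min_voxel_floor_drops_specks(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0, 0, 0] = 1
        labels[2, 2:, 2:] = 2
        objs = extract_objects(VoxelVolume(labels, (1, 1, 1)), min_voxels=2)
        assert [o.label for o in objs] == [2]


class TestShapeMetrics:
    def test_single_voxel_closed_form(self):
        obj = AstrocyteObject(1, [[0, 0, 0]], (1.0, 1.0, 1.0))
        m = shape_metrics(obj)
        assert m["volume"] == pytest.approx(1.0)
        assert m["surface_area"] == pytest.approx(6.0)

    def test_anisotropic_voxels_scale_faces(self):
        obj = AstrocyteObject(1, [[0, 0, 0]], (2.0, 3.0, 4.0))
        m = shape_metrics(obj)
        assert m["volume"] == pytest.approx(24.0)
        # faces: 2*(3*4) normal to z + 2*(2*4) normal to y + 2*(2*3) normal to x
        assert m["surface_area"] == pytest.approx(2 * 12 + 2 * 8 + 2 * 6)

    def test_ball_sphericity_within_bias_band(self):
        obj = single_object(digitized_ball(15))
        sph = shape_metrics(obj)["sphericity"]
        assert 0.95 * FACE_BIAS_SPHERICITY <= sph <= 1.05 * FACE_BIAS_SPHERICITY

    def test_rod_less_spherical_than_ball(self):
        rod = AstrocyteObject(1, [[0, 0, x] for x in range(100)], (1.0, 1.0, 1.0))
        ball = single_object(digitized_ball(15))
        assert shape_metrics(rod)["sphericity"] < shape_metrics(ball)["sphericity"]

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            AstrocyteObject(1, np.empty((0, 3)), (1.0, 1.0, 1.0))


class TestConvexHull:
    def test_solid_cuboid_is_its_own_hull(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[1:11, 1:11, 1:11] = 1
        m = convex_hull_metrics(single_object(VoxelVolume(labels, (1, 1, 1))))
        assert m["solidity"] == pytest.approx(1.0)
        assert m["convexity"] == pytest.approx(1.0)

    def test_l_shape_solidity_against_voxelized_hull_oracle(self):
        # two 10-cubes sharing an edge: object = 2000 voxels, hull is larger
        labels = np.zeros((12, 22, 22), np.int32)
        labels[1:11, 1:11, 1:11] = 1
        labels[1:11, 11:21, 11:21] = 1
        obj = single_object(VoxelVolume(labels, (1, 1, 1)))
        m = convex_hull_metrics(obj)
        # oracle: count voxel centers inside the same hull by brute force
        from scipy.spatial import Delaunay

        tri = Delaunay(obj.coords.astype(float))
        zz, yy, xx = np.mgrid[0:12, 0:22, 0:22]
        pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]).astype(float)
        n_inside = int(np.count_nonzero(tri.find_simplex(pts) >= 0))
        solidity_oracle = obj.n_voxels / n_inside
        assert m["solidity"] == pytest.approx(solidity_oracle, rel=0.02)

    def test_hull_volume_dominates_object_volume(self):
        for vol in (digitized_ball(8), digitized_ellipsoid((8, 5, 3))):
            obj = single_object(vol)
            m = convex_hull_metrics(obj)
            assert m["hull_volume"] >= shape_metrics(obj)["volume"]
            assert 0.0 < m["solidity"] <= 1.0

    def test_coplanar_object_flagged(self):
        flat = AstrocyteObject(1, [[0, y, x] for y in range(3) for x in range(3)], (1, 1, 1))
        with pytest.raises(ValueError, match="degenerate"):
            convex_hull_metrics(flat)


class TestEllipsoidFit:
    def test_axis_aligned_ellipsoid_recovered(self):
        obj = single_object(digitized_ellipsoid((20, 10, 5)))
        fit = fit_ellipsoid(obj)
        assert fit.elongation == pytest.approx(2.0, rel=0.05)
        assert fit.flatness == pytest.approx(2.0, rel=0.05)
        # major axis along z (the first grid axis) -> 90 deg off the XY plane
        assert fit.angle_xy == pytest.approx(90.0, abs=3.0)

    def test_ball_is_isotropic(self):
        fit = fit_ellipsoid(single_object(digitized_ball(12)))
        assert fit.elongation == pytest.approx(1.0, abs=0.05)
        assert fit.flatness == pytest.approx(1.0, abs=0.05)

    def test_rotation_in_xz_plane_shows_in_plane_angles(self):
        rot = rotation_about_z(45.0)
        obj = single_object(digitized_ellipsoid((20, 10, 5), rotation=rot))
        fit = fit_ellipsoid(obj)
        # the major axis moves from z toward x: 45 deg against XY and YZ,
        # staying inside the XZ plane
        assert fit.angle_xy == pytest.approx(45.0, abs=3.0)
        assert fit.angle_yz == pytest.approx(45.0, abs=3.0)
        assert fit.angle_xz == pytest.approx(0.0, abs=3.0)

    def test_all_angles_folded_into_first_quadrant(self):
        for deg in (10.0, 60.0, 80.0):
            obj = single_object(digitized_ellipsoid((15, 8, 4), rotation=rotation_about_z(deg)))
            fit = fit_ellipsoid(obj)
            for ang in (fit.angle_xy, fit.angle_xz, fit.angle_yz):
                assert 0.0 <= ang <= 90.0


class TestRelativeOrientation:
    def test_major_axis_along_normal_is_radial(self, geometry):
        fit = fit_ellipsoid(single_object(digitized_ellipsoid((20, 10, 5))))
        # construct a geometry whose normal equals the fitted major axis
        geom = CortexGeometry(1000.0, normal=fit.major_axis)
        assert relative_orientation(fit, geom) == pytest.approx(90.0, abs=0.1)

    def test_major_axis_in_tangent_plane_is_tangential(self, geometry):
        fit = fit_ellipsoid(single_object(digitized_ellipsoid((20, 10, 5))))
        t1, _ = geometry.tangent_basis()
        geom = CortexGeometry(1000.0, normal=np.cross(fit.major_axis, [0.0, 1.0, 0.0]))
        # normal orthogonal to the major axis -> axis lies in the tangent plane
        assert relative_orientation(fit, geom) == pytest.approx(0.0, abs=0.1)

    def test_known_elevation_angle(self):
        fit = fit_ellipsoid(single_object(digitized_ellipsoid((20, 10, 5))))
        v = fit.major_axis
        t = np.array([0.0, 1.0, 0.0]) if abs(v[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        t = t - (t @ v) * v
        t /= np.linalg.norm(t)
        # normal placed so the axis sits at 30 deg elevation from the tangent plane
        n = np.sin(np.radians(60.0)) * t + np.cos(np.radians(60.0)) * v
        geom = CortexGeometry(1000.0, normal=n)
        assert relative_orientation(fit, geom) == pytest.approx(30.0, abs=0.1)


class TestOrientation2D:
    @pytest.mark.parametrize(
        "bar_angle,expected",
        [(0.0, 0.0), (90.0, 90.0), (60.0, 60.0)],
    )
    def test_bar_angles_vs_horizontal_surface(self, bar_angle, expected):
        n = 101
        mask = np.zeros((n, n), dtype=bool)
        c = n // 2
        a = math.radians(bar_angle)
        for t in np.linspace(-45, 45, 400):
            r = int(round(c + t * math.sin(a)))
            col = int(round(c + t * math.cos(a)))
            mask[r, col] = True
        elong, angle = orientation_2d(mask, surface_direction=(0.0, 1.0))
        assert angle == pytest.approx(expected, abs=1.0)
        assert elong > 5.0

    def test_isotropic_mask_has_no_angle(self):
        mask = np.ones((5, 5), dtype=bool)
        elong, angle = orientation_2d(mask, surface_direction=(0.0, 1.0))
        assert elong == pytest.approx(1.0)
        assert math.isnan(angle)


class TestSubstructure:
    def test_zero_signal_gives_empty_set(self):
        obj = single_object(digitized_ball(5))
        signal = VoxelVolume(np.zeros_like(digitized_ball(5).labels), (1, 1, 1))
        assert len(substructure_mask(obj, signal, threshold=0.5)) == 0

    def test_suprathreshold_inside_roi_only(self):
        vol = digitized_ball(5)
        sig = np.zeros_like(vol.labels)
        sig[2:5, 2:5, 2:5] = 10  # partially overlapping the ball
        obj = single_object(vol)
        sub = substructure_mask(obj, VoxelVolume(sig, (1, 1, 1)), threshold=5)
        sub_set = {tuple(c) for c in sub}
        roi = {tuple(c) for c in obj.coords}
        hot = {tuple(c) for c in np.argwhere(sig > 5)}
        assert sub_set == roi & hot

    def test_grid_mismatch_rejected(self):
        obj = single_object(digitized_ball(5))
        with pytest.raises(ValueError):
            substructure_mask(obj, VoxelVolume(np.zeros((2, 2, 2), np.int32), (1, 1, 1)), 0)


class TestMorphometricVector:
    def test_exactly_24_named_features(self, geometry):
        obj = single_object(digitized_ball(8))
        vec = morphometric_vector(obj, geometry)
        assert len(vec) == 24
        assert tuple(vec) == FEATURE_NAMES

    def test_ball_is_round_and_solid(self, geometry):
        vec = morphometric_vector(single_object(digitized_ball(10)), geometry)
        assert vec["elongation"] == pytest.approx(1.0, abs=0.05)
        assert vec["flatness"] == pytest.approx(1.0, abs=0.05)
        assert vec["solidity"] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_cell_excluded(self, geometry):
        # 3 voxels: no hull, no ellipsoid fit -> most entries absent
        speck = AstrocyteObject(1, [[0, 0, 0], [0, 0, 1], [0, 1, 1]], (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="excluded"):
            morphometric_vector(speck, geometry)


class TestInvariances:
    def test_rotation_by_90_deg_preserves_scalars(self, geometry):
        vol = digitized_ellipsoid((12, 7, 4), rotation=rotation_about_z(30.0))
        rotated = VoxelVolume(np.rot90(vol.labels, axes=(1, 2)).copy(), vol.voxel_size)
        v1 = morphometric_vector(single_object(vol), geometry)
        v2 = morphometric_vector(single_object(rotated), geometry)
        for key in ("volume", "surface_area", "solidity", "sphericity", "elongation", "flatness"):
            assert v1[key] == pytest.approx(v2[key], rel=0.02), key

    def test_scale_consistency_volume_x8_area_x4(self):
        obj1 = single_object(digitized_ball(6, voxel=1.0))
        obj2 = AstrocyteObject(1, obj1.coords, (2.0, 2.0, 2.0))
        m1, m2 = shape_metrics(obj1), shape_metrics(obj2)
        assert m2["volume"] == pytest.approx(8 * m1["volume"])
        assert m2["surface_area"] == pytest.approx(4 * m1["surface_area"])
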