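"""Head-frame construction, rigid pose fitting and angular projections."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flockgaze import geometry as g


def random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.normal(0, 2.0, 3)
    return rot, trans


class TestBuildLocalAxes:
    def test_beak_thirty_degrees_below_horizon_inverts_exactly(self):
        # beak pointing 30 deg below horizon -> forward axis is the horizon
        beak = np.array([0.0, math.cos(math.radians(-30)), math.sin(math.radians(-30))])
        axes = g.build_local_axes([-1, 0, 0], [1, 0, 0], beak)
        np.testing.assert_allclose(axes, np.eye(3), atol=1e-12)

    def test_horizontal_beak_gives_forward_axis_raised_thirty_degrees(self):
        axes = g.build_local_axes([-1, 0, 0], [1, 0, 0], [0, 1, 0])
        y = axes[:, 1]
        elevation = math.degrees(math.asin(y[2]))
        assert elevation == pytest.approx(30.0, abs=1e-9)

    def test_equivariance_under_rigid_motion(self, rng):
        eye_l = np.array([-0.015, 0.002, 0.001])
        eye_r = np.array([0.016, -0.001, 0.0])
        beak = np.array([0.001, 0.05, -0.02])
        base = g.build_local_axes(eye_l, eye_r, beak)
        for _ in range(20):
            rot, trans = random_rigid(rng)
            moved = g.build_local_axes(rot @ eye_l + trans, rot @ eye_r + trans, rot @ beak + trans)
            np.testing.assert_allclose(moved, rot @ base, atol=1e-9)

    def test_degenerate_keypoints_raise(self):
        with pytest.raises(g.DegenerateGeometryError):
            g.build_local_axes([0, 0, 0], [0, 0, 0], [0, 1, 0])
        with pytest.raises(g.DegenerateGeometryError):
            # beak tip on the eye-eye axis
            g.build_local_axes([-1, 0, 0], [1, 0, 0], [0.5, 0, 0])

    def test_result_is_proper_rotation(self, rng):
        for _ in range(10):
            eyes = rng.normal(0, 0.02, (2, 3))
            beak = rng.normal(0, 0.05, 3)
            try:
                axes = g.build_local_axes(eyes[0], eyes[1], beak)
            except g.DegenerateGeometryError:
                continue
            np.testing.assert_allclose(axes.T @ axes, np.eye(3), atol=1e-9)
            assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture()
def calib():
    from flockgaze.synthetic import default_head_calibration

    return default_head_calibration()


class TestFitHeadPose:
    def test_identity_placement(self, calib):
        pose = g.fit_head_pose(calib.marker_template, calib)
        axes = g.build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
        np.testing.assert_allclose(pose.orientation, axes, atol=1e-9)
        np.testing.assert_allclose(pose.origin, calib.eye_mid, atol=1e-12)
        assert pose.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_recovers_applied_rotation(self, calib):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        observed = calib.marker_template @ rot.T + np.array([1.0, 2.0, 0.5])
        pose = g.fit_head_pose(observed, calib)
        axes = g.build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
        np.testing.assert_allclose(pose.orientation, rot @ axes, atol=1e-9)
        np.testing.assert_allclose(pose.origin, rot @ calib.eye_mid + [1.0, 2.0, 0.5], atol=1e-9)

    def test_three_exact_markers_still_determine_the_pose(self, calib):
        observed = calib.marker_template.astype(float).copy()
        observed[2] = np.nan
        pose = g.fit_head_pose(observed, calib)
        axes = g.build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
        np.testing.assert_allclose(pose.orientation, axes, atol=1e-9)
        assert pose.rms_residual == pytest.approx(0.0, abs=1e-10)

    def test_fewer_than_three_markers_is_missing_not_an_error(self, calib):
        observed = np.full((4, 3), np.nan)
        observed[0] = calib.marker_template[0]
        observed[1] = calib.marker_template[1]
        assert g.fit_head_pose(observed, calib) is None

    def test_batch_fit_matches_scalar_fit(self, calib, rng):
        n = 32
        obs = np.empty((n, 4, 3))
        for i in range(n):
            rot, trans = random_rigid(rng)
            obs[i] = calib.marker_template @ rot.T + trans
        obs[5, 2] = np.nan  # one partial frame
        obs[9] = np.nan  # one missing frame
        times = np.arange(n) / 60.0
        origins, orients, valid, rms = g.fit_head_poses(obs, calib, times)
        assert not valid[9] and valid[5]
        for i in (0, 5, 17):
            pose = g.fit_head_pose(obs[i], calib, t=times[i])
            np.testing.assert_allclose(origins[i], pose.origin, atol=1e-9)
            np.testing.assert_allclose(orients[i], pose.orientation, atol=1e-9)


class TestProjections:
    def pose(self, orientation=None, origin=(0, 0, 0)):
        return g.HeadPose(0.0, np.array(origin, float), orientation if orientation is not None else np.eye(3))

    def test_point_straight_ahead(self):
        a = g.world_to_head([0, 5, 0], self.pose())
        assert (a.azimuth, a.elevation) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_point_on_right_axis(self):
        a = g.world_to_head([3, 0, 0], self.pose())
        assert a.azimuth == pytest.approx(90.0)
        assert a.elevation == pytest.approx(0.0)

    def test_opposite_monitor_falls_105_degrees_on_the_other_side(self):
        # head midway between two diametrically opposite monitors, oriented
        # so monitor A sits on the right fovea (azimuth +75)
        monitor_a = 5.0 * g.angles_to_unit(75.0, 0.0)
        monitor_b = -monitor_a
        pose = self.pose()
        assert g.world_to_head(monitor_a, pose).azimuth == pytest.approx(75.0)
        assert g.world_to_head(monitor_b, pose).azimuth == pytest.approx(-105.0)

    def test_round_trip_reproduces_direction(self, rng):
        for _ in range(50):
            rot, trans = random_rigid(rng)
            pose = self.pose(rot, trans)
            p = rng.normal(0, 5, 3)
            if np.linalg.norm(p - trans) < 1e-3:
                continue
            a = g.world_to_head(p, pose)
            d = g.head_to_world(a, pose)
            expected = (p - trans) / np.linalg.norm(p - trans)
            np.testing.assert_allclose(d, expected, atol=1e-9)

    def test_zero_length_direction_raises(self):
        with pytest.raises(ValueError):
            g.world_to_head([0.0, 0.0, 0.0], self.pose())


class TestFovea:
    def test_offset_zero_on_axis(self):
        assert g.offset_from_fovea(g.EgocentricAngles(75, 0), "right") == pytest.approx(0.0)
        assert g.offset_from_fovea(g.EgocentricAngles(-75, 0), "left") == pytest.approx(0.0)

    def test_offset_along_meridian_equals_elevation(self):
        # from (75, 0) to (75, 10) the great-circle distance is exactly 10
        assert g.offset_from_fovea(g.EgocentricAngles(75, 10), "right") == pytest.approx(10.0, abs=0.01)

    def test_offset_zero_iff_on_axis(self, rng):
        for _ in range(30):
            az, el = rng.uniform(-180, 180), rng.uniform(-90, 90)
            off = g.offset_from_fovea(g.EgocentricAngles(az, el), "right")
            on_axis = abs(az - 75) < 1e-9 and abs(el) < 1e-9
            assert (off < 1e-9) == on_axis

    @pytest.mark.parametrize(
        "az,el,side,expected",
        [
            (75.0, 0.0, "right", True),
            (64.9, 0.0, "right", False),
            (80.0, -10.0, "right", True),
            (-75.0, 0.0, "left", True),
            (85.0, 10.0, "right", True),
            (85.1, 0.0, "right", False),
        ],
    )
    def test_rectangular_foveal_region(self, az, el, side, expected):
        assert g.is_foveated(g.EgocentricAngles(az, el), side) is expected

    def test_mirror_symmetry_swaps_eyes(self, rng):
        # reflecting a direction about the sagittal (YZ) plane flips the
        # azimuth sign, so left/right foveation verdicts swap exactly
        for _ in range(100):
            az, el = rng.uniform(-180, 180), rng.uniform(-90, 90)
            a = g.EgocentricAngles(az, el)
            m = g.EgocentricAngles(-az, el)
            assert g.is_foveated(a, "right") == g.is_foveated(m, "left")
            assert g.is_foveated(a, "left") == g.is_foveated(m, "right")

    def test_either_eye_mask_matches_scalar_tests(self, rng):
        az = rng.uniform(-180, 180, 200)
        el = rng.uniform(-90, 90, 200)
        mask = g.foveated_mask(az, el)
        for i in range(200):
            expected = g.is_foveated(g.EgocentricAngles(az[i], el[i]), "right") or g.is_foveated(
                g.EgocentricAngles(az[i], el[i]), "left"
            )
            assert mask[i] == expected
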