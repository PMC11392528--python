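"""Gap filling, smoothing, angular speed and saccade segmentation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flockgaze import preprocessing as pp


def make_series(quats=None, origins=None, n=None, valid=None, rate=60.0):
    if quats is None:
        quats = np.tile([0.0, 0.0, 0.0, 1.0], (n, 1))
    n = len(quats)
    if origins is None:
        origins = np.zeros((n, 3))
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return pp.PoseSeries(
        pigeon_id="p",
        times=np.arange(n) / rate,
        origins=np.asarray(origins, float),
        quats=np.asarray(quats, float),
        valid=np.asarray(valid, bool),
        rate=rate,
    )


def yaw_series(yaws_deg):
    angles = np.atleast_1d(np.asarray(yaws_deg, float))[:, None]
    return Rotation.from_euler("z", angles, degrees=True).as_quat()


class TestFillGaps:
    def test_constant_pose_gap_filled_with_constant(self):
        q = yaw_series([10.0] * 10)
        valid = np.ones(10, bool)
        valid[4:7] = False
        s = make_series(quats=q, valid=valid)
        out = pp.fill_gaps(s)
        assert out.valid.all()
        np.testing.assert_allclose(np.abs(out.quats @ q[0]), 1.0, atol=1e-9)

    def test_three_frame_gap_slerps_yaw(self):
        yaws = [0.0, 0.0, 0.0, 0.0, 30.0, 30.0]
        q = yaw_series(yaws)
        valid = np.array([True, False, False, False, True, True])
        s = make_series(quats=q, valid=valid)
        out = pp.fill_gaps(s, max_gap_s=0.2)
        got = Rotation.from_quat(out.quats[1:4]).as_euler("zyx", degrees=True)[:, 0]
        np.testing.assert_allclose(got, [7.5, 15.0, 22.5], atol=1e-6)

    def test_long_gap_stays_missing(self):
        n = 40
        q = yaw_series(np.zeros(n))
        valid = np.ones(n, bool)
        valid[5:35] = False  # 30 frames = 0.5 s > 0.2 s
        out = pp.fill_gaps(make_series(quats=q, valid=valid), max_gap_s=0.2)
        assert not out.valid[5:35].any()

    def test_observed_frames_never_modified(self, rng):
        n = 30
        q = Rotation.random(n, random_state=np.random.RandomState(3)).as_quat()
        origins = rng.normal(0, 1, (n, 3))
        valid = rng.random(n) > 0.3
        s = make_series(quats=q, origins=origins, valid=valid)
        out = pp.fill_gaps(s)
        np.testing.assert_array_equal(out.origins[valid], origins[valid])
        np.testing.assert_array_equal(out.quats[valid], q[valid])


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = make_series(n=20, origins=np.ones((20, 3)))
        out = pp.smooth_series(s, window_s=0.1)
        np.testing.assert_allclose(out.origins, s.origins, atol=1e-12)
        np.testing.assert_allclose(np.abs(np.sum(out.quats * s.quats, axis=1)), 1.0, atol=1e-12)

    def test_single_frame_spike_attenuated(self):
        origins = np.zeros((21, 3))
        origins[10, 0] = 0.05  # 5 cm spike
        s = make_series(n=21, origins=origins)
        out = pp.smooth_series(s, window_s=5 / 60.0)
        assert abs(out.origins[10, 0]) <= 0.011

    def test_nyquist_oscillation_killed_by_two_frame_window(self):
        # 30 Hz oscillation sampled at 60 Hz alternates sign; a 2-frame
        # moving average has zero gain at the Nyquist frequency
        n = 40
        origins = np.zeros((n, 3))
        origins[:, 0] = 0.02 * (-1.0) ** np.arange(n)
        out = pp.smooth_series(make_series(n=n, origins=origins), window_s=2 / 60.0)
        assert np.max(np.abs(out.origins[2:-2, 0])) < 1e-12


class TestAngularSpeed:
    def test_constant_orientation_zero(self):
        s = make_series(n=10)
        speeds = pp.angular_speed(s)
        np.testing.assert_allclose(speeds[:-1], 0.0, atol=1e-9)
        assert np.isnan(speeds[-1])

    def test_steady_yaw_rotation(self):
        yaws = np.arange(30) * 2.0  # 2 deg/frame at 60 Hz = 120 deg/s
        s = make_series(quats=yaw_series(yaws))
        np.testing.assert_allclose(pp.angular_speed(s)[:-1], 120.0, atol=1e-6)

    def test_matches_quaternion_angle_formula(self):
        r1 = Rotation.from_euler("z", 3.0, degrees=True)
        r2 = Rotation.from_euler("zx", [3.0, 4.0], degrees=True)
        s = make_series(quats=Rotation.concatenate([Rotation.identity(), r1, r2]).as_quat())
        speeds = pp.angular_speed(s)
        expected = np.degrees((r2 * r1.inv()).magnitude()) * 60.0
        assert speeds[1] == pytest.approx(expected, abs=1e-6)


def scripted_saccade_series(rng, n_saccades=20, rate=60.0, amp_range=(6, 40), speed_range=(70, 500)):
    """Fixation/saccade yaw script with known saccade intervals (all
    passing the 5 deg / 50 ms / 60 deg/s definition)."""
    yaws = [0.0]
    truth = []
    for _ in range(n_saccades):
        fix = int(rng.uniform(0.4, 0.9) * rate)
        yaws.extend([yaws[-1]] * fix)
        amp = rng.uniform(*amp_range)
        max_speed = min(speed_range[1], amp / 0.055 )  # keep duration >= 50 ms
        speed = rng.uniform(speed_range[0], max(speed_range[0] + 1, max_speed))
        nf = max(4, int(np.ceil(amp / speed * rate)))
        start = len(yaws) - 1
        sign = rng.choice([-1.0, 1.0])
        for k in range(1, nf + 1):
            yaws.append(yaws[start] + sign * amp * k / nf)
        truth.append((start, start + nf))
    yaws.extend([yaws[-1]] * 30)
    return np.asarray(yaws), truth


class TestDetectSaccades:
    def test_constant_orientation_no_saccades(self):
        assert pp.detect_saccades(make_series(n=50)) == []

    def test_scripted_twenty_degree_saccade(self):
        # 20 deg at 120 deg/s: 2 deg per frame for 10 frames (~167 ms)
        yaws = np.concatenate([np.zeros(20), np.arange(1, 11) * 2.0, np.full(20, 20.0)])
        events = pp.detect_saccades(make_series(quats=yaw_series(yaws)))
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(20.0, abs=1e-6)
        assert events[0].peak_speed == pytest.approx(120.0, abs=1e-6)

    def test_small_amplitude_not_a_saccade(self):
        # 3 deg at 90 deg/s: fast enough but below the 5 deg amplitude rule
        yaws = np.concatenate([np.zeros(20), np.arange(1, 3) * 1.5, np.full(20, 3.0)])
        assert pp.detect_saccades(make_series(quats=yaw_series(yaws))) == []

    def test_recall_and_precision_on_scripted_script(self, rng):
        yaws, truth = scripted_saccade_series(rng)
        s = make_series(quats=yaw_series(yaws))
        events = pp.detect_saccades(s)
        starts_true = {a for a, _ in truth}
        starts_det = {int(round(e.t_start * s.rate)) for e in events}
        hits = sum(1 for a in starts_true if any(abs(a - b) <= 1 for b in starts_det))
        recall = hits / len(starts_true)
        precision = hits / max(1, len(starts_det))
        assert recall >= 0.95 and precision >= 0.95

    def test_partition_of_valid_frames(self, rng):
        yaws, _ = scripted_saccade_series(rng, n_saccades=8)
        s = make_series(quats=yaw_series(yaws))
        events = pp.detect_saccades(s)
        mask = pp.saccade_mask(s, events)
        fixations = pp.fixation_intervals(s, events)
        fix_mask = np.zeros(len(s), bool)
        for a, b in fixations:
            fix_mask |= (s.times >= a - 1e-9) & (s.times <= b + 1e-9)
        assert not (mask & fix_mask).any()
        assert ((mask | fix_mask) == s.valid).all()

    def test_invariant_to_global_rigid_transform(self, rng):
        yaws, _ = scripted_saccade_series(rng, n_saccades=10)
        q = yaw_series(yaws)
        s = make_series(quats=q)
        world = Rotation.random(random_state=np.random.RandomState(5))
        s2 = make_series(quats=(world * Rotation.from_quat(q)).as_quat())
        e1 = pp.detect_saccades(s)
        e2 = pp.detect_saccades(s2)
        assert [(e.t_start, e.t_end) for e in e1] == [(e.t_start, e.t_end) for e in e2]
        np.testing.assert_allclose(
            [e.amplitude for e in e1], [e.amplitude for e in e2], atol=1e-9
        )


class TestImplausible:
    def test_teleport_masks_arriving_frame(self):
        origins = np.zeros((10, 3))
        origins[5:] = 2.0  # 2 m in one 60 Hz frame = 120 m/s
        out = pp.remove_implausible(make_series(n=10, origins=origins))
        assert not out.valid[5]
        assert out.valid[6:].all()
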