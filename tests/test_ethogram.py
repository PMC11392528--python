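"""Posture-rule behavior classification."""

import numpy as np
import pytest

from flockgaze import ethogram as eth

RATE = 60.0


def times(n):
    return np.arange(n) / RATE


class TestHeadDown:
    def test_head_below_body(self):
        assert eth.classify_head_down(np.array([0.10]), np.array([0.14]))[0]

    def test_equal_heights_is_not_head_down(self):
        assert not eth.classify_head_down(np.array([0.14]), np.array([0.14]))[0]


class TestPecks:
    def test_single_dip_event_at_minimum(self):
        beak = np.full(30, 0.08)
        beak[10:20] = [0.03, 0.025, 0.02, 0.015, 0.012, 0.01, 0.013, 0.02, 0.03, 0.035]
        pitch = np.full(30, -60.0)
        pecks = eth.detect_pecks(beak, pitch, times(30))
        np.testing.assert_allclose(pecks, [15 / RATE])

    def test_beak_above_threshold_no_peck(self):
        beak = np.full(30, 0.05)
        assert len(eth.detect_pecks(beak, np.full(30, -60.0), times(30))) == 0

    def test_two_dips_separated_by_rise_give_two_events(self):
        n = 150
        beak = np.full(n, 0.08)
        beak[10:16] = 0.01
        beak[80:86] = 0.01  # > 1 s later, beak above 4 cm in between
        pecks = eth.detect_pecks(beak, np.full(n, -60.0), times(n))
        assert len(pecks) == 2

    def test_beak_toward_body_excluded(self):
        beak = np.full(30, 0.01)
        pitch = np.full(30, -120.0)  # folded toward the body
        assert len(eth.detect_pecks(beak, pitch, times(30))) == 0

    def test_tie_takes_earliest_frame(self):
        beak = np.full(20, 0.08)
        beak[5:10] = 0.01  # flat-bottom dip
        pecks = eth.detect_pecks(beak, np.full(20, -60.0), times(20))
        np.testing.assert_allclose(pecks, [5 / RATE])


class TestFeedingIntervals:
    @pytest.mark.parametrize(
        "pecks,expected",
        [
            ([0.0, 3.0, 5.0], [(0.0, 5.0)]),
            ([0.0, 10.0], []),
            ([0.0, 5.0, 12.0, 14.0], [(0.0, 5.0), (12.0, 14.0)]),
            ([4.0], []),
        ],
    )
    def test_chaining_rule(self, pecks, expected):
        assert eth.feeding_intervals(np.array(pecks)) == expected


class TestGrooming:
    def check(self, pitch=0.0, roll=0.0, angle=10.0, dist=0.2, head_z=0.3, body_z=0.2):
        return eth.detect_grooming(
            np.array([pitch]), np.array([roll]), np.array([angle]),
            np.array([dist]), np.array([head_z]), np.array([body_z]),
        )[0]

    def test_breast_preen_strong_pitch(self):
        assert self.check(pitch=-110.0)

    def test_breast_preen_moderate_pitch_with_backward_head(self):
        assert self.check(pitch=-85.0, angle=70.0)

    def test_back_preen_requires_close_beak(self):
        assert self.check(angle=70.0, dist=0.05)
        assert not self.check(angle=70.0, dist=0.15)

    def test_scratch_rule(self):
        assert self.check(roll=60.0, head_z=0.21, body_z=0.20)
        assert not self.check(roll=60.0, head_z=0.30, body_z=0.20)

    def test_upright_scanning_is_not_grooming(self):
        assert not self.check(pitch=-10.0, angle=10.0, roll=0.0)


def _bowing_pitch(n, bow_frames, depth=35.0):
    """Upright pitch baseline with short scripted bows."""
    pitch = np.zeros(n)
    for f in bow_frames:
        pitch[f : f + 18] = -depth  # 0.3 s dip
    return pitch


class TestCourting:
    def setup_pair(self, n, bow_frames, separation, facing_toward=True):
        pitch_a = _bowing_pitch(n, bow_frames)
        pos_a = np.tile([0.0, 0.0, 0.2], (n, 1))
        pos_b = np.tile([0.0, separation, 0.2], (n, 1))
        fwd = [0.0, 1.0, 0.0] if facing_toward else [0.0, -1.0, 0.0]
        head_a = np.tile(fwd, (n, 1))
        head_b = np.tile([0.0, 1.0, 0.0], (n, 1))
        return (
            {"a": pitch_a, "b": np.zeros(n)},
            {"a": pos_a, "b": pos_b},
            {"a": head_a, "b": head_b},
        )

    def test_three_bows_close_and_facing_is_courting(self):
        n = 900
        pitches, pos, heads = self.setup_pair(n, [200, 400, 600], 0.4)
        courting, courted = eth.detect_courting(pitches, pos, heads, times(n), RATE)
        assert courting["a"].any()
        assert courted["b"].any()
        assert not courting["b"].any()

    def test_same_bows_too_far_is_not_courting(self):
        n = 900
        pitches, pos, heads = self.setup_pair(n, [200, 400, 600], 1.0)
        courting, _ = eth.detect_courting(pitches, pos, heads, times(n), RATE)
        assert not courting["a"].any()

    def test_single_bow_is_not_courting(self):
        n = 900
        pitches, pos, heads = self.setup_pair(n, [400], 0.4)
        courting, _ = eth.detect_courting(pitches, pos, heads, times(n), RATE)
        assert not courting["a"].any()

    def test_facing_away_is_not_courting(self):
        n = 900
        pitches, pos, heads = self.setup_pair(n, [200, 400, 600], 0.4, facing_toward=False)
        courting, _ = eth.detect_courting(pitches, pos, heads, times(n), RATE)
        assert not courting["a"].any()


class TestLocomotion:
    def test_running_directly_away(self):
        n = 120
        speed = np.zeros(n)
        speed[30:60] = 1.0
        dist = np.cumsum(np.where(np.arange(n) >= 30, 1.0 / RATE, 0.0)) + 3.0
        dist[60:] = dist[59]
        running = eth.detect_running_away(speed, dist, np.zeros(n, bool), RATE)
        assert running[35:55].all()
        assert not running[:25].any()

    def test_tangential_run_is_not_running_away(self):
        n = 120
        speed = np.zeros(n)
        speed[30:60] = 1.0
        dist = np.full(n, 3.0)  # constant distance from monitor
        assert not eth.detect_running_away(speed, dist, np.zeros(n, bool), RATE).any()

    def test_courting_excludes_running(self):
        n = 120
        speed = np.zeros(n)
        speed[30:60] = 1.0
        dist = np.cumsum(np.full(n, 1.0 / RATE)) + 3.0
        court = np.ones(n, bool)
        assert not eth.detect_running_away(speed, dist, court, RATE).any()

    def test_flying_burst(self):
        speed = np.zeros(120)
        speed[40:64] = 3.0  # 0.4 s
        flying = eth.detect_flying(speed, RATE)
        assert flying[40:63].all() and not flying[:39].any()

    def test_flying_too_short_or_too_slow(self):
        speed = np.zeros(120)
        speed[40:43] = 3.0  # 50 ms
        assert not eth.detect_flying(speed, RATE).any()
        assert not eth.detect_flying(np.full(120, 1.9), RATE).any()


class TestCompose:
    def test_precedence_and_residual(self):
        n = 6
        valid = np.array([True, True, True, True, True, False])
        feeding = np.array([True, False, False, False, False, False])
        head_down = np.array([True, True, False, False, False, False])
        flying = np.array([False, False, True, False, False, False])
        zeros = np.zeros(n, bool)
        tl = eth.compose_ethogram(
            "p", times(n), valid, flying, zeros, zeros, zeros, feeding, head_down,
            np.array([]), RATE,
        )
        assert list(tl.labels) == ["feeding", "head_down", "flying", "head_up", "head_up", "missing"]

    def test_labels_partition_valid_frames(self, rng):
        n = 200
        valid = rng.random(n) > 0.1
        masks = [rng.random(n) > 0.7 for _ in range(6)]
        tl = eth.compose_ethogram("p", times(n), valid, *masks, np.array([]), RATE)
        assert ((tl.labels == "missing") == ~valid).all()
        assert set(tl.labels[valid]) <= set(eth.PRECEDENCE)


class TestPitchRoll:
    def test_extended_pitch_past_minus_ninety(self):
        from flockgaze.synthetic import _yaw_pitch_matrix

        for target in (-30.0, -80.0, -110.0, 40.0, 100.0):
            mat = _yaw_pitch_matrix(25.0, target)
            pitch, roll = eth.head_pitch_roll(mat[None])
            assert pitch[0] == pytest.approx(target, abs=1e-9)
            assert roll[0] == pytest.approx(0.0, abs=1e-9)
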