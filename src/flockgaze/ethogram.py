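"""Rule-based per-frame behavior classification from 3D posture.

Each behavior is a simple kinematic threshold rule on head and body pose:

================  =========================================================
head_down         head centroid below the body centroid (strict)
pecking (event)   beak tip < 4 cm above ground while not oriented toward
                  the body (pitch > -100 deg); event at the beak-z minimum
feeding           any time between two pecks no more than 6 s apart
grooming          back-preen / breast-preen / head-scratch posture rules
courting          >= 2 head bows in an 8 s window within 0.6 m of a
                  neighbor faced within 120 deg; episodes < 1 s dropped
running_away      body speed > 0.6 m/s while receding from the monitor at
                  > 0.2 m/s and not courting; runs < 70 ms dropped
flying            body speed > 2 m/s; runs < 70 ms dropped
head_up           residual: valid, not head-down, no other rule firing
================  =========================================================

Frame labels are mutually exclusive with precedence
flying > running_away > courting > grooming > feeding > head_down > head_up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

PECK_BEAK_HEIGHT_M = 0.04
PECK_MIN_PITCH_DEG = -100.0
FEEDING_MAX_GAP_S = 6.0
RUN_SPEED_M_S = 0.6
RUN_RADIAL_SPEED_M_S = 0.2
FLY_SPEED_M_S = 2.0
LOCOMOTION_MIN_DURATION_S = 0.07
COURT_MAX_DISTANCE_M = 0.6
COURT_MAX_FACING_DEG = 120.0
COURT_WINDOW_S = 8.0
COURT_MIN_BOWS = 2
COURT_MIN_DURATION_S = 1.0
BOW_DEPTH_DEG = 25.0
BOW_MAX_DURATION_S = 2.0

#: label precedence, strongest first
PRECEDENCE = ("flying", "running_away", "courting", "grooming", "feeding", "head_down", "head_up")

_DUR_EPS = 1e-9


@dataclass
class BehaviorTimeline:
    """Per-frame behavior labels plus point events for one bird."""

    pigeon_id: str
    times: np.ndarray
    labels: np.ndarray  # strings, 'missing' where the frame is unresolved
    peck_times: np.ndarray
    rate: float = 60.0

    def proportion(self, label: str) -> float:
        """Proportion of valid frames carrying ``label``."""
        ok = self.labels != "missing"
        if not ok.any():
            return float("nan")
        return float(np.mean(self.labels[ok] == label))


def head_pitch_roll(orientations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extended-range pitch and roll of head orientations.

    Pitch is the elevation of the head's forward (Y) axis, disambiguated
    past +/-90 degrees by the dorsal (Z) axis so that a head tipped
    upside-forward (breast preening) reads below -90; range (-180, 180].
    Roll is the elevation of the lateral (X) axis, range [-90, 90].
    """
    o = np.asarray(orientations, dtype=float)
    fwd_z = o[..., 2, 1]
    dorsal_z = o[..., 2, 2]
    lateral_z = o[..., 2, 0]
    pitch = np.degrees(np.arctan2(fwd_z, dorsal_z))
    pitch = np.where(pitch <= -180.0, pitch + 360.0, pitch)
    roll = np.degrees(np.arcsin(np.clip(lateral_z, -1.0, 1.0)))
    return pitch, roll


def classify_head_down(head_z: np.ndarray, body_z: np.ndarray) -> np.ndarray:
    """Head centroid strictly below the body centroid (vertical axis)."""
    with np.errstate(invalid="ignore"):
        return np.asarray(head_z) < np.asarray(body_z)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs (stop exclusive)."""
    m = np.asarray(mask, dtype=bool)
    n = len(m)
    i = 0
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def detect_pecks(
    beak_z: np.ndarray,
    pitch: np.ndarray,
    times: np.ndarray,
    height_threshold: float = PECK_BEAK_HEIGHT_M,
    min_pitch: float = PECK_MIN_PITCH_DEG,
) -> np.ndarray:
    """Peck event times: one per maximal low-beak run, at the beak-z minimum.

    A frame qualifies when the beak tip is below ``height_threshold`` above
    the ground (z = 0) and the head is not folded toward the body
    (pitch > ``min_pitch``).  Ties take the earliest frame.
    """
    with np.errstate(invalid="ignore"):
        low = (np.asarray(beak_z) < height_threshold) & (np.asarray(pitch) > min_pitch)
    low &= np.isfinite(beak_z)
    out = []
    for i, j in _runs(low):
        k = i + int(np.argmin(beak_z[i:j]))
        out.append(times[k])
    return np.asarray(out, dtype=float)


def feeding_intervals(peck_times: np.ndarray, max_gap_s: float = FEEDING_MAX_GAP_S) -> list[tuple[float, float]]:
    """Union of spans between consecutive pecks spaced <= ``max_gap_s``."""
    p = np.sort(np.asarray(peck_times, dtype=float))
    if len(p) < 2:
        return []
    out: list[tuple[float, float]] = []
    start = None
    for a, b in zip(p[:-1], p[1:]):
        if b - a <= max_gap_s + _DUR_EPS:
            if start is None:
                start = a
            end = b
        else:
            if start is not None:
                out.append((start, end))
            start = None
    if start is not None:
        out.append((start, end))
    return out


def detect_grooming(
    pitch: np.ndarray,
    roll: np.ndarray,
    facing_angle: np.ndarray,
    beak_body_distance: np.ndarray,
    head_z: np.ndarray,
    body_z: np.ndarray,
) -> np.ndarray:
    """Per-frame grooming flag from the three preening/scratching sub-rules.

    ``facing_angle`` is the angle (degrees) between the head-direction
    vector and the body->head vector; large values mean the head is turned
    back over the body.
    """
    with np.errstate(invalid="ignore"):
        back_a = (facing_angle > 60.0) & (beak_body_distance < 0.10)
        back_b = (facing_angle > 40.0) & (beak_body_distance < 0.10) & (head_z > body_z)
        breast = (pitch < -100.0) | ((pitch < -80.0) & (facing_angle > 60.0))
        scratch = (np.abs(roll) > 50.0) & (head_z < body_z + 0.03)
    out = back_a | back_b | breast | scratch
    return np.where(np.isfinite(pitch), out, False)


def _bow_times(
    pitch: np.ndarray,
    times: np.ndarray,
    rate: float,
    depth_deg: float = BOW_DEPTH_DEG,
    max_duration_s: float = BOW_MAX_DURATION_S,
    baseline_window_s: float = 10.0,
    upright_baseline_deg: float = -30.0,
) -> np.ndarray:
    """Head-bow event times: pitch dips >= depth below the rolling median
    that return within ``max_duration_s``.

    Bowing is a courtship display performed down-and-back-up from an
    upright stance, so a dip only counts when the rolling-median baseline
    is upright (> ``upright_baseline_deg``) and the bird's median pitch in
    the half-second before and after the dip is upright too; this keeps
    pecking and preening dips from head-down postures from registering as
    bows."""
    p = np.asarray(pitch, dtype=float)
    finite = np.isfinite(p)
    if not finite.any():
        return np.asarray([])
    filled = p.copy()
    filled[~finite] = np.nanmedian(p)
    w = max(3, int(round(baseline_window_s * rate)) | 1)
    base = median_filter(filled, size=w, mode="nearest")
    dipped = finite & (filled < base - depth_deg) & (base > upright_baseline_deg)
    k = max(1, int(round(0.5 * rate)))
    out = []
    for i, j in _runs(dipped):
        if (j - i) / rate > max_duration_s + _DUR_EPS:
            continue
        before = np.median(filled[max(0, i - k):i]) if i > 0 else filled[i]
        after = np.median(filled[j:j + k]) if j < len(filled) else filled[j - 1]
        if before <= upright_baseline_deg or after <= upright_baseline_deg:
            continue
        m = i + int(np.argmin(filled[i:j]))
        out.append(times[m])
    return np.asarray(out, dtype=float)


def detect_courting(
    pitch_by_bird: dict[str, np.ndarray],
    position_by_bird: dict[str, np.ndarray],
    heading_by_bird: dict[str, np.ndarray],
    times: np.ndarray,
    rate: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Courting / courted frame masks across a flock.

    A bird courts when it bows at least twice within any 8 s window while
    standing within 0.6 m of a neighbor it faces within 120 degrees; the
    targeted neighbor is flagged courted over the same frames.  Episodes
    shorter than 1 s are discarded.  The facing test uses the courter's
    orientation cone only.
    """
    ids = list(pitch_by_bird)
    n = len(times)
    courting = {b: np.zeros(n, dtype=bool) for b in ids}
    courted = {b: np.zeros(n, dtype=bool) for b in ids}
    half = COURT_WINDOW_S / 2.0

    for b in ids:
        bows = _bow_times(pitch_by_bird[b], times, rate)
        if len(bows) < COURT_MIN_BOWS:
            continue
        # frames lying in some 8 s window holding >= 2 bows
        lo = np.searchsorted(bows, times - half, side="left")
        hi = np.searchsorted(bows, times + half, side="right")
        bowing = (hi - lo) >= COURT_MIN_BOWS

        pos = position_by_bird[b]
        head = heading_by_bird[b]
        target_idx = np.full(n, -1)
        others = [o for o in ids if o != b]
        if not others:
            continue
        dists = np.stack([np.linalg.norm(position_by_bird[o] - pos, axis=1) for o in others], axis=1)
        vecs = np.stack([position_by_bird[o] - pos for o in others], axis=1)
        hnorm = np.linalg.norm(head, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("nkj,nj->nk", vecs, head) / (
                np.linalg.norm(vecs, axis=2) * hnorm
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            eligible = (dists < COURT_MAX_DISTANCE_M) & (ang < COURT_MAX_FACING_DEG)
        masked = np.where(eligible, dists, np.inf)
        best = np.argmin(masked, axis=1)
        has_target = np.isfinite(masked[np.arange(n), best])
        target_idx = np.where(has_target, best, -1)

        active = bowing & has_target
        for i, j in _runs(active):
            if (j - i) / rate < COURT_MIN_DURATION_S - _DUR_EPS:
                continue
            courting[b][i:j] = True
            for k in range(i, j):
                courted[others[target_idx[k]]][k] = True
    return courting, courted


def _duration_filtered_runs(mask: np.ndarray, rate: float, min_duration_s: float):
    """Runs of a per-transition mask with duration = n_transitions / rate."""
    for i, j in _runs(mask):
        if (j - i) / rate >= min_duration_s - _DUR_EPS:
            yield i, j


def radial_speed(distance: np.ndarray, rate: float, window_s: float = 0.25) -> np.ndarray:
    """Centrally differenced d/dt of a distance series over ``window_s``."""
    d = np.asarray(distance, dtype=float)
    k = max(1, int(round(window_s * rate / 2.0)))
    n = len(d)
    out = np.full(n, np.nan)
    if n <= 2 * k:
        return out
    out[k:-k] = (d[2 * k:] - d[:-2 * k]) / (2 * k / rate)
    return out


def detect_running_away(
    speed: np.ndarray,
    distance_to_monitor: np.ndarray,
    courting_mask: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Per-frame running-away mask: fast locomotion receding from the
    monitor while not courting/courted, runs >= 70 ms."""
    rad = radial_speed(distance_to_monitor, rate)
    with np.errstate(invalid="ignore"):
        cand = (speed > RUN_SPEED_M_S) & (rad > RUN_RADIAL_SPEED_M_S) & ~courting_mask
    cand = np.where(np.isfinite(speed) & np.isfinite(rad), cand, False)
    out = np.zeros(len(speed), dtype=bool)
    for i, j in _duration_filtered_runs(cand, rate, LOCOMOTION_MIN_DURATION_S):
        out[i:j] = True
    return out


def detect_flying(speed: np.ndarray, rate: float) -> np.ndarray:
    """Per-frame flying mask: body speed > 2 m/s, runs >= 70 ms."""
    with np.errstate(invalid="ignore"):
        cand = np.asarray(speed) > FLY_SPEED_M_S
    cand = np.where(np.isfinite(speed), cand, False)
    out = np.zeros(len(speed), dtype=bool)
    for i, j in _duration_filtered_runs(cand, rate, LOCOMOTION_MIN_DURATION_S):
        out[i:j] = True
    return out


def intervals_to_mask(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for a, b in intervals:
        mask |= (times >= a - _DUR_EPS) & (times <= b + _DUR_EPS)
    return mask


def compose_ethogram(
    pigeon_id: str,
    times: np.ndarray,
    valid: np.ndarray,
    flying: np.ndarray,
    running_away: np.ndarray,
    courting: np.ndarray,
    grooming: np.ndarray,
    feeding: np.ndarray,
    head_down: np.ndarray,
    peck_times: np.ndarray,
    rate: float = 60.0,
) -> BehaviorTimeline:
    """Resolve co-firing detectors into one label per valid frame.

    Precedence puts locomotor escape above everything so that escape
    latencies are never masked by feeding or grooming labels; head_up is
    the residual state.
    """
    n = len(times)
    labels = np.full(n, "missing", dtype=object)
    masks = {
        "flying": flying,
        "running_away": running_away,
        "courting": courting,
        "grooming": grooming,
        "feeding": feeding,
        "head_down": head_down,
    }
    assigned = np.zeros(n, dtype=bool)
    for name in PRECEDENCE[:-1]:
        take = valid & masks[name] & ~assigned
        labels[take] = name
        assigned |= take
    rest = valid & ~assigned
    labels[rest] = "head_up"
    return BehaviorTimeline(
        pigeon_id=pigeon_id,
        times=np.asarray(times, dtype=float),
        labels=labels,
        peck_times=np.asarray(peck_times, dtype=float),
        rate=rate,
    )
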