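"""Pose time-series conditioning at 60 Hz: gap-filling, smoothing,
implausible-motion removal, and head-saccade segmentation.

Saccades follow the standard kinematic definition for head-tracked birds:
any head rotation larger than 5 degrees, lasting at least 50 ms, at more
than 60 deg/s; fixations are the complementary intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

#: saccade thresholds
SACCADE_SPEED_DEG_S = 60.0
SACCADE_MIN_DURATION_S = 0.05
SACCADE_MIN_AMPLITUDE_DEG = 5.0

#: implausible-motion gates (motion-capture glitches, not biology)
MAX_TRANSLATIONAL_SPEED_M_S = 20.0
MAX_ANGULAR_SPEED_DEG_S = 3000.0

_DUR_EPS = 1e-9


@dataclass
class PoseSeries:
    """Evenly sampled head-pose stream for one bird.

    Orientations are stored as scalar-last unit quaternions (world<-head).
    ``valid`` marks frames with a resolved head pose; ``body_centroid`` is
    the per-frame body reference point (6 cm below the back-marker cluster
    center) used by the posture rules, with its own validity implied by
    finite coordinates.
    """

    pigeon_id: str
    times: np.ndarray
    origins: np.ndarray
    quats: np.ndarray
    valid: np.ndarray
    body_centroid: np.ndarray | None = None
    rate: float = 60.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.origins = np.asarray(self.origins, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        if not (len(self.origins) == len(self.quats) == len(self.valid) == n):
            raise ValueError("series arrays must share one length")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError("sampling interval must be constant")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def __len__(self) -> int:
        return len(self.times)

    def rotations(self) -> Rotation:
        """Scipy Rotation view of the quaternions (invalid frames hold
        placeholder identity)."""
        q = np.where(self.valid[:, None], self.quats, [0.0, 0.0, 0.0, 1.0])
        return Rotation.from_quat(q)

    def orientation_matrices(self) -> np.ndarray:
        """(n, 3, 3) world<-head rotation matrices, NaN on invalid frames."""
        mats = self.rotations().as_matrix()
        mats[~self.valid] = np.nan
        return mats


@dataclass(frozen=True)
class SaccadeEvent:
    """One head saccade: a supra-threshold rotation run."""

    t_start: float
    t_end: float
    amplitude: float
    peak_speed: float


def _missing_runs(valid: np.ndarray):
    """Yield (start, stop) index ranges of consecutive invalid frames."""
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def fill_gaps(series: PoseSeries, max_gap_s: float = 0.2) -> PoseSeries:
    """Interpolate across short dropouts.

    Positions (and body centroids) are linearly interpolated; orientations
    are spherically interpolated (slerp).  Gaps longer than ``max_gap_s``
    remain missing, as do gaps touching either end of the series.  Observed
    frames are never modified.
    """
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")
    origins = series.origins.copy()
    quats = series.quats.copy()
    valid = series.valid.copy()
    body = None if series.body_centroid is None else series.body_centroid.copy()

    for i, j in _missing_runs(series.valid):
        if i == 0 or j == len(series):
            continue
        if (j - i) * series.dt > max_gap_s + _DUR_EPS:
            continue
        t0, t1 = series.times[i - 1], series.times[j]
        tt = series.times[i:j]
        w = (tt - t0) / (t1 - t0)
        origins[i:j] = (1 - w)[:, None] * origins[i - 1] + w[:, None] * origins[j]
        key = Rotation.from_quat(series.quats[[i - 1, j]])
        quats[i:j] = Slerp([t0, t1], key)(tt).as_quat()
        valid[i:j] = True

    if body is not None:
        bvalid = np.isfinite(body).all(axis=1)
        for i, j in _missing_runs(bvalid):
            if i == 0 or j == len(series):
                continue
            if (j - i) * series.dt > max_gap_s + _DUR_EPS:
                continue
            t0, t1 = series.times[i - 1], series.times[j]
            w = (series.times[i:j] - t0) / (t1 - t0)
            body[i:j] = (1 - w)[:, None] * body[i - 1] + w[:, None] * body[j]

    return replace(series, origins=origins, quats=quats, valid=valid, body_centroid=body)


def _windowed_mean(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over valid frames, window shrinking at edges."""
    n, k = values.shape
    filled = np.where(valid[:, None], values, 0.0)
    kernel = np.ones(window)
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    out = np.empty_like(filled)
    for c in range(k):
        out[:, c] = np.convolve(filled[:, c], kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = out / counts[:, None]
    out[counts == 0] = np.nan
    return out


def smooth_series(series: PoseSeries, window_s: float = 0.1) -> PoseSeries:
    """Zero-phase moving-average smoothing of positions and orientations.

    Orientation smoothing uses sign-aligned quaternion averaging followed by
    renormalization, adequate for the small within-window rotations of a
    60 Hz head-pose stream.  A window at or below one sample returns the
    series unchanged.
    """
    window = int(round(window_s * series.rate))
    if window <= 1:
        return series
    valid = series.valid
    origins = _windowed_mean(series.origins, valid, window)
    origins[~valid] = np.nan

    # align quaternion hemispheres along the series before averaging
    q = series.quats.copy()
    q[~valid] = 0.0
    ref = None
    for i in range(len(q)):
        if not valid[i]:
            continue
        if ref is not None and np.dot(q[i], ref) < 0:
            q[i] = -q[i]
        ref = q[i]
    qs = _windowed_mean(q, valid, window)
    norms = np.linalg.norm(qs, axis=1)
    ok = valid & (norms > 1e-9)
    qs[ok] = qs[ok] / norms[ok][:, None]
    qs[~ok] = series.quats[~ok]

    body = series.body_centroid
    if body is not None:
        bvalid = np.isfinite(body).all(axis=1)
        body_s = _windowed_mean(body, bvalid, window)
        body_s[~bvalid] = np.nan
        body = body_s

    out_origins = np.where(valid[:, None], origins, series.origins)
    return replace(series, origins=out_origins, quats=qs, body_centroid=body)


def angular_speed(series: PoseSeries) -> np.ndarray:
    """Per-transition head rotation speed, deg/s.

    Entry ``i`` is the geodesic angle between frames ``i`` and ``i+1`` times
    the rate; NaN where either frame is missing and at the final frame.
    """
    n = len(series)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    r = series.rotations()
    rel = r[1:] * r[:-1].inv()
    ang = np.degrees(rel.magnitude())
    pair_ok = series.valid[:-1] & series.valid[1:]
    out[:-1] = np.where(pair_ok, ang * series.rate, np.nan)
    return out


def translational_speed(positions: np.ndarray, rate: float) -> np.ndarray:
    """Per-transition speed (m/s) of a 3D track; NaN-propagating."""
    n = len(positions)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    step = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    out[:-1] = step * rate
    return out


def remove_implausible(
    series: PoseSeries,
    max_trans_speed: float = MAX_TRANSLATIONAL_SPEED_M_S,
    max_ang_speed: float = MAX_ANGULAR_SPEED_DEG_S,
) -> PoseSeries:
    """Mask frames reached by physically impossible jumps.

    A transition faster than the translational or angular gate marks the
    arriving frame missing; these are tracking glitches (marker swaps,
    ghost reflections), far beyond anything a pigeon can do.
    """
    valid = series.valid.copy()
    ts = translational_speed(series.origins, series.rate)
    ang = angular_speed(series)
    bad = np.zeros(len(series), dtype=bool)
    with np.errstate(invalid="ignore"):
        bad[1:] = (ts[:-1] > max_trans_speed) | (ang[:-1] > max_ang_speed)
    valid &= ~bad
    origins = series.origins.copy()
    quats = series.quats.copy()
    origins[bad] = np.nan
    return replace(series, origins=origins, quats=quats, valid=valid)


def detect_saccades(
    series: PoseSeries,
    speed_threshold: float = SACCADE_SPEED_DEG_S,
    min_duration_s: float = SACCADE_MIN_DURATION_S,
    min_amplitude_deg: float = SACCADE_MIN_AMPLITUDE_DEG,
) -> list[SaccadeEvent]:
    """Head saccades: maximal supra-speed runs passing duration and
    amplitude gates.

    Amplitude is the net geodesic rotation from the run's first to its last
    frame (displacement, not path length).
    """
    speeds = angular_speed(series)
    n = len(series)
    events: list[SaccadeEvent] = []
    with np.errstate(invalid="ignore"):
        fast = speeds > speed_threshold
    i = 0
    r = series.rotations()
    while i < n - 1:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and fast[j]:
            j += 1
        # transitions i..j-1 cover frames i..j
        duration = (j - i) / series.rate
        if duration >= min_duration_s - _DUR_EPS:
            amp = float(np.degrees((r[j] * r[i].inv()).magnitude()))
            if amp > min_amplitude_deg:
                events.append(
                    SaccadeEvent(
                        t_start=float(series.times[i]),
                        t_end=float(series.times[j]),
                        amplitude=amp,
                        peak_speed=float(np.nanmax(speeds[i:j])),
                    )
                )
        i = j
    return events


def saccade_mask(series: PoseSeries, saccades: list[SaccadeEvent]) -> np.ndarray:
    """Boolean per-frame mask covering all saccade frames (inclusive)."""
    mask = np.zeros(len(series), dtype=bool)
    for s in saccades:
        mask |= (series.times >= s.t_start - _DUR_EPS) & (series.times <= s.t_end + _DUR_EPS)
    return mask


def fixation_intervals(series: PoseSeries, saccades: list[SaccadeEvent]) -> list[tuple[float, float]]:
    """Inter-saccadic intervals over valid frames (start, end) in seconds."""
    mask = ~saccade_mask(series, saccades) & series.valid
    out: list[tuple[float, float]] = []
    i = 0
    n = len(series)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((float(series.times[i]), float(series.times[j - 1])))
            i = j
        else:
            i += 1
    return out
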