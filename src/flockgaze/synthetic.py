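"""Synthetic motion-capture generator for a foraging pigeon flock.

Produces marker-level 60 Hz data for a full experiment replica — 20 birds,
6 sessions split into 2 flocks of 10, 2 predator presentation events per
flock session — with complete ground truth: scripted behavior intervals,
peck and saccade times, per-bird detection latencies, and run/fly onsets
driven by a contagion model.  Every pipeline stage can be validated against
the scripts.

The scene replicates the experimental room: a 15 x 7 m hall with a monitor
on a predator hiding table at each of two opposite corners and a central
feeding area.  Birds forage on a correlated random walk, alternating pecking
bouts, head-up scanning (fixation/saccade cycles), and occasional grooming.
At each event, a bird foveates the active monitor after a lognormal
detection latency, runs away after a further delay, and flies at a time
drawn from the escape-contagion model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from . import geometry
from .ethogram import detect_grooming, feeding_intervals, head_pitch_roll
from .gaze import PredatorEvent
from .geometry import HeadCalibration, SceneObject

BODY_Z = 0.20
BACK_CENTER_ABOVE_BODY = 0.06
HEAD_FWD_OFFSET = 0.06  # head centroid sits ahead of the body centroid, along the head's facing
HEAD_Z_UP = 0.30
HEAD_Z_DOWN = 0.12
HEAD_Z_PECK = 0.065
HEAD_Z_GROOM = 0.17
PITCH_FEED = -55.0
PITCH_PECK = -80.0
PITCH_GROOM = -110.0

#: beak tip in head-local coordinates (4.5 cm, 30 deg below the horizon)
BEAK_OFFSET_HEAD = 0.045 * np.array(
    [0.0, math.cos(math.radians(-30.0)), math.sin(math.radians(-30.0))]
)


@dataclass
class GeneratorParams:
    """Study-condition knobs of the generator (defaults = the emulated
    experiment).

    Detection latencies are lognormal with a 3 s median; escape runs start a
    lognormal delay after detection; flight times follow the contagion model
    (independent lognormal base draws, followers attracted to the first
    flyer by an exponential kernel of mean ``contagion_kernel_s / coupling``).
    """

    rate: float = 60.0
    noise_sd: float = 0.001  # isotropic marker noise, meters
    before_cue_s: float = 120.0
    inter_event_s: float = 120.0
    tail_s: float = 15.0
    loom_duration_s: float = 10.0
    predator_run_s: float = 3.0
    detection_median_s: float = 3.0
    detection_sigma: float = 0.4
    run_delay_median_s: float = 5.0
    run_delay_sigma: float = 0.5
    fly_base_median_s: float = 12.0
    fly_base_sigma: float = 0.4
    coupling: float = 1.0
    contagion_kernel_s: float = 0.3
    walk_speed_m_s: float = 0.1
    feeding_radius_m: float = 1.8
    groom_probability: float = 0.12


# ---------------------------------------------------------------------------
# calibration and scene


def default_head_calibration() -> HeadCalibration:
    """Head calibration of the simulated birds.

    Keypoints are laid out in head-local coordinates (eyes 3 cm apart, beak
    tip 4.5 cm ahead and 30 degrees below the local horizon, a ~3 cm marker
    tetrahedron above the skull), then expressed in an arbitrary rotated and
    translated cluster frame, as a photogrammetric calibration would deliver
    them.
    """
    eye_left = np.array([-0.015, 0.0, 0.0])
    eye_right = np.array([0.015, 0.0, 0.0])
    beak_tip = BEAK_OFFSET_HEAD
    template = np.array(
        [
            [0.015, 0.010, 0.020],
            [-0.015, 0.010, 0.020],
            [0.000, -0.012, 0.030],
            [0.000, 0.022, 0.034],
        ]
    )
    rot = Rotation.from_euler("xyz", [20.0, -10.0, 35.0], degrees=True).as_matrix()
    shift = np.array([0.012, 0.021, 0.033])
    to_cluster = lambda p: p @ rot.T + shift
    return HeadCalibration(
        eye_left=to_cluster(eye_left),
        eye_right=to_cluster(eye_right),
        beak_tip=to_cluster(beak_tip),
        marker_template=to_cluster(template),
    )


#: back-plate marker template (7 x 3.5 cm styrofoam plate), plate frame
BACK_TEMPLATE = np.array(
    [
        [0.035, 0.0175, 0.0],
        [0.035, -0.0175, 0.0],
        [-0.035, 0.0175, 0.0],
        [-0.035, -0.0175, 0.0],
    ]
)


@dataclass
class Scene:
    """World layout: room, monitors, hiding tables, feeding area."""

    room: tuple[float, float, float]
    objects: list[SceneObject]
    feeding_center: np.ndarray

    def monitor(self, side: str) -> SceneObject:
        return next(o for o in self.objects if o.kind == "monitor" and o.id.endswith(side))

    def table(self, side: str) -> SceneObject:
        return next(o for o in self.objects if o.kind == "hiding_table" and o.id.endswith(side))

    @property
    def monitors(self) -> list[SceneObject]:
        return [o for o in self.objects if o.kind == "monitor"]


def simulate_scene() -> Scene:
    """The 15 x 7 m room with monitors/tables at two opposite corners and a
    central feeding area, all approximated by spheres."""
    north_xy = np.array([1.0, 6.0])
    south_xy = np.array([14.0, 1.0])
    objects = [
        SceneObject("monitor_North", "monitor", [*north_xy, 0.94], 0.35),
        SceneObject("monitor_South", "monitor", [*south_xy, 0.94], 0.35),
        SceneObject("table_North", "hiding_table", [*north_xy, 0.375], 0.65),
        SceneObject("table_South", "hiding_table", [*south_xy, 0.375], 0.65),
        SceneObject("feeding_area", "feeding_area", [7.5, 3.5, 0.0], 2.1),
    ]
    return Scene(room=(15.0, 7.0, 4.0), objects=objects, feeding_center=np.array([7.5, 3.5]))


# ---------------------------------------------------------------------------
# experiment design


@dataclass
class ExperimentDesign:
    """Roster of flock sessions and predator events."""

    rosters: pd.DataFrame  # trial_id, session, flock, pigeon_id
    events: pd.DataFrame  # trial_id, session, flock, event_index, side
    n_pigeons: int
    flock_size: int

    @property
    def trial_ids(self) -> list[str]:
        return sorted(self.rosters["trial_id"].unique())

    @property
    def n_trials(self) -> int:
        return self.rosters["trial_id"].nunique()

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_observations(self) -> int:
        per_trial = self.rosters.groupby("trial_id")["pigeon_id"].size()
        ev_per_trial = self.events.groupby("trial_id")["event_index"].size()
        return int((per_trial * ev_per_trial).sum())

    def pigeons_in(self, trial_id: str) -> list[str]:
        return self.rosters.loc[self.rosters["trial_id"] == trial_id, "pigeon_id"].tolist()


def pairing_matrix(design: ExperimentDesign) -> np.ndarray:
    """Counts of co-flock membership for every pigeon pair."""
    ids = sorted(design.rosters["pigeon_id"].unique())
    index = {p: i for i, p in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)), dtype=int)
    for _, grp in design.rosters.groupby("trial_id"):
        members = [index[p] for p in grp["pigeon_id"]]
        for i in members:
            for j in members:
                if i != j:
                    mat[i, j] += 1
    return mat


def build_design(
    seed: int,
    n_pigeons: int = 20,
    flock_size: int = 10,
    n_sessions: int = 6,
    max_restarts: int = 50,
) -> ExperimentDesign:
    """Pseudo-random flock assignment satisfying the pairing constraint.

    Each session splits the birds into two flocks; the search greedily picks,
    among random candidate splits, the one covering the most not-yet-paired
    bird pairs, restarting if any pair is still uncovered at the end.  Sides
    are counterbalanced: within a session one flock sees North first, the
    other South first, alternating across sessions.
    """
    if n_pigeons != 2 * flock_size:
        raise ValueError("design assumes exactly two flocks per session")
    rng = np.random.default_rng(seed)
    pigeons = [f"p{i:02d}" for i in range(n_pigeons)]

    for _ in range(max_restarts):
        covered = np.zeros((n_pigeons, n_pigeons), dtype=bool)
        sessions: list[tuple[list[int], list[int]]] = []
        for _s in range(n_sessions):
            best = None
            best_gain = -1
            for _c in range(60):
                perm = rng.permutation(n_pigeons)
                a, b = perm[:flock_size], perm[flock_size:]
                gain = 0
                for grp in (a, b):
                    sub = covered[np.ix_(grp, grp)]
                    gain += int((~sub).sum())
                if gain > best_gain:
                    best_gain = gain
                    best = (a.tolist(), b.tolist())
            a, b = best
            for grp in (a, b):
                covered[np.ix_(grp, grp)] = True
            sessions.append((sorted(a), sorted(b)))
        np.fill_diagonal(covered, True)
        if covered.all():
            break
    else:
        raise RuntimeError("could not satisfy the pairing constraint")

    roster_rows = []
    event_rows = []
    for s, (a, b) in enumerate(sessions, start=1):
        for flock, members in (("A", a), ("B", b)):
            trial_id = f"S{s}{flock}"
            for m in members:
                roster_rows.append(
                    {"trial_id": trial_id, "session": s, "flock": flock, "pigeon_id": pigeons[m]}
                )
            # counterbalance: A starts North on odd sessions, B the reverse
            first_north = (flock == "A") == (s % 2 == 1)
            sides = ["North", "South"] if first_north else ["South", "North"]
            for k, side in enumerate(sides, start=1):
                event_rows.append(
                    {
                        "trial_id": trial_id,
                        "session": s,
                        "flock": flock,
                        "event_index": k,
                        "side": side,
                    }
                )
    return ExperimentDesign(
        rosters=pd.DataFrame(roster_rows),
        events=pd.DataFrame(event_rows),
        n_pigeons=n_pigeons,
        flock_size=flock_size,
    )


# ---------------------------------------------------------------------------
# latency model


def simulate_latency_model(
    n_birds: int,
    coupling: float,
    rng: np.random.Generator,
    params: GeneratorParams | None = None,
) -> np.ndarray:
    """Flight latencies for one event under the escape-contagion model.

    With ``coupling`` = 0 the latencies are i.i.d. lognormal (the null
    model).  With coupling c > 0, each bird other than the earliest flyer
    flies at the first flight time plus an Exp(mean kernel/c) lag, truncated
    at its own independent draw.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    p = params or GeneratorParams()
    base = rng.lognormal(mean=math.log(p.fly_base_median_s), sigma=p.fly_base_sigma, size=n_birds)
    if coupling == 0:
        return base
    first = np.argmin(base)
    lags = rng.exponential(scale=p.contagion_kernel_s / coupling, size=n_birds)
    out = np.minimum(base, base[first] + lags)
    out[first] = base[first]
    return out


# ---------------------------------------------------------------------------
# track rendering


def _yaw_pitch_matrix(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """World<-head rotation with forward bearing ``yaw`` (0 = +Y, positive
    clockwise toward +X, matching the azimuth convention) and pitch about
    the head's lateral axis."""
    y = math.radians(yaw_deg)
    rz = np.array(
        [[math.cos(y), math.sin(y), 0.0], [-math.sin(y), math.cos(y), 0.0], [0.0, 0.0, 1.0]]
    )
    rx = geometry._rotation_about_axis(np.array([1.0, 0.0, 0.0]), pitch_deg)
    return rz @ rx


def _bearing_deg(from_xy: np.ndarray, to_xy: np.ndarray) -> float:
    d = np.asarray(to_xy, float) - np.asarray(from_xy, float)
    return math.degrees(math.atan2(d[0], d[1]))


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _monitor_safe_yaw(rng: np.random.Generator, head_xy: np.ndarray, monitors_xy: list[np.ndarray],
                      buffer_deg: float = 18.0) -> float:
    """Random scan bearing keeping both monitors outside the foveal azimuth
    band (so chance cue foveations cannot precede the scripted detection)."""
    for _ in range(200):
        yaw = rng.uniform(-180.0, 180.0)
        ok = True
        for m in monitors_xy:
            az = _wrap_deg(_bearing_deg(head_xy, m) - yaw)
            if abs(abs(az) - geometry.FOVEA_AZIMUTH_DEG) <= buffer_deg:
                ok = False
                break
        if ok:
            return yaw
    return yaw  # pragma: no cover


class _BirdScript:
    """Frame-by-frame renderer of one bird's trial, with ground truth."""

    def __init__(
        self,
        pigeon_id: str,
        n_frames: int,
        params: GeneratorParams,
        rng: np.random.Generator,
        scene: Scene,
        start_xy: np.ndarray,
    ):
        self.pid = pigeon_id
        self.n = n_frames
        self.p = params
        self.rng = rng
        self.scene = scene
        self.rate = params.rate
        self.dt = 1.0 / params.rate
        self.body = np.zeros((n_frames, 3))
        self.body[:, 2] = BODY_Z
        self.head = np.zeros((n_frames, 3))
        self.quat = np.zeros((n_frames, 4))
        self.heading = np.zeros(n_frames)  # body bearing, degrees
        self.i = 0
        # current state
        self.xy = np.array(start_xy, dtype=float)
        self.walk_dir = rng.uniform(-180, 180)
        self.cur_yaw = self.walk_dir
        self.R = Rotation.from_matrix(_yaw_pitch_matrix(self.walk_dir, 0.0))
        self.head_z = HEAD_Z_UP
        self.limit = n_frames  # hard frame cap honored by every fill
        # ground truth
        self.gt_saccades: list[tuple[float, float]] = []
        self.gt_pecks: list[float] = []
        self.groom_iv: list[tuple[float, float]] = []
        self.run_iv: list[tuple[float, float]] = []
        self.fly_iv: list[tuple[float, float]] = []
        self.fov_iv: list[tuple[float, float, str]] = []
        self.monitors_xy = [m.center[:2] for m in scene.monitors]

    # -- primitive fills ----------------------------------------------------

    def _head_xy(self) -> np.ndarray:
        # neck carries the head ahead of the body along the head's facing
        fwd = self.R.as_matrix()[:2, 1]
        n = np.linalg.norm(fwd)
        if n < 0.2:  # near-vertical pitch; fall back to the body heading
            fwd = np.array(
                [math.sin(math.radians(self.cur_yaw)), math.cos(math.radians(self.cur_yaw))]
            )
            n = 1.0
        return self.xy + HEAD_FWD_OFFSET * fwd / n

    def _emit(self, k: int, velocity_xy: np.ndarray | None = None, crw: bool = False,
              body_z: float | None = None, vz: float = 0.0):
        """Advance k frames of body motion with the current head state."""
        k = min(k, self.limit - self.i, self.n - self.i)
        q = self.R.as_quat()
        for _ in range(k):
            if crw:
                self.walk_dir += self.rng.normal(0.0, 8.0)
                to_center = self.scene.feeding_center - self.xy
                if np.linalg.norm(to_center) > self.p.feeding_radius_m:
                    self.walk_dir = _bearing_deg(self.xy, self.scene.feeding_center) + self.rng.normal(0, 15)
                step = self.p.walk_speed_m_s * self.dt
                self.xy = self.xy + step * np.array(
                    [math.sin(math.radians(self.walk_dir)), math.cos(math.radians(self.walk_dir))]
                )
            elif velocity_xy is not None:
                self.xy = self.xy + velocity_xy * self.dt
            self.xy[0] = np.clip(self.xy[0], 0.4, self.scene.room[0] - 0.4)
            self.xy[1] = np.clip(self.xy[1], 0.4, self.scene.room[1] - 0.4)
            i = self.i
            self.body[i, :2] = self.xy
            if body_z is not None:
                self.body[i, 2] = body_z
            elif vz != 0.0 and i > 0:
                self.body[i, 2] = self.body[i - 1, 2] + vz * self.dt
            self.head[i, :2] = self._head_xy()
            self.head[i, 2] = self.head_z
            self.quat[i] = q
            self.heading[i] = self.walk_dir
            self.i += 1
            if self.i >= self.n:
                return

    def rotate_to(self, R_target: Rotation, n_frames: int, head_z: float | None = None,
                  crw: bool = False):
        """Slerp rotation (and head-height blend) over n_frames; records the
        movement as a ground-truth saccade when it meets the definition."""
        n_frames = max(1, min(n_frames, self.n - self.i))
        rel = R_target * self.R.inv()
        amp = math.degrees(rel.magnitude())
        t0 = self.i * self.dt
        key = Rotation.concatenate([self.R, R_target])
        slerp = Slerp([0.0, 1.0], key)
        z0 = self.head_z
        z1 = self.head_z if head_z is None else head_z
        for k in range(1, n_frames + 1):
            if self.i >= min(self.limit, self.n):
                break
            f = k / n_frames
            self.R = slerp(f)
            self.head_z = z0 + (z1 - z0) * f
            self._emit(1, crw=crw)
        dur = n_frames * self.dt
        speed = amp / dur if dur > 0 else 0.0
        if amp > 5.0 and dur >= 0.05 - 1e-9 and speed > 60.0:
            self.gt_saccades.append((t0, self.i * self.dt))

    # -- foraging segments --------------------------------------------------

    def scan_segment(self, until_frame: int, walking: bool = True,
                     walk_velocity: np.ndarray | None = None):
        """Head-up fixation/saccade cycles until ``until_frame``."""
        yaw = _monitor_safe_yaw(self.rng, self._head_xy(), self.monitors_xy)
        self.rotate_to(Rotation.from_matrix(_yaw_pitch_matrix(yaw, 0.0)), 9, head_z=HEAD_Z_UP)
        self.cur_yaw = yaw
        while self.i < min(until_frame, self.n):
            fix = int(round(self.rng.uniform(0.3, 0.8) * self.rate))
            fix = min(fix, until_frame - self.i)
            if fix > 0:
                self._emit(fix, crw=walking and walk_velocity is None, velocity_xy=walk_velocity)
            if self.i >= until_frame:
                break
            amp = self.rng.uniform(10.0, 60.0)
            speed = self.rng.uniform(100.0, 400.0)
            nf = max(4, int(math.ceil(amp / speed * self.rate)))
            yaw = _monitor_safe_yaw(self.rng, self._head_xy(), self.monitors_xy)
            self.cur_yaw = yaw
            self.rotate_to(Rotation.from_matrix(_yaw_pitch_matrix(yaw, 0.0)), nf)

    def feed_segment(self, until_frame: int):
        """Head-down pecking bout until ``until_frame``.

        Head yaw stays fixed for the whole bout so every transition is a
        pure pitch rotation (no roll transients from the slerp)."""
        yaw = self.cur_yaw
        self.rotate_to(
            Rotation.from_matrix(_yaw_pitch_matrix(yaw, PITCH_FEED)), 10, head_z=HEAD_Z_DOWN
        )
        down = Rotation.from_matrix(_yaw_pitch_matrix(yaw, PITCH_PECK))
        up = Rotation.from_matrix(_yaw_pitch_matrix(yaw, PITCH_FEED))
        while self.i < min(until_frame, self.n):
            gap = int(round(self.rng.uniform(0.9, 1.6) * self.rate))
            hold = min(gap, until_frame - self.i)
            self._emit(hold, crw=True)
            if self.i + 12 > until_frame or self.i + 12 > self.n:
                break
            # peck dip: 6 frames down, 6 up; event at the bottom frame
            self.rotate_to(down, 6, head_z=HEAD_Z_PECK)
            self.gt_pecks.append((self.i - 1) * self.dt)
            self.rotate_to(up, 6, head_z=HEAD_Z_DOWN)

    def groom_segment(self, until_frame: int):
        """Breast-preening bout (strong downward pitch) until ``until_frame``."""
        self.rotate_to(
            Rotation.from_matrix(_yaw_pitch_matrix(self.cur_yaw, PITCH_GROOM)), 15, head_z=HEAD_Z_GROOM
        )
        t0 = self.i * self.dt
        self._emit(max(0, until_frame - self.i))
        self.groom_iv.append((t0, self.i * self.dt))
        self.rotate_to(
            Rotation.from_matrix(_yaw_pitch_matrix(self.cur_yaw, 0.0)), 15, head_z=HEAD_Z_UP
        )

    def forage_until(self, stop_frame: int):
        """Alternate feeding / scanning / occasional grooming segments,
        arriving exactly at ``stop_frame`` (current pose held at the end)."""
        stop_frame = min(stop_frame, self.n)
        self.limit = stop_frame
        while self.i < stop_frame:
            if stop_frame - self.i < 40:
                self._emit(stop_frame - self.i)
                break
            u = self.rng.random()
            dur = self.rng.uniform(4.0, 9.0)
            seg_end = min(stop_frame, self.i + int(dur * self.rate))
            if u < self.p.groom_probability:
                self.groom_segment(min(seg_end, self.i + int(self.rng.uniform(2.0, 4.0) * self.rate)))
            elif u < self.p.groom_probability + 0.35:
                self.scan_segment(seg_end)
            else:
                self.feed_segment(seg_end)
        self.limit = self.n

    # -- predator event -----------------------------------------------------

    def respond_to_event(self, monitor: SceneObject, detect_t: float, run_t: float, fly_t: float):
        """Detection saccade, monitor hold, escape run, flight, and return."""
        sacc_frames = 6
        d_f = int(round(detect_t * self.rate))
        self.forage_until(d_f - sacc_frames)

        # orientation putting the monitor exactly on one fovea at detection;
        # iterate once because the head offset follows the final facing
        side = 1.0 if _wrap_deg(_bearing_deg(self.xy, monitor.center[:2]) - self.cur_yaw) >= 0 else -1.0
        u = geometry.angles_to_unit(side * geometry.FOVEA_AZIMUTH_DEG, 0.0)
        head_pos = np.array([*self._head_xy(), HEAD_Z_UP])
        for _ in range(3):
            d = monitor.center - head_pos
            d = d / np.linalg.norm(d)
            bearing = _bearing_deg(head_pos[:2], monitor.center[:2])
            r0 = _yaw_pitch_matrix(bearing - side * geometry.FOVEA_AZIMUTH_DEG, 0.0)
            u0 = r0.T @ d
            axis = np.cross(u, u0)
            norm = np.linalg.norm(axis)
            if norm > 1e-12:
                ang = math.degrees(math.asin(min(1.0, norm)))
                if np.dot(u, u0) < 0:
                    ang = 180.0 - ang
                corr = geometry._rotation_about_axis(axis / norm, ang)
            else:
                corr = np.eye(3)
            r_target = Rotation.from_matrix(r0 @ corr)
            fwd = r_target.as_matrix()[:2, 1]
            fwd = fwd / max(np.linalg.norm(fwd), 0.2)
            head_pos = np.array([*(self.xy + HEAD_FWD_OFFSET * fwd), HEAD_Z_UP])

        self.rotate_to(r_target, sacc_frames, head_z=HEAD_Z_UP)
        fov_start = self.i * self.dt

        # hold the monitor foveated, standing, until the escape run
        r_f = int(round(run_t * self.rate))
        self._emit(max(0, r_f - self.i))

        flee = self.xy - monitor.center[:2]
        flee = flee / np.linalg.norm(flee)
        f_f = int(round(fly_t * self.rate))
        run_frames = min(
            int(round(self.rng.uniform(0.6, 1.0) * self.rate)), max(5, f_f - self.i - 3)
        )
        t0 = self.i * self.dt
        self._emit(run_frames, velocity_xy=1.0 * flee)
        self.run_iv.append((t0, self.i * self.dt))
        self._emit(max(0, f_f - self.i))

        # flight burst, then landing glide
        fly_frames = int(round(0.7 * self.rate))
        t0 = self.i * self.dt
        self._emit(fly_frames, velocity_xy=3.0 * flee, vz=0.85)
        self.fly_iv.append((t0, self.i * self.dt))
        self.fov_iv.append((fov_start, self.i * self.dt, monitor.id))
        land_frames = int(round(2.0 * self.rate))
        self._emit(land_frames, velocity_xy=0.2 * flee, vz=-(self.body[self.i - 1, 2] - BODY_Z) / (land_frames * self.dt))
        self.body[max(0, self.i - 1), 2] = BODY_Z
        self._emit(int(1.0 * self.rate))

        # walk back toward the feeding area, scanning
        back_f = self.i + int(round(np.linalg.norm(self.scene.feeding_center - self.xy) / 0.3 * self.rate))
        self.walk_dir = _bearing_deg(self.xy, self.scene.feeding_center)
        v = 0.3 * np.array(
            [math.sin(math.radians(self.walk_dir)), math.cos(math.radians(self.walk_dir))]
        )
        self.scan_segment(min(back_f, self.n), walk_velocity=v)


@dataclass
class TrialGroundTruth:
    """Scripted truth for one simulated trial."""

    labels: dict[str, np.ndarray]
    peck_times: dict[str, np.ndarray]
    saccades: dict[str, list[tuple[float, float]]]
    cue_foveations: dict[str, list[tuple[float, float, str]]]
    responses: pd.DataFrame  # pigeon_id, event_index, side, detect_t, run_t, fly_t (absolute)


@dataclass
class SimulatedTrial:
    """Marker-level output of one flock session plus its ground truth."""

    trial_id: str
    times: np.ndarray
    rate: float
    pigeons: list[str]
    head_markers: dict[str, np.ndarray]
    back_markers: dict[str, np.ndarray]
    events: list[PredatorEvent]
    truth: TrialGroundTruth
    calibration: HeadCalibration


def _ground_truth_labels(script: _BirdScript) -> np.ndarray:
    """Per-frame labels by applying the behavior definitions to the scripted
    (noise-free, pre-marker) kinematics, with the same precedence the
    classifier uses."""
    n = script.n
    times = np.arange(n) / script.rate
    labels = np.full(n, "head_up", dtype=object)

    def mask_of(intervals):
        m = np.zeros(n, dtype=bool)
        for iv in intervals:
            a, b = iv[0], iv[1]
            m |= (times >= a - 1e-9) & (times < b - 1e-9)
        return m

    head_down = script.head[:, 2] < script.body[:, 2]
    mats = Rotation.from_quat(script.quat).as_matrix()
    pitch, roll = head_pitch_roll(mats)
    fwd = mats[:, :, 1]
    to_head = script.head - script.body
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ni,ni->n", fwd, to_head) / (
            np.linalg.norm(fwd, axis=1) * np.linalg.norm(to_head, axis=1)
        )
    facing = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    beak = script.head + np.einsum("nij,j->ni", mats, BEAK_OFFSET_HEAD)
    beak_body = np.linalg.norm(beak - script.body, axis=1)
    grooming = mask_of(script.groom_iv) | detect_grooming(
        pitch, roll, facing, beak_body, script.head[:, 2], script.body[:, 2]
    )
    feeding = mask_of(feeding_intervals(np.asarray(script.gt_pecks)))
    running = mask_of(script.run_iv)
    flying = mask_of(script.fly_iv)

    labels[head_down] = "head_down"
    labels[feeding] = "feeding"
    labels[grooming] = "grooming"
    labels[running] = "running_away"
    labels[flying] = "flying"
    return labels


def simulate_trial(
    trial_id: str,
    pigeons: list[str],
    events_spec: list[tuple[int, str]],
    scene: Scene,
    params: GeneratorParams,
    seed: int,
    calib: HeadCalibration | None = None,
) -> SimulatedTrial:
    """Render one flock session: 60 Hz markers for every bird plus truth.

    ``events_spec`` lists (event_index, side) in presentation order.  The
    first loom starts after the before-cue period; subsequent events follow
    after the inter-event feeding period.
    """
    rng = np.random.default_rng(seed)
    calib = calib or default_head_calibration()
    p = params

    event_onsets = []
    t = p.before_cue_s
    for _ in events_spec:
        event_onsets.append(t)
        t += p.loom_duration_s + p.predator_run_s + p.inter_event_s
    total_s = event_onsets[-1] + p.loom_duration_s + p.predator_run_s + p.tail_s
    n = int(round(total_s * p.rate))
    times = np.arange(n) / p.rate

    events = [
        PredatorEvent(
            trial_id=trial_id,
            event_index=k,
            side=side,
            t_loom_on=on,
            t_loom_off=on + p.loom_duration_s,
            t_pred_on=on + p.loom_duration_s,
            t_pred_off=on + p.loom_duration_s + p.predator_run_s,
        )
        for (k, side), on in zip(events_spec, event_onsets)
    ]

    # response schedule: detection, run, fly per bird per event
    rows = []
    schedule: dict[str, list[tuple[SceneObject, float, float, float]]] = {b: [] for b in pigeons}
    for ev in events:
        detect = np.clip(
            rng.lognormal(math.log(p.detection_median_s), p.detection_sigma, size=len(pigeons)),
            0.5,
            p.loom_duration_s - 1.0,
        )
        run_delay = np.maximum(
            rng.lognormal(math.log(p.run_delay_median_s), p.run_delay_sigma, size=len(pigeons)),
            0.55,
        )
        fly = simulate_latency_model(len(pigeons), p.coupling, rng, p)
        # keep the contagion-model flight times intact: the escape run is
        # pulled earlier when needed rather than delaying the flight
        fly_abs = np.minimum(ev.t_loom_on + fly, ev.t_pred_off + 6.0)
        run_abs = np.minimum(ev.t_loom_on + detect + run_delay, fly_abs - 0.4)
        floor = ev.t_loom_on + detect + 0.55
        late = run_abs < floor
        run_abs[late] = floor[late]
        fly_abs = np.maximum(fly_abs, run_abs + 0.4)
        monitor = scene.monitor(ev.side)
        for b, d, r, f in zip(pigeons, ev.t_loom_on + detect, run_abs, fly_abs):
            schedule[b].append((monitor, d, r, f))
            rows.append(
                {
                    "pigeon_id": b,
                    "trial_id": trial_id,
                    "event_index": ev.event_index,
                    "side": ev.side,
                    "detect_t": d,
                    "run_t": r,
                    "fly_t": f,
                }
            )

    # render each bird
    head_markers: dict[str, np.ndarray] = {}
    back_markers: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    pecks: dict[str, np.ndarray] = {}
    saccades: dict[str, list[tuple[float, float]]] = {}
    fovs: dict[str, list[tuple[float, float, str]]] = {}

    axes = geometry.build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
    head_offsets = (calib.marker_template - calib.eye_mid) @ axes  # head-frame offsets

    for b in pigeons:
        r = rng.uniform(0.3, p.feeding_radius_m * 0.8)
        a = rng.uniform(0, 2 * math.pi)
        start = scene.feeding_center + r * np.array([math.cos(a), math.sin(a)])
        script = _BirdScript(b, n, p, rng, scene, start)
        for monitor, d, rn, fl in schedule[b]:
            script.respond_to_event(monitor, d, rn, fl)
        script.forage_until(n)

        rot = Rotation.from_quat(script.quat).as_matrix()
        hm = np.einsum("nij,kj->nki", rot, head_offsets) + script.head[:, None, :]
        ryaw = np.stack(
            [_yaw_pitch_matrix(h, 0.0) for h in script.heading]
        )
        back_center = script.body + np.array([0.0, 0.0, BACK_CENTER_ABOVE_BODY])
        bm = np.einsum("nij,kj->nki", ryaw, BACK_TEMPLATE) + back_center[:, None, :]
        if p.noise_sd > 0:
            hm = hm + rng.normal(0.0, p.noise_sd, hm.shape)
            bm = bm + rng.normal(0.0, p.noise_sd, bm.shape)
        head_markers[b] = hm
        back_markers[b] = bm
        labels[b] = _ground_truth_labels(script)
        pecks[b] = np.asarray(script.gt_pecks)
        saccades[b] = script.gt_saccades
        fovs[b] = script.fov_iv

    truth = TrialGroundTruth(
        labels=labels,
        peck_times=pecks,
        saccades=saccades,
        cue_foveations=fovs,
        responses=pd.DataFrame(rows),
    )
    return SimulatedTrial(
        trial_id=trial_id,
        times=times,
        rate=p.rate,
        pigeons=list(pigeons),
        head_markers=head_markers,
        back_markers=back_markers,
        events=events,
        truth=truth,
        calibration=calib,
    )


def simulate_tracks(
    design: ExperimentDesign,
    scene: Scene,
    seed: int,
    params: GeneratorParams | None = None,
    trial_ids: list[str] | None = None,
) -> dict[str, SimulatedTrial]:
    """Render the (optionally restricted) design; one seeded substream per
    trial so any subset reproduces the full run exactly."""
    params = params or GeneratorParams()
    out: dict[str, SimulatedTrial] = {}
    wanted = set(trial_ids) if trial_ids is not None else None
    for k, trial_id in enumerate(design.trial_ids):
        if wanted is not None and trial_id not in wanted:
            continue
        ev = design.events[design.events["trial_id"] == trial_id].sort_values("event_index")
        spec = list(zip(ev["event_index"], ev["side"]))
        out[trial_id] = simulate_trial(
            trial_id,
            design.pigeons_in(trial_id),
            spec,
            scene,
            params,
            seed=int((seed * 1000 + k) % (2**31 - 1)),
        )
    return out


def trial_to_marker_frame(trial: SimulatedTrial) -> pd.DataFrame:
    """Long-format motion-capture CSV table: time, pigeon_id, marker, x, y, z."""
    frames = []
    for b in trial.pigeons:
        for name, arr in (("h", trial.head_markers[b]), ("b", trial.back_markers[b])):
            for k in range(arr.shape[1]):
                frames.append(
                    pd.DataFrame(
                        {
                            "time": trial.times,
                            "pigeon_id": b,
                            "marker": f"{name}{k + 1}",
                            "x": arr[:, k, 0],
                            "y": arr[:, k, 1],
                            "z": arr[:, k, 2],
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["time", "pigeon_id", "marker"], kind="stable").reset_index(drop=True)
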