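"""Head-centric geometry: local head frame, foveal axes, and angular projections.

The head-local coordinate system follows the convention used for pigeon
gaze reconstruction: X points to the animal's right (left eye -> right eye),
Y points forward along the local horizon, Z points up.  The local horizon is
defined 30 degrees above the principal axis of the beak, reflecting the
typical standing head posture of a pigeon.  Each fovea projects laterally at
75 degrees azimuth and 0 degrees elevation in this frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Elevation of the local horizon above the beak principal axis (degrees).
HORIZON_OFFSET_DEG = 30.0
#: Lateral projection of each fovea (degrees azimuth; right eye positive).
FOVEA_AZIMUTH_DEG = 75.0
#: Half-width of the rectangular foveal region in azimuth and elevation.
FOVEA_MARGIN_DEG = 10.0

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when calibration keypoints do not define a valid head frame."""


@dataclass(frozen=True)
class HeadCalibration:
    """Per-bird head calibration in the marker-cluster frame (meters).

    ``marker_template`` holds the resting positions of the head markers in
    the same frame as the eye and beak keypoints, so that a rigid fit of the
    template to observed markers carries the keypoints into world space.
    """

    eye_left: np.ndarray
    eye_right: np.ndarray
    beak_tip: np.ndarray
    marker_template: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eye_left", "eye_right", "beak_tip"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "marker_template", np.asarray(self.marker_template, dtype=float))
        if self.marker_template.ndim != 2 or self.marker_template.shape[1] != 3:
            raise ValueError("marker_template must be (n_markers, 3)")
        if self.marker_template.shape[0] < 3:
            raise ValueError("need at least 3 template markers for a rigid fit")
        if np.linalg.norm(self.eye_right - self.eye_left) < 1e-6:
            raise DegenerateGeometryError("eye centers coincide")
        # rigid fit is ill-posed if template markers are (near) collinear
        centered = self.marker_template - self.marker_template.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9:
            raise DegenerateGeometryError("marker template is collinear")

    @property
    def eye_mid(self) -> np.ndarray:
        """Head centroid: midpoint of the two eye centers."""
        return 0.5 * (self.eye_left + self.eye_right)


@dataclass
class HeadPose:
    """Rigid pose of the head-local frame in world coordinates.

    ``orientation`` is a proper rotation matrix mapping head-frame vectors to
    world-frame vectors (columns are the head X/Y/Z axes in world space).
    """

    t: float
    origin: np.ndarray
    orientation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)


@dataclass(frozen=True)
class EgocentricAngles:
    """Direction of a world point in the head frame, degrees.

    azimuth in (-180, 180], 0 = straight ahead, positive to the right;
    elevation in [-90, 90], 0 = local horizon.
    """

    azimuth: float
    elevation: float


@dataclass
class SceneObject:
    """A scene item approximated by its encompassing sphere."""

    id: str
    kind: str  # monitor | hiding_table | conspecific | feeding_area
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = math.radians(angle_deg)
    k = np.asarray(axis, dtype=float)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(a) * kx + (1.0 - math.cos(a)) * (kx @ kx)


def build_local_axes(
    eye_left: np.ndarray,
    eye_right: np.ndarray,
    beak_tip: np.ndarray,
    horizon_offset_deg: float = HORIZON_OFFSET_DEG,
) -> np.ndarray:
    """Head-local axes from the eye centers and beak tip.

    X is the unit vector from the left to the right eye.  The beak principal
    axis (eye midpoint -> beak tip, orthogonalized against X) is rotated
    upward about X by ``horizon_offset_deg`` to give the forward axis Y, so
    the beak points 30 degrees below the local horizon.  Z = X x Y.

    Returns a proper rotation matrix whose columns are X, Y, Z expressed in
    the frame of the inputs.
    """
    eye_left = np.asarray(eye_left, dtype=float)
    eye_right = np.asarray(eye_right, dtype=float)
    beak_tip = np.asarray(beak_tip, dtype=float)

    x = _unit(eye_right - eye_left, "eye-eye axis")
    centroid = 0.5 * (eye_left + eye_right)
    b = beak_tip - centroid
    b_perp = b - np.dot(b, x) * x
    if np.linalg.norm(b_perp) < 1e-9:
        raise DegenerateGeometryError("beak tip collinear with the eye-eye axis")
    beak_axis = _unit(b_perp)
    y = _rotation_about_axis(x, horizon_offset_deg) @ beak_axis
    z = np.cross(x, y)
    axes = np.column_stack([x, y, z])
    return axes


def fit_head_pose(
    observed_markers: np.ndarray,
    calib: HeadCalibration,
    t: float = 0.0,
) -> HeadPose | None:
    """Least-squares rigid fit of the calibration template to observed markers.

    Markers with any non-finite coordinate are dropped; with fewer than three
    valid markers the frame is unresolvable and ``None`` is returned (a
    missing frame, not an error).  The returned pose composes the fitted
    cluster->world transform with the calibration's head-local axes.
    """
    observed = np.asarray(observed_markers, dtype=float)
    valid = np.isfinite(observed).all(axis=1)
    if valid.sum() < 3:
        return None
    obs = observed[valid]
    tmpl = calib.marker_template[valid]

    rot, trans, rms = _kabsch(tmpl, obs)
    axes = build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
    origin = rot @ calib.eye_mid + trans
    return HeadPose(t=t, origin=origin, orientation=rot @ axes, rms_residual=rms)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rigid transform R, t minimizing ||R src + t - dst||, plus RMS."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = dc - rot @ sc
    resid = dst - (src @ rot.T + trans)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rot, trans, rms


def fit_head_poses(
    observed: np.ndarray,
    calib: HeadCalibration,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rigid fit over a series of frames.

    Parameters
    ----------
    observed : (n_frames, n_markers, 3) world coordinates, NaN where missing.
    times : (n_frames,) seconds.

    Returns
    -------
    origins : (n_frames, 3), NaN on unresolved frames
    orientations : (n_frames, 3, 3) world<-head rotations, NaN on unresolved
    valid : (n_frames,) bool
    rms : (n_frames,) fit residuals
    """
    observed = np.asarray(observed, dtype=float)
    n = observed.shape[0]
    origins = np.full((n, 3), np.nan)
    orients = np.full((n, 3, 3), np.nan)
    rms = np.full(n, np.nan)
    marker_ok = np.isfinite(observed).all(axis=2)
    n_ok = marker_ok.sum(axis=1)
    valid = n_ok >= 3

    axes = build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
    tmpl = calib.marker_template
    eye_mid = calib.eye_mid

    full = marker_ok.all(axis=1)
    if full.any():
        obs = observed[full]  # (m, k, 3)
        sc = tmpl.mean(axis=0)
        dc = obs.mean(axis=1)  # (m, 3)
        h = np.einsum("ki,mkj->mij", tmpl - sc, obs - dc[:, None, :])
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(np.einsum("mij,mkj->mik", vt.transpose(0, 2, 1), u.transpose(0, 2, 1))))
        diag = np.zeros((len(d), 3, 3))
        diag[:, 0, 0] = 1.0
        diag[:, 1, 1] = 1.0
        diag[:, 2, 2] = d
        rot = np.einsum("mji,mjk,mlk->mil", vt, diag, u)
        trans = dc - np.einsum("mij,j->mi", rot, sc)
        fitted = np.einsum("mij,kj->mki", rot, tmpl - sc) + dc[:, None, :]
        rms[full] = np.sqrt(np.mean(np.sum((obs - fitted) ** 2, axis=2), axis=1))
        origins[full] = np.einsum("mij,j->mi", rot, eye_mid) + trans
        orients[full] = rot @ axes

    partial = valid & ~full
    for i in np.nonzero(partial)[0]:
        pose = fit_head_pose(observed[i], calib, t=times[i])
        origins[i] = pose.origin
        orients[i] = pose.orientation
        rms[i] = pose.rms_residual
    return origins, orients, valid, rms


# ---------------------------------------------------------------------------
# angular projections


def angles_to_unit(azimuth_deg, elevation_deg) -> np.ndarray:
    """Unit direction in the head frame for given egocentric angles."""
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    return np.stack(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)], axis=-1
    )


def unit_to_angles(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`angles_to_unit`; accepts (..., 3) arrays."""
    d = np.asarray(direction, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    horiz = np.hypot(x, y)
    az = np.degrees(np.arctan2(x, y))
    az = np.where(az <= -180.0, az + 360.0, az)
    el = np.degrees(np.arctan2(z, horiz))
    return az, el


def world_to_head(p: np.ndarray, pose: HeadPose) -> EgocentricAngles:
    """Egocentric angles of a world point as seen from a head pose."""
    d = np.asarray(p, dtype=float) - pose.origin
    if np.linalg.norm(d) < _EPS:
        raise ValueError("point coincides with the head origin")
    local = pose.orientation.T @ d
    az, el = unit_to_angles(local)
    return EgocentricAngles(azimuth=float(az), elevation=float(el))


def head_to_world(a: EgocentricAngles, pose: HeadPose) -> np.ndarray:
    """Unit world direction corresponding to egocentric angles."""
    return pose.orientation @ angles_to_unit(a.azimuth, a.elevation)


def project_points(
    points: np.ndarray,
    origins: np.ndarray,
    orientations: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch egocentric angles of world points across frames.

    ``points`` may be a single (3,) point or per-frame (n, 3) positions;
    returns azimuth and elevation arrays of length n (NaN where the pose is
    missing).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = np.broadcast_to(points, origins.shape)
    d = points - origins
    local = np.einsum("nji,nj->ni", orientations, d)
    return unit_to_angles(local)


def _fovea_axis(side: str) -> np.ndarray:
    if side == "right":
        return angles_to_unit(FOVEA_AZIMUTH_DEG, 0.0)
    if side == "left":
        return angles_to_unit(-FOVEA_AZIMUTH_DEG, 0.0)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def offset_from_fovea(a: EgocentricAngles, side: str) -> float:
    """Great-circle angular distance (degrees) from the foveal axis."""
    u = angles_to_unit(a.azimuth, a.elevation)
    v = _fovea_axis(side)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def is_foveated(
    a: EgocentricAngles | tuple,
    side: str,
    margin_deg: float = FOVEA_MARGIN_DEG,
) -> bool:
    """Whether a direction lies in the rectangular foveal region of one eye.

    The region is 75 +/- margin degrees azimuth (signed by eye) and
    0 +/- margin degrees elevation, with inclusive boundaries — the red
    squares of a foveation heatmap, not a great-circle cone.
    """
    if margin_deg <= 0:
        raise ValueError("margin_deg must be positive")
    az, el = (a.azimuth, a.elevation) if isinstance(a, EgocentricAngles) else a
    center = FOVEA_AZIMUTH_DEG if side == "right" else -FOVEA_AZIMUTH_DEG
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return bool(abs(az - center) <= margin_deg and abs(el) <= margin_deg)


def foveated_mask(
    azimuth: np.ndarray,
    elevation: np.ndarray,
    margin_deg: float = FOVEA_MARGIN_DEG,
) -> np.ndarray:
    """Either-eye rectangular foveation test, vectorized over frames."""
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    in_el = np.abs(el) <= margin_deg
    right = np.abs(az - FOVEA_AZIMUTH_DEG) <= margin_deg
    left = np.abs(az + FOVEA_AZIMUTH_DEG) <= margin_deg
    return (right | left) & in_el
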