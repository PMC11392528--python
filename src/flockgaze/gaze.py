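"""Foveation events, escape/detection latencies, visual-field heatmaps and
before-cue behavioral summaries.

A foveation event is a maximal run of frames in which a scene object sits in
the rectangular foveal region of either eye, after saccade frames have been
removed; runs shorter than 300 ms (a typical pigeon intersaccadic interval)
are discarded as chance gaze crossings.  Detection latency is the start of
the first qualifying foveation on a predator-cue object, ignoring the first
200 ms of the looming period (below pigeon reaction time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ethogram import BehaviorTimeline
from .preprocessing import SaccadeEvent

FOVEATION_MIN_DURATION_S = 0.3
ONSET_EXCLUSION_S = 0.2
BEFORE_CUE_WINDOW_S = 120.0
HEATMAP_CELL_DEG = 5.0
LOGIT_EPS = 1e-4

_EPS = 1e-9


@dataclass(frozen=True)
class PredatorEvent:
    """Timing of one looming-stimulus + model-predator presentation."""

    trial_id: str
    event_index: int
    side: str  # North | South
    t_loom_on: float
    t_loom_off: float
    t_pred_on: float
    t_pred_off: float

    def __post_init__(self) -> None:
        if not (self.t_loom_on < self.t_loom_off <= self.t_pred_on < self.t_pred_off):
            raise ValueError("event times must be ordered loom_on < loom_off <= pred_on < pred_off")

    @property
    def loom_duration(self) -> float:
        return self.t_loom_off - self.t_loom_on


@dataclass(frozen=True)
class FoveationEvent:
    """Interval during which an object stayed inside a foveal region."""

    pigeon_id: str
    object_id: str
    t_start: float
    t_end: float
    eye: str = "either"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class LatencyRecord:
    """Per pigeon x predator event response latencies (s from loom onset)."""

    pigeon_id: str
    trial_id: str
    event_index: int
    side: str
    t_foveate: float | None
    t_run: float | None
    t_fly: float | None
    escaped_before_offset: bool
    response_delay: float | None
    state_at_onset: str = "other"
    distance_to_monitor: float = float("nan")


@dataclass
class VisualFieldHeatmap:
    """Normalized 5x5-degree visual-field occupancy grid for one object.

    ``grid[i, j]`` covers azimuth [-180 + 5i, -180 + 5(i+1)) and elevation
    [-90 + 5j, -90 + 5(j+1)); 72 x 36 cells summing to one when any frame
    contributes.  ``foveal_region_freq`` is the logit of the summed
    frequency inside the two foveal rectangles (75 +/- 10 azimuth,
    0 +/- 10 elevation), clipped to [eps, 1 - eps] before the logit.
    """

    grid: np.ndarray
    n_frames: int
    foveal_freq: float
    foveal_region_freq: float


def extract_foveation_events(
    foveated: np.ndarray,
    times: np.ndarray,
    saccade_frames: np.ndarray,
    valid: np.ndarray,
    rate: float,
    pigeon_id: str,
    object_id: str,
    min_duration_s: float = FOVEATION_MIN_DURATION_S,
    eye: str = "either",
) -> list[FoveationEvent]:
    """Foveation events after saccade removal and the minimum-duration gate.

    Saccade frames are removed before run-finding, so a saccade crossing a
    long foveation splits it and each half is measured against the 300 ms
    minimum on its own.
    """
    keep = np.asarray(foveated, dtype=bool) & ~np.asarray(saccade_frames, dtype=bool) & np.asarray(valid, dtype=bool)
    events: list[FoveationEvent] = []
    n = len(keep)
    dt = 1.0 / rate
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        duration = (j - i) * dt
        if duration >= min_duration_s - _EPS:
            events.append(
                FoveationEvent(
                    pigeon_id=pigeon_id,
                    object_id=object_id,
                    t_start=float(times[i]),
                    t_end=float(times[i]) + duration,
                    eye=eye,
                )
            )
        i = j
    return events


def latency_to_foveate(
    events: list[FoveationEvent],
    pe: PredatorEvent,
    cue_object_ids: set[str] | list[str],
    onset_exclusion_s: float = ONSET_EXCLUSION_S,
) -> float | None:
    """Latency (s from loom onset) of the first qualifying cue foveation.

    Foveations starting inside the first ``onset_exclusion_s`` of the loom
    are skipped (the gaze vector was likely already on the cue by chance).
    If the first qualifying cue foveation only begins after the looming
    stimulus has ended, the observation is excluded (returns None), since
    that foveation targets the model predator rather than the cue.
    """
    cue = set(cue_object_ids)
    starts = sorted(
        ev.t_start
        for ev in events
        if ev.object_id in cue and ev.t_start >= pe.t_loom_on + onset_exclusion_s - _EPS
    )
    if not starts:
        return None
    if starts[0] > pe.t_loom_off + _EPS:
        return None
    return float(starts[0] - pe.t_loom_on)


def escape_latencies(
    timeline: BehaviorTimeline,
    pe: PredatorEvent,
) -> tuple[float | None, float | None, bool]:
    """Onsets of the first running-away and flying intervals after loom
    onset (s from loom onset) and the escape-before-offset flag."""

    def first_onset(label: str) -> float | None:
        after = timeline.times >= pe.t_loom_on - _EPS
        is_label = (timeline.labels == label) & after
        if not is_label.any():
            return None
        idx = np.nonzero(is_label)[0]
        # onset = first frame of the first run after loom onset
        k = idx[0]
        return float(timeline.times[k] - pe.t_loom_on)

    t_run = first_onset("running_away")
    t_fly = first_onset("flying")
    onsets = [t for t in (t_run, t_fly) if t is not None]
    escaped = bool(onsets) and min(onsets) < pe.loom_duration
    return t_run, t_fly, escaped


def build_latency_record(
    pigeon_id: str,
    pe: PredatorEvent,
    t_foveate: float | None,
    t_run: float | None,
    t_fly: float | None,
    escaped_before_offset: bool,
    state_at_onset: str = "other",
    distance_to_monitor: float = float("nan"),
) -> LatencyRecord:
    delay = None
    if t_foveate is not None and t_fly is not None:
        delay = max(0.0, t_fly - t_foveate)
    return LatencyRecord(
        pigeon_id=pigeon_id,
        trial_id=pe.trial_id,
        event_index=pe.event_index,
        side=pe.side,
        t_foveate=t_foveate,
        t_run=t_run,
        t_fly=t_fly,
        escaped_before_offset=escaped_before_offset,
        response_delay=delay,
        state_at_onset=state_at_onset,
        distance_to_monitor=distance_to_monitor,
    )


def _heatmap_bins(az: np.ndarray, el: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed 5-degree bin indices; boundary angles go to the higher
    bin, with the az = 180 / el = 90 edges folded into the last bin."""
    ai = np.floor((az + 180.0) / HEATMAP_CELL_DEG).astype(int)
    ei = np.floor((el + 90.0) / HEATMAP_CELL_DEG).astype(int)
    ai = np.clip(ai, 0, 71)
    ei = np.clip(ei, 0, 35)
    return ai, ei


def visualfield_heatmap(
    azimuth: np.ndarray,
    elevation: np.ndarray,
    include: np.ndarray,
    fovea_azimuth_deg: float = 75.0,
    margin_deg: float = 10.0,
) -> VisualFieldHeatmap:
    """Bin object directions into the 72 x 36 visual-field grid.

    ``include`` selects the contributing frames (typically: inside the
    loom-to-first-escape window, valid pose, not a saccade frame).  Counts
    are normalized to unit sum; the foveal-region frequency is summed over
    the two rectangles and logit-transformed after clipping.
    """
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    use = np.asarray(include, dtype=bool) & np.isfinite(az) & np.isfinite(el)
    grid = np.zeros((72, 36))
    n = int(use.sum())
    if n > 0:
        ai, ei = _heatmap_bins(az[use], el[use])
        np.add.at(grid, (ai, ei), 1.0)
        grid /= grid.sum()
        in_el = np.abs(el[use]) <= margin_deg
        in_az = (np.abs(az[use] - fovea_azimuth_deg) <= margin_deg) | (
            np.abs(az[use] + fovea_azimuth_deg) <= margin_deg
        )
        fov = float(np.mean(in_az & in_el))
    else:
        fov = float("nan")
    clipped = min(max(fov, LOGIT_EPS), 1.0 - LOGIT_EPS) if n > 0 else float("nan")
    logit = math.log(clipped / (1.0 - clipped)) if n > 0 else float("nan")
    return VisualFieldHeatmap(grid=grid, n_frames=n, foveal_freq=fov, foveal_region_freq=logit)


def heatmap_window(
    pe: PredatorEvent,
    t_run: float | None,
    t_fly: float | None,
) -> tuple[float, float]:
    """Sampling window for the visual-field heatmap: looming period
    truncated at the first escape response of either kind."""
    onsets = [pe.t_loom_on + t for t in (t_run, t_fly) if t is not None]
    end = min([pe.t_loom_off] + onsets)
    return pe.t_loom_on, end


@dataclass
class BeforeCueMetrics:
    """Baseline vigilance/feeding summaries over the 2 min before the cue."""

    pigeon_id: str
    trial_id: str
    event_index: int
    prop_head_up: float
    peck_rate: float
    saccade_rate: float
    prop_foveating_monitor: float
    prop_foveating_conspecific: float
    n_valid_frames: int


def before_cue_metrics(
    timeline: BehaviorTimeline,
    monitor_events: list[FoveationEvent],
    conspecific_events: list[FoveationEvent],
    saccades: list[SaccadeEvent],
    pe: PredatorEvent,
    window_s: float = BEFORE_CUE_WINDOW_S,
) -> BeforeCueMetrics:
    """Behavioral summaries over [t_loom_on - window, t_loom_on).

    Proportions of time are computed over valid frames; rates are counts per
    second of window.  Foveation proportions use the qualifying foveation
    events (post saccade-removal, >= 300 ms) clipped to the window.
    """
    t0, t1 = pe.t_loom_on - window_s, pe.t_loom_on
    in_win = (timeline.times >= t0 - _EPS) & (timeline.times < t1 - _EPS)
    labels = timeline.labels[in_win]
    valid = labels != "missing"
    n_valid = int(valid.sum())
    prop_head_up = float(np.mean(labels[valid] == "head_up")) if n_valid else float("nan")

    pecks = np.asarray(timeline.peck_times)
    n_pecks = int(np.sum((pecks >= t0) & (pecks < t1)))
    n_sacc = sum(1 for s in saccades if t0 <= s.t_start < t1)

    def event_time(events: list[FoveationEvent]) -> float:
        total = 0.0
        for ev in events:
            total += max(0.0, min(ev.t_end, t1) - max(ev.t_start, t0))
        return total

    span = float(np.sum(in_win & (timeline.labels != "missing"))) / timeline.rate
    prop_mon = event_time(monitor_events) / span if span > 0 else float("nan")
    prop_con = event_time(conspecific_events) / span if span > 0 else float("nan")
    return BeforeCueMetrics(
        pigeon_id=timeline.pigeon_id,
        trial_id=pe.trial_id,
        event_index=pe.event_index,
        prop_head_up=prop_head_up,
        peck_rate=n_pecks / window_s,
        saccade_rate=n_sacc / window_s,
        prop_foveating_monitor=min(1.0, prop_mon) if np.isfinite(prop_mon) else prop_mon,
        prop_foveating_conspecific=min(1.0, prop_con) if np.isfinite(prop_con) else prop_con,
        n_valid_frames=n_valid,
    )


def state_at_onset(timeline: BehaviorTimeline, pe: PredatorEvent) -> str:
    """Behavioral state at loom onset collapsed to head_up/feeding/other."""
    idx = int(np.searchsorted(timeline.times, pe.t_loom_on - _EPS))
    idx = min(idx, len(timeline.times) - 1)
    label = timeline.labels[idx]
    if label in ("head_up", "feeding"):
        return str(label)
    return "other"
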