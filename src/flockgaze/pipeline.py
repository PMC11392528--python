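"""End-to-end pipeline: markers -> head poses -> ethogram -> gaze events ->
latency tables -> contagion statistics.

``process_trial`` handles one flock session; ``run_pipeline`` runs the whole
synthetic design and writes tidy output tables plus the permutation-test
results.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import contagion as ctg
from . import ethogram as eth
from . import gaze
from . import geometry, preprocessing
from .gaze import BeforeCueMetrics, LatencyRecord, PredatorEvent, VisualFieldHeatmap
from .geometry import HeadCalibration
from .io import RunConfig
from .preprocessing import PoseSeries, SaccadeEvent
from .synthetic import (
    BACK_CENTER_ABOVE_BODY,
    ExperimentDesign,
    Scene,
    build_design,
    default_head_calibration,
    simulate_scene,
    simulate_tracks,
)


@dataclass
class PigeonTrialResult:
    """Everything derived for one bird in one trial."""

    pigeon_id: str
    series: PoseSeries
    saccades: list[SaccadeEvent]
    timeline: eth.BehaviorTimeline
    foveation_events: dict[str, list[gaze.FoveationEvent]]
    latency_records: list[LatencyRecord]
    before_cue: list[BeforeCueMetrics]
    heatmaps: dict[tuple[int, str], VisualFieldHeatmap]


@dataclass
class TrialResult:
    trial_id: str
    events: list[PredatorEvent]
    pigeons: dict[str, PigeonTrialResult]

    def latency_table(self) -> pd.DataFrame:
        rows = []
        for pr in self.pigeons.values():
            for rec in pr.latency_records:
                rows.append(dataclasses.asdict(rec))
        return pd.DataFrame(rows)


def _pose_series_from_markers(
    pigeon_id: str,
    times: np.ndarray,
    head_markers: np.ndarray,
    back_markers: np.ndarray,
    calib: HeadCalibration,
    config: RunConfig,
    rate: float,
) -> PoseSeries:
    """Rigid-fit head poses, derive the body centroid, and condition the
    series (implausible-motion removal, gap fill, smoothing)."""
    origins, orients, valid, _rms = geometry.fit_head_poses(head_markers, calib, times)
    quats = np.tile([0.0, 0.0, 0.0, 1.0], (len(times), 1))
    if valid.any():
        quats[valid] = Rotation.from_matrix(orients[valid]).as_quat()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        back_center = np.nanmean(back_markers, axis=1)
    body = back_center - np.array([0.0, 0.0, BACK_CENTER_ABOVE_BODY])
    series = PoseSeries(
        pigeon_id=pigeon_id,
        times=times,
        origins=origins,
        quats=quats,
        valid=valid,
        body_centroid=body,
        rate=rate,
    )
    series = preprocessing.remove_implausible(series)
    series = preprocessing.fill_gaps(series, max_gap_s=config.gap_fill_max_s)
    if config.smooth_window_s * rate > 1.5:
        series = preprocessing.smooth_series(series, window_s=config.smooth_window_s)
    return series


def _active_side_per_frame(times: np.ndarray, events: list[PredatorEvent]) -> list[str]:
    """Side of the most recently (or next) presented monitor per frame."""
    sides = np.empty(len(times), dtype=object)
    sides[:] = events[0].side
    for ev in events:
        sides[times >= ev.t_loom_on] = ev.side
    return sides


def process_trial(
    trial_id: str,
    times: np.ndarray,
    head_markers: dict[str, np.ndarray],
    back_markers: dict[str, np.ndarray],
    events: list[PredatorEvent],
    calib: HeadCalibration,
    scene: Scene,
    config: RunConfig,
    rate: float = 60.0,
) -> TrialResult:
    """Run the full per-trial chain for every bird of a flock session."""
    pigeons = sorted(head_markers)
    series: dict[str, PoseSeries] = {}
    feats: dict[str, dict] = {}

    for pid in pigeons:
        s = _pose_series_from_markers(
            pid, times, head_markers[pid], back_markers[pid], calib, config, rate
        )
        series[pid] = s
        mats = s.orientation_matrices()
        pitch, roll = eth.head_pitch_roll(mats)
        axes = geometry.build_local_axes(calib.eye_left, calib.eye_right, calib.beak_tip)
        beak_head = axes.T @ (calib.beak_tip - calib.eye_mid)
        beak = s.origins + np.einsum("nij,j->ni", np.nan_to_num(mats), beak_head)
        beak[~s.valid] = np.nan
        fwd = mats[:, :, 1]
        feats[pid] = {
            "mats": mats,
            "pitch": pitch,
            "roll": roll,
            "beak": beak,
            "fwd": fwd,
            "body": s.body_centroid,
            "speed": preprocessing.translational_speed(s.body_centroid, rate),
        }

    # courting needs the whole flock at once
    courting, courted = eth.detect_courting(
        {p: feats[p]["pitch"] for p in pigeons},
        {p: np.nan_to_num(feats[p]["body"], nan=1e6) for p in pigeons},
        {p: np.nan_to_num(feats[p]["fwd"]) for p in pigeons},
        times,
        rate,
    )

    side_per_frame = _active_side_per_frame(times, events)
    monitor_xyz = {s_: scene.monitor(s_).center for s_ in ("North", "South")}

    results: dict[str, PigeonTrialResult] = {}
    for pid in pigeons:
        s = series[pid]
        f = feats[pid]
        head_z = s.origins[:, 2]
        body_z = f["body"][:, 2]
        head_down = eth.classify_head_down(head_z, body_z)

        pecks = eth.detect_pecks(
            f["beak"][:, 2], f["pitch"], times, height_threshold=config.peck_beak_height_m
        )
        feeding = eth.intervals_to_mask(
            times, eth.feeding_intervals(pecks, max_gap_s=config.feeding_max_gap_s)
        )
        to_head = s.origins - f["body"]
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ni,ni->n", f["fwd"], to_head) / (
                np.linalg.norm(f["fwd"], axis=1) * np.linalg.norm(to_head, axis=1)
            )
        facing = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        beak_body = np.linalg.norm(f["beak"] - f["body"], axis=1)
        grooming = eth.detect_grooming(f["pitch"], f["roll"], facing, beak_body, head_z, body_z)

        dist_mon = np.array(
            [
                np.linalg.norm(f["body"][i] - monitor_xyz[side_per_frame[i]])
                for i in range(len(times))
            ]
        )
        court_mask = courting[pid] | courted[pid]
        running = eth.detect_running_away(f["speed"], dist_mon, court_mask, rate)
        flying = eth.detect_flying(f["speed"], rate)

        timeline = eth.compose_ethogram(
            pid, times, s.valid, flying, running, court_mask, grooming, feeding, head_down,
            pecks, rate,
        )

        saccades = preprocessing.detect_saccades(
            s,
            speed_threshold=config.saccade_speed_deg_s,
            min_duration_s=config.saccade_min_duration_s,
            min_amplitude_deg=config.saccade_min_amplitude_deg,
        )
        sacc_mask = preprocessing.saccade_mask(s, saccades)

        # egocentric angles of the objects of interest
        angles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for obj in scene.objects:
            if obj.kind in ("monitor", "hiding_table"):
                angles[obj.id] = geometry.project_points(obj.center, s.origins, f["mats"])

        others = [q for q in pigeons if q != pid]
        consp_fov = np.zeros(len(times), dtype=bool)
        nn_az = np.full(len(times), np.nan)
        nn_el = np.full(len(times), np.nan)
        if others:
            dists = np.stack(
                [np.linalg.norm(feats[q]["body"] - f["body"], axis=1) for q in others], axis=1
            )
            nearest = np.nanargmin(np.where(np.isfinite(dists), dists, np.inf), axis=1)
            for k, q in enumerate(others):
                head_q = series[q].origins
                az, el = geometry.project_points(head_q, s.origins, f["mats"])
                m = geometry.foveated_mask(az, el, config.fovea_margin_deg)
                consp_fov |= np.where(np.isfinite(az), m, False)
                sel = nearest == k
                nn_az[sel] = az[sel]
                nn_el[sel] = el[sel]

        fov_events: dict[str, list[gaze.FoveationEvent]] = {}
        for obj_id, (az, el) in angles.items():
            mask = geometry.foveated_mask(az, el, config.fovea_margin_deg)
            fov_events[obj_id] = gaze.extract_foveation_events(
                mask, times, sacc_mask, s.valid, rate, pid, obj_id,
                min_duration_s=config.foveation_min_duration_s,
            )
        fov_events["conspecific"] = gaze.extract_foveation_events(
            consp_fov, times, sacc_mask, s.valid, rate, pid, "conspecific",
            min_duration_s=config.foveation_min_duration_s,
        )

        monitor_events = fov_events["monitor_North"] + fov_events["monitor_South"]
        records: list[LatencyRecord] = []
        metrics: list[BeforeCueMetrics] = []
        heatmaps: dict[tuple[int, str], VisualFieldHeatmap] = {}
        for ev in events:
            cue_ids = {f"monitor_{ev.side}", f"table_{ev.side}"}
            cue_events = [e for oid in cue_ids for e in fov_events[oid]]
            t_fov = gaze.latency_to_foveate(
                cue_events, ev, cue_ids, onset_exclusion_s=config.onset_exclusion_s
            )
            t_run, t_fly, escaped = gaze.escape_latencies(timeline, ev)
            onset_idx = min(
                int(np.searchsorted(times, ev.t_loom_on - 1e-9)), len(times) - 1
            )
            dist = float(np.linalg.norm(f["body"][onset_idx] - monitor_xyz[ev.side]))
            records.append(
                gaze.build_latency_record(
                    pid, ev, t_fov, t_run, t_fly, escaped,
                    state_at_onset=gaze.state_at_onset(timeline, ev),
                    distance_to_monitor=dist,
                )
            )
            metrics.append(
                gaze.before_cue_metrics(
                    timeline, monitor_events, fov_events["conspecific"], saccades, ev,
                    window_s=config.before_cue_window_s,
                )
            )
            w0, w1 = gaze.heatmap_window(ev, t_run, t_fly)
            in_win = (times >= w0 - 1e-9) & (times < w1 - 1e-9)
            include = in_win & s.valid & ~sacc_mask
            other = "South" if ev.side == "North" else "North"
            for label, (az, el) in (
                ("active_monitor", angles[f"monitor_{ev.side}"]),
                ("other_monitor", angles[f"monitor_{other}"]),
                ("nearest_conspecific", (nn_az, nn_el)),
            ):
                heatmaps[(ev.event_index, label)] = gaze.visualfield_heatmap(
                    az, el, include,
                    fovea_azimuth_deg=config.fovea_azimuth_deg,
                    margin_deg=config.fovea_margin_deg,
                )

        results[pid] = PigeonTrialResult(
            pigeon_id=pid,
            series=s,
            saccades=saccades,
            timeline=timeline,
            foveation_events=fov_events,
            latency_records=records,
            before_cue=metrics,
            heatmaps=heatmaps,
        )
    return TrialResult(trial_id=trial_id, events=events, pigeons=results)


def count_agreement_icc(truth_counts, pipeline_counts) -> float:
    """Intraclass correlation (two-way random, absolute agreement, single
    rater) between ground-truth and recovered event counts.

    Exact agreement across all units yields ICC = 1 by definition (the
    ANOVA estimator is 0/0 there).
    """
    import pingouin as pg

    a = np.asarray(truth_counts, dtype=float)
    b = np.asarray(pipeline_counts, dtype=float)
    if len(a) != len(b):
        raise ValueError("count vectors must align")
    if np.array_equal(a, b):
        return 1.0
    frame = pd.DataFrame(
        {
            "target": np.tile(np.arange(len(a)), 2),
            "rater": ["truth"] * len(a) + ["pipeline"] * len(b),
            "count": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(frame, targets="target", raters="rater", ratings="count")
    return float(icc.loc[icc["Type"] == "ICC2", "ICC"].iloc[0])


# ---------------------------------------------------------------------------
# whole-design orchestration


def latency_sets_from_table(
    table: pd.DataFrame,
    design: ExperimentDesign | None = None,
    response: str = "fly",
) -> list[ctg.EventLatencySet]:
    """Per-event latency sets for the contagion test.

    ``response`` selects flight latencies ('fly') or escape latencies
    ('escape': the earlier of run and fly).  Birds without the response are
    excluded from the event's set.  Without a design table, the session and
    flock are parsed from the trial id (e.g. 'S3B' -> session S3, flock B).
    """
    meta = None
    if design is not None:
        meta = design.events.set_index(["trial_id", "event_index"])
    out = []
    for (trial_id, ev_idx), grp in table.groupby(["trial_id", "event_index"]):
        if response == "fly":
            lat = grp["t_fly"]
        elif response == "escape":
            lat = grp[["t_run", "t_fly"]].min(axis=1, skipna=True)
        else:
            raise ValueError("response must be 'fly' or 'escape'")
        keep = lat.notna()
        if keep.sum() == 0:
            continue
        if meta is not None:
            row = meta.loc[(trial_id, ev_idx)]
            session, flock = f"S{row['session']}", str(row["flock"])
        else:
            session, flock = str(trial_id)[:-1], str(trial_id)[-1]
        out.append(
            ctg.EventLatencySet(
                trial_id=session,
                side=str(grp["side"].iloc[0]),
                flock_id=flock,
                latencies=lat[keep].to_numpy(dtype=float),
                distances=grp.loc[keep, "distance_to_monitor"].to_numpy(dtype=float),
            )
        )
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate the design, process every trial, and run the contagion tests.

    Returns a bundle with the latency table (one row per pigeon x event),
    before-cue metrics, heatmap summaries, and the four permutation results
    (escape/fly x with/without distance control); writes tidy CSV/JSON
    artifacts when ``out_dir`` is given.
    """
    design = build_design(
        config.seed,
        n_pigeons=config.n_pigeons,
        flock_size=config.flock_size,
        n_sessions=config.n_sessions,
    )
    scene = simulate_scene()
    calib = default_head_calibration()
    trials = simulate_tracks(design, scene, config.seed, config.generator)

    latency_frames = []
    before_rows = []
    heat_rows = []
    for trial_id, trial in trials.items():
        res = process_trial(
            trial_id, trial.times, trial.head_markers, trial.back_markers,
            trial.events, calib, scene, config, rate=trial.rate,
        )
        latency_frames.append(res.latency_table())
        for pr in res.pigeons.values():
            before_rows.extend(dataclasses.asdict(m) for m in pr.before_cue)
            for (ev_idx, label), hm in pr.heatmaps.items():
                heat_rows.append(
                    {
                        "trial_id": trial_id,
                        "pigeon_id": pr.pigeon_id,
                        "event_index": ev_idx,
                        "object": label,
                        "n_frames": hm.n_frames,
                        "foveal_freq": hm.foveal_freq,
                        "foveal_region_logit": hm.foveal_region_freq,
                    }
                )

    latency_table = pd.concat(latency_frames, ignore_index=True)
    before_table = pd.DataFrame(before_rows)
    heat_table = pd.DataFrame(heat_rows)

    contagion_results = {}
    contagion_null: dict[str, np.ndarray] = {}
    for response in ("escape", "fly"):
        sets = latency_sets_from_table(latency_table, design, response)
        pairs, _un = ctg.pair_events([s for s in sets if s.n >= 2])
        for control in (False, True):
            key = f"{response}_{'controlled' if control else 'raw'}"
            try:
                r = ctg.aggregate_contagion(
                    pairs, n_perm=config.n_perm, rng_seed=config.seed, control_distance=control
                )
                contagion_results[key] = {
                    "observed_mean_gap": r.observed_mean_gap,
                    "p_value": r.p_value,
                    "n_perm": r.n_perm,
                    "n_pairs": r.n_pairs,
                    "null_mean": float(np.mean(r.null_gaps)),
                }
                contagion_null[key] = r.null_gaps
            except ValueError as exc:
                contagion_results[key] = {"error": str(exc)}

    bundle = {
        "design": design,
        "latency_table": latency_table,
        "before_cue_table": before_table,
        "heatmap_table": heat_table,
        "contagion": contagion_results,
        "contagion_null": contagion_null,
        "config": config,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        latency_table.to_csv(out / "latencies.csv", index=False)
        before_table.to_csv(out / "before_cue.csv", index=False)
        heat_table.to_csv(out / "heatmaps.csv", index=False)
        (out / "contagion.json").write_text(json.dumps(contagion_results, indent=2))
        if contagion_null:
            pd.DataFrame(contagion_null).to_csv(out / "contagion_null.csv", index=False)
        log = {
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_trials": design.n_trials,
            "n_events": design.n_events,
            "n_observations": design.n_observations,
            "thresholds": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if isinstance(v, (int, float))
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def report(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Summary figures: latency histograms, foveal-frequency summaries and
    permutation null distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lat = bundle["latency_table"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, col, color in zip(axes, ("t_foveate", "t_run", "t_fly"), ("g", "b", "r")):
        vals = lat[col].dropna()
        if len(vals):
            ax.hist(vals, bins=24, color=color, alpha=0.7)
        ax.axvline(10.0, ls="--", c="k", lw=0.8)
        ax.set_xlabel(f"{col} (s)")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    p = out / "latency_histograms.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    heat = bundle["heatmap_table"]
    if len(heat):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        heat.boxplot(column="foveal_region_logit", by="object", ax=ax)
        ax.set_ylabel("logit foveal-region frequency")
        fig.suptitle("")
        fig.tight_layout()
        p = out / "foveal_frequency.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    keys = ["escape_raw", "escape_controlled", "fly_raw", "fly_controlled"]
    nulls = bundle.get("contagion_null", {})
    for ax, key in zip(axes.ravel(), keys):
        res = bundle["contagion"].get(key, {})
        if "p_value" in res:
            ax.set_title(f"{key}: p = {res['p_value']:.4g}")
            if key in nulls:
                ax.hist(nulls[key], bins=40, alpha=0.6)
            ax.axvline(res["observed_mean_gap"], ls="--", c="k")
            ax.set_xlabel("mean time gap (s)")
        else:
            ax.set_title(f"{key}: unavailable")
            ax.text(0.5, 0.5, res.get("error", "no data"), ha="center", va="center")
    fig.tight_layout()
    p = out / "contagion_null.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
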