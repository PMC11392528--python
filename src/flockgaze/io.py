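"""Readers, writers and run configuration.

Motion-capture input is the long-format CSV export convention:
``time, pigeon_id, marker, x, y, z`` with one row per marker per frame and
empty cells where a marker was not reconstructed.  Head markers are named
``h1..h4`` and back markers ``b1..b4``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GeneratorParams

HEAD_MARKERS = ("h1", "h2", "h3", "h4")
BACK_MARKERS = ("b1", "b2", "b3", "b4")


@dataclass
class RunConfig:
    """All thresholds and run settings of the pipeline.

    Defaults are the constants of the underlying behavioral definitions:
    the 75 degree foveal azimuth with a +/-10 degree margin, a 30 degree
    beak-to-horizon offset, 300 ms minimum foveation, a 200 ms onset
    exclusion, the 5 degree / 50 ms / 60 deg/s saccade rule, the 4 cm / 6 s
    pecking and feeding rules, the 0.6 and 2 m/s locomotion gates with the
    0.2 m/s radial criterion and the 70 ms duration filter, 5 degree
    heatmap cells, a 120 s before-cue window, and 10,000 permutations.
    """

    seed: int = 0
    out_dir: str = "results"
    n_perm: int = 10_000
    # geometry / gaze
    fovea_azimuth_deg: float = 75.0
    fovea_margin_deg: float = 10.0
    horizon_offset_deg: float = 30.0
    foveation_min_duration_s: float = 0.3
    onset_exclusion_s: float = 0.2
    heatmap_cell_deg: float = 5.0
    before_cue_window_s: float = 120.0
    # saccades
    saccade_speed_deg_s: float = 60.0
    saccade_min_duration_s: float = 0.05
    saccade_min_amplitude_deg: float = 5.0
    # ethogram
    peck_beak_height_m: float = 0.04
    feeding_max_gap_s: float = 6.0
    run_speed_m_s: float = 0.6
    run_radial_speed_m_s: float = 0.2
    fly_speed_m_s: float = 2.0
    locomotion_min_duration_s: float = 0.07
    # preprocessing
    gap_fill_max_s: float = 0.2
    smooth_window_s: float = 0.1
    # synthetic generator (study conditions)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    n_sessions: int = 6
    n_pigeons: int = 20
    flock_size: int = 10

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.type == "float" and getattr(self, f.name) <= 0 and f.name != "seed":
                raise ValueError(f"threshold {f.name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorParams(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class MarkerSeries:
    """Per-bird marker arrays decoded from a motion-capture CSV."""

    pigeon_id: str
    times: np.ndarray
    head: np.ndarray  # (n, 4, 3), NaN where missing
    back: np.ndarray

    @property
    def head_loss(self) -> float:
        """Fraction of head marker cells missing."""
        return float(np.mean(~np.isfinite(self.head[..., 0])))


def read_markers(path_or_frame: str | Path | pd.DataFrame) -> dict[str, MarkerSeries]:
    """Load a long-format marker CSV into per-bird arrays.

    Validates the schema and strictly increasing per-bird timestamps;
    missing coordinate cells become NaN (masked frames downstream).
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    required = {"time", "pigeon_id", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")

    out: dict[str, MarkerSeries] = {}
    for pid, grp in df.groupby("pigeon_id", sort=True):
        for marker, sub in grp.groupby("marker"):
            tvals = sub["time"].to_numpy()
            if np.any(np.diff(tvals) <= 0):
                raise ValueError(f"non-monotone timestamps for {pid}/{marker}")
        times = np.sort(grp["time"].unique())
        index = {t: i for i, t in enumerate(times)}
        head = np.full((len(times), len(HEAD_MARKERS), 3), np.nan)
        back = np.full((len(times), len(BACK_MARKERS), 3), np.nan)
        for marker, sub in grp.groupby("marker"):
            if marker in HEAD_MARKERS:
                arr, k = head, HEAD_MARKERS.index(marker)
            elif marker in BACK_MARKERS:
                arr, k = back, BACK_MARKERS.index(marker)
            else:
                raise ValueError(f"unknown marker label {marker!r}")
            rows = sub["time"].map(index).to_numpy()
            arr[rows, k, :] = sub[["x", "y", "z"]].to_numpy()
        out[str(pid)] = MarkerSeries(pigeon_id=str(pid), times=times, head=head, back=back)
    return out


def loss_report(series: dict[str, MarkerSeries]) -> pd.DataFrame:
    """Per-bird fraction of missing marker cells."""
    rows = [
        {
            "pigeon_id": pid,
            "head_loss": ms.head_loss,
            "back_loss": float(np.mean(~np.isfinite(ms.back[..., 0]))),
        }
        for pid, ms in series.items()
    ]
    return pd.DataFrame(rows)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
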