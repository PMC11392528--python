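"""Shared fixtures: a small zero-noise simulated trial and its processed
pipeline result, reused across the gaze/ethogram/pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from flockgaze.io import RunConfig
from flockgaze.pipeline import process_trial
from flockgaze.synthetic import GeneratorParams, simulate_scene, simulate_trial


@pytest.fixture(scope="session")
def scene():
    return simulate_scene()


@pytest.fixture(scope="session")
def zero_noise_trial(scene):
    """One flock session, 10 birds, both events, no marker noise, with
    shortened feeding periods to keep the suite fast."""
    params = GeneratorParams(
        noise_sd=0.0, before_cue_s=30.0, inter_event_s=30.0, tail_s=5.0
    )
    return simulate_trial(
        "S1A",
        [f"p{i:02d}" for i in range(10)],
        [(1, "North"), (2, "South")],
        scene,
        params,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_noise_config():
    """Pipeline settings matched to noise-free input: smoothing disabled
    (window below one sample), before-cue window matching the short trial."""
    return RunConfig(smooth_window_s=1e-6, before_cue_window_s=30.0)


@pytest.fixture(scope="session")
def processed_trial(zero_noise_trial, scene, zero_noise_config):
    tr = zero_noise_trial
    return process_trial(
        tr.trial_id,
        tr.times,
        tr.head_markers,
        tr.back_markers,
        tr.events,
        tr.calibration,
        scene,
        zero_noise_config,
        rate=tr.rate,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
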