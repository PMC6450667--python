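import numpy as np
import pandas as pd
import pytest

from mnemonet.synthgen import (
    StudyDesign, BehavioralParams, NeuralParams,
    generate_design, generate_behavior, generate_timeseries,
)
from mnemonet import scoring

DEFAULT_THRESHOLDS = {"color": 57.0, "scene": 30.0}


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign.small()


@pytest.fixture(scope="session")
def full_design():
    return StudyDesign.full()


@pytest.fixture(scope="session")
def behaved_trials(small_design):
    trials = generate_design(small_design, seed=11)
    return generate_behavior(trials, BehavioralParams(), seed=12)


@pytest.fixture(scope="session")
def scored_trials(behaved_trials):
    return scoring.score_trials(behaved_trials, DEFAULT_THRESHOLDS)


@pytest.fixture(scope="session")
def one_subject_timeseries(small_design, scored_trials):
    sub = scored_trials[scored_trials["subject"] == 1].reset_index(drop=True)
    nparams = NeuralParams(seed=77)
    ts = generate_timeseries(sub, nparams, small_design)
    ts.trials = sub
    return ts


def make_error_sample(rng, n, k, gamma):
    """Draw n wrapped errors (degrees) from the von Mises + uniform mixture."""
    guess = rng.random(n) < gamma
    vm = np.rad2deg(rng.vonmises(0.0, k, size=n))
    uni = rng.uniform(-180.0, 180.0, size=n)
    return np.where(guess, uni, vm)


def make_trials_frame(n, targets_seed=0):
    """Bare trial table (targets + onsets) usable by generate_behavior."""
    rng = np.random.default_rng(targets_seed)
    return pd.DataFrame({
        "subject": 1,
        "block": 1,
        "trial": np.arange(1, n + 1),
        "run": 1,
        "panorama": 1,
        "valence": 0,
        "target_color_deg": rng.uniform(0, 360, n),
        "target_scene_deg": rng.uniform(0, 360, n),
        "onset_encoding_s": np.arange(n) * 7.0,
        "onset_remember_s": 1e6 + np.arange(n) * 20.0,
    })
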