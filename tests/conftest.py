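"""Shared fixtures: small deterministic synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

import motistate as ms
from motistate import config as cfg
from motistate import features as feat
from motistate import labeling


def small_mouse_config(**kw):
    """An 8-channel, short-session configuration for stream-based tests."""
    defaults = dict(mouse_id="t1", n_sessions=2, trials_per_session=60,
                    seed=7, probe=ms.ProbeConfig(n_channels=8),
                    landmark_depth_mm=0.10, dipole_depth_mm=0.06)
    defaults.update(kw)
    return ms.MouseConfig(**defaults)


@pytest.fixture(scope="session")
def small_mouse():
    """One mouse, 2 sessions x 60 trials, full streams on a small probe."""
    return ms.gen_dataset([small_mouse_config()])["t1"]


@pytest.fixture(scope="session")
def small_features(small_mouse):
    return ms.extract_features({"t1": small_mouse})


@pytest.fixture(scope="session")
def labeled_session_table():
    """Feature-level dataset large enough for state labeling/decoding:
    one mouse, 7 sessions x 500 trials via the fast feature path."""
    c = ms.MouseConfig(mouse_id="m1", n_sessions=7, trials_per_session=500,
                       seed=11)
    tl = ms.gen_state_timeline(c)
    tr = ms.gen_trials(tl, c)
    table = ms.gen_feature_table(tl, tr, c, rng=5)
    table["mouse"] = "m1"
    labels = labeling.label_states(table)
    smoothed = feat.smooth_per_session(
        table, list(cfg.NONPERFORMANCE_VARS) + ["correctness"])
    return table, smoothed, labels
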