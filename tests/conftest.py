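import copy
import dataclasses

import numpy as np
import pytest

from henstrack import synthetic_video as sv
from henstrack import tracker as tk
from henstrack.geometry import RotatedRect


@pytest.fixture(scope="session")
def static_scene():
    """A short noise-bearing scene with a motionless target."""
    cfg = dataclasses.replace(sv.PRESETS["linear"], n_frames=6, speed=0.0, seed=3)
    return sv.generate(cfg)


@pytest.fixture(scope="session")
def _static_state_master(static_scene):
    frames, truth, _ = static_scene
    return tk.initialize(frames[0], truth[0], tk.TrackerConfig(), seed=3)


@pytest.fixture
def static_state(_static_state_master):
    """A fresh (deep-copied) initialized tracker state per test."""
    return copy.deepcopy(_static_state_master)


@pytest.fixture(scope="session")
def textured_frame():
    """A small textured frame with a reference box for sampling tests."""
    rng = np.random.default_rng(11)
    from scipy.ndimage import gaussian_filter
    frame = 120.0 + 60.0 * gaussian_filter(rng.standard_normal((60, 80)), 1.5)
    ref = RotatedRect(40.0, 30.0, 16.0, 12.0, 20.0)
    return np.clip(frame, 0, 255), ref
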