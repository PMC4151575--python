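"""Shared fixtures: camera, rendered scenes and background sessions.

Expensive artefacts (background estimation, reference renders) are session
scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from fesgrasp.camera_geometry import CameraModel
from fesgrasp.hand_track import build_table_model
from fesgrasp.plane_detect import RansacConfig, estimate_background
from fesgrasp.scene_sim import NoiseSpec, SceneSpec, render_background_frames

STUDY_SIGMA = 3.0  # mm depth noise used throughout the synthetic evaluation


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def noisy_table(cam):
    """TableModel from a background session at the study noise level."""
    spec = SceneSpec(noise=NoiseSpec(STUDY_SIGMA, True))
    frames = render_background_frames(spec, cam, n_frames=15, seed=11)
    bg = estimate_background(frames, cam, RansacConfig(seed=11), n_frames=15)
    return build_table_model(bg, cam)


@pytest.fixture(scope="session")
def noiseless_table(cam):
    spec = SceneSpec()
    frames = render_background_frames(spec, cam, n_frames=10, seed=0)
    bg = estimate_background(frames, cam, RansacConfig(seed=0), n_frames=10)
    return build_table_model(bg, cam)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
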