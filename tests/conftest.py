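"""Shared fixtures: reference synthetic sequences and cached pipeline runs.

The heavy fixtures are session-scoped: the clean and artifact reference
sweeps (100 frames, 256 px, 1024 px texture) and the occlusion fixture
(80 frames with a 5-frame full occlusion) are generated once and their
pipeline results reused across test modules.
"""
from __future__ import annotations

import numpy as np
import pytest

from fetomosaic import PipelineConfig, make_reference_sequence
from fetomosaic.pipeline import run_sequence

REF_SEED = 11
N_REF_FRAMES = 100
FRAME_SIZE = 256
TEXTURE_SIZE = 1024
OCCLUSION = (45, 49, "full")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_seq():
    """Artifact-free 100-frame reference sweep."""
    return make_reference_sequence(
        n_frames=N_REF_FRAMES,
        frame_size=FRAME_SIZE,
        texture_size=TEXTURE_SIZE,
        vignette_strength=0.0,
        turbidity=0.0,
        laser_dot=False,
        seed=REF_SEED,
    )


@pytest.fixture(scope="session")
def artifact_seq():
    """Same trajectory with default vignetting, turbidity and laser dot."""
    return make_reference_sequence(
        n_frames=N_REF_FRAMES,
        frame_size=FRAME_SIZE,
        texture_size=TEXTURE_SIZE,
        seed=REF_SEED,
    )


@pytest.fixture(scope="session")
def occlusion_seq():
    """Artifact sequence with a 5-frame full occlusion."""
    return make_reference_sequence(
        n_frames=80,
        frame_size=FRAME_SIZE,
        texture_size=TEXTURE_SIZE,
        occlusion_spec=[OCCLUSION],
        seed=REF_SEED,
    )


@pytest.fixture(scope="session")
def clean_result(clean_seq, config):
    return run_sequence(clean_seq.frames, config=config, render=False)


@pytest.fixture(scope="session")
def artifact_result(artifact_seq, config):
    return run_sequence(artifact_seq.frames, config=config, render=False)


@pytest.fixture(scope="session")
def occlusion_result(occlusion_seq, config):
    return run_sequence(occlusion_seq.frames, config=config, recovery=True, render=False)


@pytest.fixture(scope="session")
def small_seq():
    """Cheap 12-frame sequence for fast functional tests."""
    return make_reference_sequence(
        n_frames=12, frame_size=128, texture_size=512, seed=3
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
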