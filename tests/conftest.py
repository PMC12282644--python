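import numpy as np
import pytest

from agidet import pipeline, pose_features
from agidet.synthetic import (
    PhysioSimConfig,
    PoseSimConfig,
    generate_physio,
    generate_pose,
)


@pytest.fixture(scope="session")
def physio_cfg():
    return PhysioSimConfig(
        duration_s=3600.0,
        n_episodes=2,
        episode_duration_range_s=(480.0, 780.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def physio_session(physio_cfg):
    """One generated participant session: (stream, biomarkers, labels)."""
    return generate_physio(physio_cfg)


@pytest.fixture(scope="session")
def pose_cfg():
    return PoseSimConfig(
        duration_s=420.0,
        fps=5.0,
        n_episodes=1,
        episode_duration_range_s=(120.0, 180.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def pose_session(pose_cfg):
    return generate_pose(pose_cfg)


@pytest.fixture(scope="session")
def pose_windows(pose_session, pose_cfg):
    frames, labels = pose_session
    df = pose_features.frames_to_features(frames)
    return pose_features.build_windows(df, labels, fps=pose_cfg.fps)


@pytest.fixture(scope="session")
def small_cohort():
    from agidet.synthetic import generate_cohort

    return generate_cohort(3, pipeline.DEFAULT_PHYSIO, seed=5)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return pipeline.cohort_features(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
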