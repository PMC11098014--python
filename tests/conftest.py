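import numpy as np
import pytest

from dancekin.features import FeatureMatrix, extract_feature_matrix
from dancekin.kinematics import SmoothingConfig
from dancekin.motionsim import BASE_POSE, MotionSpec, generate_genre_dataset, generate_motion
from dancekin.pose_io import COCO17, PoseSequence

FPS = 60.0


def make_pose(positions, fps=FPS, sequence_id="test", **kwargs):
    return PoseSequence(
        sequence_id=sequence_id, fps=fps, positions=np.asarray(positions, float), **kwargs
    )


def static_pose(n_frames=240, fps=FPS):
    """A motionless standing figure (3 s more than covers every feature)."""
    return make_pose(np.broadcast_to(BASE_POSE, (n_frames, 17, 3)).copy(), fps=fps)


@pytest.fixture
def no_smoothing():
    return SmoothingConfig(enabled=False)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact labeled synthetic dataset shared across classifier tests."""
    return generate_genre_dataset(n_per_genre=8, seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_feature_matrix(small_dataset)
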