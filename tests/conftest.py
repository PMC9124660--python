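import numpy as np
import pytest

from fetomosaic.simulator import (
    ArtifactConfig,
    MotionConfig,
    SceneConfig,
    make_texture,
    render_sequence,
    sample_trajectory,
)


@pytest.fixture(scope="session")
def texture():
    return make_texture(SceneConfig(seed=3))


@pytest.fixture(scope="session")
def short_sequence(texture):
    """12-frame artifact-free sequence with moderate smooth motion."""
    scene = SceneConfig(seed=3)
    traj = sample_trajectory(MotionConfig(n_frames=12, seed=4), (320, 320), texture_size=1024)
    return render_sequence(texture, traj, scene, None, (320, 320))


@pytest.fixture(scope="session")
def artifact_sequence(texture):
    """12-frame sequence with floating particles and speculars."""
    scene = SceneConfig(seed=3)
    traj = sample_trajectory(MotionConfig(n_frames=12, seed=4), (320, 320), texture_size=1024)
    return render_sequence(texture, traj, scene, ArtifactConfig(seed=5), (320, 320))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_affine(rng, scale_jitter=0.05, max_translation=10.0):
    """Well-conditioned random affine for property tests."""
    lin = np.eye(2) + rng.uniform(-scale_jitter, scale_jitter, (2, 2))
    t = rng.uniform(-max_translation, max_translation, 2)
    from fetomosaic.geometry import AffineTransform

    return AffineTransform(np.column_stack([lin, t]))
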