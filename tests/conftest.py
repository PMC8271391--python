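import numpy as np
import pytest

from imugait import syngait
from imugait.dataset import build_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    return syngait.sample_cohort(4, 2, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort):
    """4 subjects (2 with measured IMU), 2 noiseless trials each."""
    return syngait.make_dataset(
        tiny_cohort, trials_per_subject=2,
        noise_config=syngait.NoiseConfig.zero(), seed=7,
    )


@pytest.fixture(scope="session")
def angle_samples(tiny_bundle):
    return build_samples(tiny_bundle, target="angles")


def random_smooth_pose(rate=1000.0, duration=1.0, amp=1.0, seed=0):
    """Low-frequency random orientation/translation path (band-limited by
    construction, so finite-difference derivatives behave)."""
    from imugait import quat
    from imugait.rigid import PoseSequence

    rng = np.random.default_rng(seed)
    t = np.arange(0, duration, 1.0 / rate)
    angles = np.zeros((len(t), 3))
    origins = np.zeros((len(t), 3))
    for k in range(3):
        for f, in zip(rng.uniform(0.5, 2.0, 3)[:, None]):
            angles[:, k] += amp * rng.uniform(0.2, 1.0) * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            origins[:, k] += 0.1 * rng.uniform(0.2, 1.0) * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    from scipy.spatial.transform import Rotation

    q = quat.from_scipy(Rotation.from_rotvec(angles))
    return PoseSequence(rate=rate, orientations=q, origins=origins)
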