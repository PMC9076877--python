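import numpy as np
import pytest

from drusemap.clustering import MultispectralStack


@pytest.fixture
def eight_landmarks():
    """Eight well-spread, non-collinear landmark positions (row, col)."""
    return np.array(
        [
            [10.0, 12.0],
            [14.0, 88.0],
            [50.0, 50.0],
            [82.0, 20.0],
            [86.0, 90.0],
            [30.0, 70.0],
            [66.0, 34.0],
            [48.0, 8.0],
        ]
    )


def make_affine(theta_deg=5.0, scale=1.02, translation=(3.0, -2.0)):
    """2x3 row/col affine: rotation + isotropic scale + translation."""
    t = np.deg2rad(theta_deg)
    A = scale * np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return np.hstack([A, np.asarray(translation, float)[:, None]])


def apply_affine(matrix, points):
    return np.atleast_2d(points) @ matrix[:, :2].T + matrix[:, 2]


@pytest.fixture
def two_population_stack():
    """A 20x20 stack with two spectrally distant pixel populations split
    left/right, full mask; ground-truth labels returned alongside."""
    rng = np.random.default_rng(42)
    rows = cols = 20
    channels = np.empty((rows, cols, 3))
    truth = np.zeros((rows, cols), dtype=int)
    truth[:, cols // 2 :] = 1
    lo, hi = np.array([0.2, 0.25, 0.3]), np.array([0.8, 0.75, 0.7])
    for i in range(3):
        base = np.where(truth == 0, lo[i], hi[i])
        channels[..., i] = base + rng.normal(0, 0.01, size=base.shape)
    stack = MultispectralStack(np.clip(channels, 0, 1), np.ones((rows, cols), bool))
    return stack, truth
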