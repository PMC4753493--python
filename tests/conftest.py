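import numpy as np
import pytest

import actolayer as al


@pytest.fixture(scope="session")
def grid():
    """Standard small film: 10x10 domain, 33 wall-to-wall nodes."""
    return al.GridSpec(32, 33, 10.0, 10.0)


@pytest.fixture(scope="session")
def fine_grid():
    return al.GridSpec(64, 65, 10.0, 10.0)


@pytest.fixture
def tumbling():
    return al.preset("tumbling")


@pytest.fixture
def aligning():
    return al.preset("aligning")


def smooth_anchored_theta(grid, amp=0.4, seed=0):
    """Random smooth polarity angle respecting wall anchoring (theta = 0)."""
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(grid.x, grid.y)
    th = np.zeros(grid.shape)
    for mx in range(3):
        for my in range(1, 4):
            a = amp * rng.standard_normal() / (1 + mx + my) ** 2
            phase = rng.uniform(0, 2 * np.pi)
            th += a * np.sin(2 * np.pi * mx * x / grid.L_x + phase) * np.sin(
                np.pi * my * y / grid.L_y)
    return th


@pytest.fixture
def smooth_state(grid):
    return al.FieldState.from_theta(smooth_anchored_theta(grid))
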