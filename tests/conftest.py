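import numpy as np
import pytest

from saltnav import (
    GradientSpec,
    SegmentationParams,
    Trajectory,
    derive_speed,
)


@pytest.fixture
def gradient() -> GradientSpec:
    """Standard 0-100 mM gradient over a 120 mm plate, release at midpoint."""
    return GradientSpec()


@pytest.fixture
def seg_params() -> SegmentationParams:
    return SegmentationParams()


def make_traj(xy, dt=0.5, worm_id="test") -> Trajectory:
    """Trajectory from raw positions with speed derived directly (no smoothing),
    so constructed geometric fixtures keep their exact shape."""
    xy = np.asarray(xy, dtype=float)
    t = np.arange(xy.shape[0]) * dt
    return Trajectory(worm_id=worm_id, t=t, xy=xy, speed=derive_speed(xy, dt))


@pytest.fixture
def straight_up_track(gradient) -> Trajectory:
    """Constant 0.1 mm/s straight up the gradient for 60 s."""
    n = 121
    y = 60.0 + 0.05 * np.arange(n)
    xy = np.column_stack([np.full(n, 60.0), y])
    return make_traj(xy)
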