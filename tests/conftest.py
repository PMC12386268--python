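import numpy as np
import pytest

from halffield import DishGeometry, Trajectory


@pytest.fixture
def dish() -> DishGeometry:
    return DishGeometry()


@pytest.fixture
def make_trajectory():
    """Build a Trajectory from a list of (x, y) um positions."""

    def _make(points, frame_interval=15.0, **kwargs):
        return Trajectory(
            cell_id=kwargs.pop("cell_id", 0),
            positions=np.asarray(points, dtype=float),
            frame_interval=frame_interval,
            **kwargs,
        )

    return _make
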