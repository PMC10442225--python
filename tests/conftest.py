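import numpy as np
import pandas as pd
import pytest

from xcdyn.core_io import TrajectoryTable


def make_table(points, frame_interval=0.005477, pixel_size=0.106):
    """Build a TrajectoryTable from {traj_id: [(frame, x, y), ...]}."""
    rows = [
        {"trajectory_id": tid, "frame": f, "x": x, "y": y}
        for tid, pts in points.items()
        for f, x, y in pts
    ]
    return TrajectoryTable(
        pd.DataFrame(rows), frame_interval=frame_interval, pixel_size=pixel_size
    )


@pytest.fixture
def random_walk_table():
    """One long isotropic 2D random walk, jumps ~0.3 μm, far from origin."""
    rng = np.random.default_rng(42)
    n = 5000
    steps = rng.normal(0.0, 0.2, size=(n, 2))
    pos = 50.0 + np.cumsum(steps, axis=0)
    df = pd.DataFrame(
        {
            "trajectory_id": 0,
            "frame": np.arange(n),
            "x": pos[:, 0],
            "y": pos[:, 1],
        }
    )
    return TrajectoryTable(df)
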