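import numpy as np
import pytest

from spermwall.trajectory import Spot, Trajectory


def make_traj(points, frames=None, tid="t0", **kwargs):
    """Trajectory from a list of (x, y) µm points; frames default to 0..n-1."""
    if frames is None:
        frames = range(len(points))
    spots = [Spot(frame=f, x=float(x), y=float(y))
             for f, (x, y) in zip(frames, points)]
    return Trajectory(id=tid, spots=spots, **kwargs)


@pytest.fixture
def zigzag():
    """The reference zigzag: path 4·√2 µm, displacement 4 µm, band width 1 µm."""
    return make_traj([(0, 0), (1, 1), (2, 0), (3, 1), (4, 0)])


@pytest.fixture
def straight():
    """Collinear track along x at 1 µm/frame."""
    return make_traj([(0, 0), (1, 0), (2, 0)])


def random_trajectory(rng, n_min=3, n_max=40, scale=50.0):
    """Random trajectory with nonzero displacement (for property tests)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        pts = rng.uniform(-scale, scale, size=(n, 2))
        if np.hypot(*(pts[-1] - pts[0])) > 1e-6:
            return make_traj(pts)
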