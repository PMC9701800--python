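import numpy as np
import pytest

from adaptherm.geometry import SliceFrame, VolumeGrid
from adaptherm.thermometry import TemperatureMap


@pytest.fixture
def small_frame():
    """A 21x21, 1 mm frame at angle 0 with the axis in column 10."""
    return SliceFrame(angle=0.0, matrix=(21, 21), pixel_spacing=1.0)


@pytest.fixture
def ridge_map(small_frame):
    """Noiseless tent field T = 60 - 2*|col - 10|, hottest on the axis."""
    cols = np.arange(21)
    values = np.tile(60.0 - 2.0 * np.abs(cols - 10), (21, 1))
    return TemperatureMap(values=values, frame=small_frame, baseline_T0=20.0)


@pytest.fixture
def radial_map():
    """Radially decreasing Gaussian temperature field on a 41x41 frame."""
    frame = SliceFrame(angle=0.0, matrix=(41, 41), pixel_spacing=1.0)
    rows, cols = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
    r2 = (cols - 20.0) ** 2
    values = 21.0 + 60.0 * np.exp(-r2 / (2 * 8.0**2))
    return TemperatureMap(values=values, frame=frame, baseline_T0=21.0)


def brute_force_min_path(costs, connectivity=1):
    """Exhaustive enumeration of all monotone paths; returns (cost, cols).

    Ties resolve to the path that is nearest the left at the end and then
    at every predecessor, matching the DP backtracking order.
    """
    n_rows, n_cols = costs.shape
    best = None
    stack = [((c,), costs[0, c]) for c in range(n_cols)]
    while stack:
        path, cost = stack.pop()
        r = len(path)
        if r == n_rows:
            key = (cost, tuple(reversed(path)))
            if best is None or key < best:
                best = key
            continue
        c = path[-1]
        for nc in range(max(0, c - connectivity),
                        min(n_cols, c + connectivity + 1)):
            stack.append((path + (nc,), cost + costs[r, nc]))
    return best[0], list(reversed(best[1]))
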