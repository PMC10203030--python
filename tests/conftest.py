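import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scaleofeffect.landscape import CLASSES, LandscapeGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_grid(rng):
    """A 60x60 random 4-class grid, 10 m cells, origin (0, 0)."""
    values = rng.integers(0, len(CLASSES), size=(60, 60))
    return LandscapeGrid(values=values, cell_size=10.0)


@pytest.fixture
def half_plane_grid():
    """Forest for x < 500 m, 'other' for x >= 500 m; 10 m cells, 100x100."""
    values = np.full((100, 100), CLASSES.index("other"), dtype=np.int64)
    values[:, :50] = CLASSES.index("forest")
    return LandscapeGrid(values=values, cell_size=10.0)


@pytest.fixture
def toy_sites():
    return pd.DataFrame(
        {
            "site_id": ["a", "b", "c"],
            "x": [300.0, 250.0, 380.0],
            "y": [300.0, 350.0, 260.0],
            "effort": [10, 12, 8],
        }
    )


def brute_force_cover_fraction(grid, center, radius, cls):
    """Independent oracle: pure-Python enumeration of cell centers in the disc."""
    code = grid.classes.index(cls)
    x0, y0 = grid.origin
    n_in = 0
    n_cls = 0
    for i in range(grid.nrows):
        for j in range(grid.ncols):
            cx = x0 + (j + 0.5) * grid.cell_size
            cy = y0 + (grid.nrows - i - 0.5) * grid.cell_size
            dx = cx - center[0]
            dy = cy - center[1]
            if dx * dx + dy * dy <= radius * radius:
                n_in += 1
                if grid.values[i, j] == code:
                    n_cls += 1
    return n_cls / n_in
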