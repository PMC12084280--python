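import numpy as np
import pytest

from pspde.grids import make_grid, PhenotypeDensityField
from pspde.fixtures import gaussian_profile


@pytest.fixture
def small_grid():
    """10 x 8 grid on [0, 10] x [0, 1]."""
    return make_grid(0.0, 10.0, 10, 0.0, 1.0, 8)


@pytest.fixture
def fine_y_grid():
    """Well-resolved phenotype axis on [-5, 5] (degenerate in x)."""
    return make_grid(0.0, 1.0, 1, -5.0, 5.0, 500)


@pytest.fixture
def gaussian_field(fine_y_grid):
    """Weight-60 phenotype Gaussian (mean -1, variance 0.5) as a 1 x ny field."""
    vals = gaussian_profile(fine_y_grid.y_centers, 60.0, -1.0, 0.5)[None, :]
    return PhenotypeDensityField(fine_y_grid, vals)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
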