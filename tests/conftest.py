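import numpy as np
import pytest

from deforisk import (
    GridSpec,
    RasterField,
    RiskParams,
    ScenarioKnobs,
    make_synthetic_landscape,
)


@pytest.fixture
def grid5() -> GridSpec:
    """A 5x5 grid at the standard 5 km nominal resolution."""
    return GridSpec(n_rows=5, n_cols=5, cell_size=0.05, nominal_resolution=5.0)


@pytest.fixture
def params() -> RiskParams:
    return RiskParams()


@pytest.fixture
def landscape():
    """Seeded 32x32 synthetic landscape shared across tests."""
    grid = GridSpec(n_rows=32, n_cols=32)
    return make_synthetic_landscape(7, grid, ScenarioKnobs())


def constant_field(grid: GridSpec, value: float, units: str = "1") -> RasterField:
    return RasterField(grid, np.full(grid.shape, float(value)), units=units)
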