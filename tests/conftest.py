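import numpy as np
import pytest
from shapely.geometry import Polygon

from spatialenroll.spatial_structure import AreaUnit
from spatialenroll.synthetic_region import SimulationConfig, simulate_dataset


def square(x0: float, y0: float, side: float = 1.0) -> Polygon:
    return Polygon(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )


def grid_areas(n_rows: int, n_cols: int, side: float = 1.0) -> list[AreaUnit]:
    """Unit-square lattice of AreaUnits in row-major order."""
    areas = []
    for r in range(n_rows):
        for c in range(n_cols):
            areas.append(
                AreaUnit(
                    area_id=f"g{r}_{c}",
                    polygon=square(c * side, r * side, side),
                    centroid=((c + 0.5) * side, (r + 0.5) * side),
                    n_insurants=10,
                )
            )
    return areas


@pytest.fixture(scope="session")
def demo_dataset():
    """One 10x10 synthetic region shared by read-only tests."""
    return simulate_dataset(SimulationConfig(n_rows=10, n_cols=10, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
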