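import numpy as np
import pandas as pd
import pytest

from sdmbaseline.layers import GridSpec, Layer, LayerStack
from sdmbaseline.occurrence import OccurrenceSet
from sdmbaseline.synthetic import SimulationConfig, generate_layers


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, cell_size=0.1,
                    origin_lon=-100.0, origin_lat=31.0)


@pytest.fixture
def small_stack(small_grid) -> LayerStack:
    """10x10 stack: two continuous gradients and one 3-category layer."""
    rng = np.random.default_rng(42)
    rows, cols = np.mgrid[0:10, 0:10]
    cont1 = Layer("grad_ns", "continuous", rows / 9.0)
    cont2 = Layer("noise", "continuous", rng.normal(size=(10, 10)))
    cat = Layer("zone", "categorical", (cols // 4).astype(float),
                categories=(0, 1, 2))
    return LayerStack(small_grid, [cont1, cont2, cat])


@pytest.fixture
def synthetic_stack():
    cfg = SimulationConfig(n_rows=40, n_cols=40, seed=3)
    return cfg, generate_layers(cfg)


def make_occurrences(rows, grid: GridSpec | None = None) -> OccurrenceSet:
    """Build an OccurrenceSet from (species, lon, lat, unc_m, year, vouch)."""
    df = pd.DataFrame(rows, columns=["species_id", "lon", "lat",
                                     "uncertainty_m", "year", "vouchered"])
    df["year"] = df["year"].astype("Int64")
    df["source_id"] = [f"r{i}" for i in range(len(df))]
    return OccurrenceSet(df.reset_index(drop=True))


@pytest.fixture
def occ_factory():
    return make_occurrences
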