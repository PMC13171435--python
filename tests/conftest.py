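import numpy as np
import pandas as pd
import pytest

from hoiforest.census import PlotMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stems(x, y, dbh, sp):
    n = len(x)
    return pd.DataFrame(
        {
            "treeID": [f"t{i}" for i in range(n)],
            "stemID": ["1"] * n,
            "sp": list(sp),
            "gx": list(map(float, x)),
            "gy": list(map(float, y)),
            "dbh": list(map(float, dbh)),
        }
    )


def random_stems(rng, n, extent, n_species=3):
    return make_stems(
        rng.uniform(0, extent, n),
        rng.uniform(0, extent, n),
        rng.lognormal(np.log(3), 0.8, n) + 1.0,
        rng.choice([f"s{k}" for k in range(n_species)], size=n),
    )


@pytest.fixture
def plot_meta():
    return PlotMeta(
        plot_id="demo",
        latitude=10.0,
        x_extent=100.0,
        y_extent=100.0,
        census_dates=(2000.0, 2005.0),
    )
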