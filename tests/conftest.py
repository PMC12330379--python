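import numpy as np
import pandas as pd
import pytest

from vertexstats.cohort import CohortSurface
from vertexstats.templates import hemisphere_pair, mean_edge_length


@pytest.fixture(scope="session")
def ico1_pair():
    return hemisphere_pair(1)


@pytest.fixture(scope="session")
def ico2_pair():
    return hemisphere_pair(2)


@pytest.fixture(scope="session")
def ico2_edge(ico2_pair):
    return mean_edge_length(ico2_pair[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort(ico2_pair, rng):
    """20 subjects of white noise on the ico-2 pair, with a covariate sheet."""
    left, right = ico2_pair
    v = left.n_vertices + right.n_vertices
    data = rng.normal(2.5, 0.3, size=(20, v))
    sheet = pd.DataFrame(
        {
            "age": rng.uniform(20, 70, 20),
            "sex": rng.choice(["F", "M"], 20),
            "group": np.r_[np.full(10, -1.0), np.full(10, 1.0)],
        }
    )
    cohort = CohortSurface(
        data, [f"sub-{i:02d}" for i in range(20)], "synthetic-ico2", "thickness",
        left.n_vertices,
    )
    return cohort, sheet
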