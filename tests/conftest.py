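import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def path3():
    return nx.path_graph(["a", "b", "c"])


@pytest.fixture
def small_matrix(rng):
    """8 genes x 6 samples, two groups of 3, no planted effects."""
    values = rng.normal(8.0, 1.0, size=(8, 6))
    matrix = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(6)],
    )
    phenotype = pd.Series(
        ["case"] * 3 + ["control"] * 3, index=matrix.columns, name="group"
    )
    return matrix, phenotype


def random_graph(n, p, seed):
    return nx.gnp_random_graph(n, p, seed=seed)
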