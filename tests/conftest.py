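import numpy as np
import pandas as pd
import pytest

from ergmix.graph_core import NodeAttributeTable, validate_graph


def make_graph(edges, n):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return validate_graph(a)


def random_graph(rng, n, p=0.3):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return validate_graph(a + a.T)


def make_attrs(labels, groups=None, rng=None, structural=False):
    n = len(labels)
    df = pd.DataFrame(
        {
            "rsn_label": list(labels),
            "cortical_group": list(groups) if groups else ["cortical"] * n,
        }
    )
    if structural:
        rng = rng or np.random.default_rng(0)
        df["struct_degree"] = rng.integers(0, 8, n).astype(float)
        df["struct_clustering"] = rng.random(n)
        df["struct_efficiency"] = rng.random(n)
        df["latent_cluster"] = rng.integers(0, 3, n)
    return NodeAttributeTable(df)


@pytest.fixture
def triangle():
    return make_graph([(0, 1), (1, 2), (0, 2)], 3)


@pytest.fixture
def k4():
    return make_graph([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)


@pytest.fixture
def star4():
    return make_graph([(0, 1), (0, 2), (0, 3)], 4)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
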