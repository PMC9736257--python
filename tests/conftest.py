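import networkx as nx
import pandas as pd
import pytest

from bcrisknet.catalog import ProfileCategorizer
from bcrisknet.graphs import build_affiliation_graph
from bcrisknet.simulate import default_params, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400 women from the default synthetic world, fixed seed."""
    params = default_params(n_women=400)
    cohort, truth = generate_cohort(params, seed=13)
    return cohort, truth


@pytest.fixture(scope="session")
def small_assignments(small_cohort):
    cohort, _ = small_cohort
    out = {}
    for p in (1, 2, 3):
        cat = ProfileCategorizer(profile=p).fit(cohort)
        out[p] = (cat, cat.transform(cohort))
    return out


@pytest.fixture(scope="session")
def small_graphs(small_assignments):
    return {
        p: build_affiliation_graph(assign, p)
        for p, (_, assign) in small_assignments.items()
    }


@pytest.fixture
def two_triangles():
    return nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))


@pytest.fixture
def toy_assignments():
    """Two women: w1={A1,B1}, w2={A1,B2} (via two variables A and B)."""
    return pd.DataFrame(
        {
            "id": ["w1", "w1", "w2", "w2"],
            "profile": [1, 1, 1, 1],
            "variable": ["A", "B", "A", "B"],
            "label": ["A1", "B1", "A1", "B2"],
        }
    )
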