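import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced cohort (2 subjects per sex x band) for fast end-to-end tests."""
    from fdconn import CohortConfig, load_fixture

    sizes = load_fixture("table1")
    sizes["n_male"] = 2
    sizes["n_female"] = 2
    return CohortConfig(group_sizes=sizes, seed=7)


@pytest.fixture(scope="session")
def fitted_small(small_cohort_config):
    from fdconn import FDConnectivity

    return FDConnectivity.from_synthetic(small_cohort_config).fit()


@pytest.fixture(scope="session")
def fixture_link_tables():
    """Published link-frequency tables wrapped as LinkTable objects."""
    from fdconn import load_fixture
    from fdconn.grouping import LinkTable

    return {
        sex: LinkTable(load_fixture(f"table3_{sex}"), [])
        for sex in ("male", "female")
    }


@pytest.fixture(scope="session")
def fixture_centrality():
    """Published centrality indices as Series keyed by node id."""
    from fdconn import load_fixture

    out = {}
    for sex in ("male", "female"):
        t = load_fixture(f"table6_{sex}")
        out[sex] = pd.Series(t["ci"].values, index=t["node"].values, name="ci")
    return out
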