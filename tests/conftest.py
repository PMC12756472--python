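import pytest
from hypothesis import HealthCheck, settings

from phylogrid.io_formats import parse_newick
from phylogrid.synthetic_data import simulate_yule_tree

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FIXTURE_NEWICK = "((A:1.0,B:1.0):2.0,(C:2.0,D:2.0):1.0);"
# Six tips, ultrametric at depth 3: cherries (A,B) at 1.0, (C,D) at 1.5,
# (E,F) at 2.0.
SIX_TIP_NEWICK = "(((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5):1.0,(E:2.0,F:2.0):1.0);"


@pytest.fixture(scope="session")
def fixture_tree():
    return parse_newick(FIXTURE_NEWICK)


@pytest.fixture(scope="session")
def six_tip_tree():
    return parse_newick(SIX_TIP_NEWICK)


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, seed=11, depth=100.0)


@pytest.fixture(scope="session")
def yule200():
    return simulate_yule_tree(200, seed=17, depth=100.0)
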