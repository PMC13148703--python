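import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cliquescreen.netcore import Network


@pytest.fixture
def p3() -> Network:
    """Path a-b-c."""
    return Network.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def k3() -> Network:
    return Network.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4() -> Network:
    nodes = ["a", "b", "c", "d"]
    edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1 :]]
    return Network.from_edges(nodes, edges)


@pytest.fixture
def star() -> Network:
    """K_{1,3} with center c."""
    return Network.from_edges(
        ["c", "l1", "l2", "l3"], [("c", "l1"), ("c", "l2"), ("c", "l3")]
    )


@pytest.fixture
def two_k2() -> Network:
    return Network.from_edges(["a", "b", "x", "y"], [("a", "b"), ("x", "y")])
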