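import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ehc_access import RegionConfig, generate_region
from ehc_access.road_network import RoadNetwork

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SMALL_CONFIG = RegionConfig(
    seed=11, n_nodes=400, n_areas=60, n_stations=6, n_hospitals=3, extent_km=60.0
)


@pytest.fixture(scope="session")
def small_region():
    """A quick-to-generate region reused across routing/statistics tests."""
    return generate_region(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_region():
    """A full 500-area region at the generator's default study conditions."""
    return generate_region(RegionConfig(seed=7))


@pytest.fixture()
def path_graph():
    """A -- B -- C path with travel times 2 and 3 minutes."""
    net = RoadNetwork()
    net.add_node(0, 0.0, 0.0)
    net.add_node(1, 2000.0, 0.0)
    net.add_node(2, 5000.0, 0.0)
    net.add_edge(0, 1, 2000.0, 60.0)  # 2 min
    net.add_edge(1, 2, 3000.0, 60.0)  # 3 min
    return net


def random_network(rng: np.random.Generator, n_nodes: int) -> RoadNetwork:
    """Random connected graph with plausible edge attributes (test helper)."""
    net = RoadNetwork()
    coords = rng.uniform(0, 10_000, size=(n_nodes, 2))
    for i, (x, y) in enumerate(coords):
        net.add_node(i, x, y)
    for i in range(1, n_nodes):  # random tree keeps it connected
        j = int(rng.integers(0, i))
        net.add_edge(i, j, float(rng.uniform(100, 5000)), float(rng.choice([50, 70, 90])))
    extra = rng.integers(0, n_nodes, size=(n_nodes, 2))
    for a, b in extra:
        if a != b and not net.graph.has_edge(int(a), int(b)):
            net.add_edge(int(a), int(b), float(rng.uniform(100, 5000)),
                         float(rng.choice([50, 70, 90])))
    return net
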