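import numpy as np
import pytest
from shapely.geometry import LineString

from velopath.network import Edge, Node, StreetNetwork


def make_network(nodes, edges):
    """nodes: {id: (x, y)}; edges: (id, u, v, {attr}) tuples, straight lines."""
    net = StreetNetwork()
    for nid, (x, y) in nodes.items():
        net.add_node(Node(id=nid, x=x, y=y))
    for eid, u, v, attrs in edges:
        a, b = nodes[u], nodes[v]
        net.add_edge(Edge(id=eid, u=u, v=v, geometry=LineString([a, b]), **attrs))
    return net


@pytest.fixture
def triangle_net():
    """Direct edge (100 m, worst exposure) vs two-leg detour (120 m, best).

    GVI 0 -> ce 1 on the direct edge; GVI 1 -> ce 0 on the detour legs.
    AQI / noise are set so the detour is also cleaner and quieter.
    """
    nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (50.0, 33.166247903554)}
    # legs a-c and c-b are 60 m each (33.166... = sqrt(60^2 - 50^2))
    return make_network(
        nodes,
        [
            ("direct", "a", "b", dict(gvi=0.0, aqi=5.0, noise_db=75.0)),
            ("leg1", "a", "c", dict(gvi=1.0, aqi=1.0, noise_db=45.0)),
            ("leg2", "c", "b", dict(gvi=1.0, aqi=1.0, noise_db=45.0)),
        ],
    )


@pytest.fixture(scope="session")
def small_city():
    """Session-scoped small synthetic city for pipeline-level tests."""
    from velopath.synth import CityConfig, generate_city

    cfg = CityConfig(grid_n=8, n_stations=8, total_trips=5_000, seed=7)
    net, stations, trips = generate_city(cfg)
    return cfg, net, stations, trips
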