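"""Independent oracles used by the test suite.

The routing oracle enumerates every simple path with networkx and scores
it with a direct evaluation of the impedance formula, independently of
the package's Dijkstra implementation.  The area oracle estimates polygon
areas by Monte-Carlo point sampling, independently of GEOS area algebra.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from shapely import contains_xy
from shapely.geometry import LineString

from velopath.network import Edge, Node, StreetNetwork


def random_connected_network(
    rng: np.random.Generator, max_edges: int = 12
) -> StreetNetwork:
    """Small random connected network with random GVI values per edge.

    Node positions are random planar points; edge lengths are their
    geometric distances (so stored length always matches arc length).
    """
    n_nodes = int(rng.integers(3, 8))
    coords = rng.uniform(200.0, 1200.0, size=(n_nodes, 2))
    net = StreetNetwork()
    for i in range(n_nodes):
        net.add_node(Node(id=f"n{i}", x=float(coords[i, 0]), y=float(coords[i, 1])))
    # random spanning tree first (guarantees connectivity), then extras
    order = rng.permutation(n_nodes)
    pairs = []
    for k in range(1, n_nodes):
        a = order[k]
        b = order[int(rng.integers(0, k))]
        pairs.append(tuple(sorted((int(a), int(b)))))
    all_pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    rng.shuffle(all_pairs)
    for p in all_pairs:
        if len(pairs) >= max_edges:
            break
        if p not in pairs:
            pairs.append(p)
    for eidx, (i, j) in enumerate(sorted(pairs)):
        net.add_edge(
            Edge(
                id=f"e{eidx:03d}",
                u=f"n{i}",
                v=f"n{j}",
                geometry=LineString([tuple(coords[i]), tuple(coords[j])]),
                gvi=float(rng.uniform(0.0, 1.0)),
            )
        )
    return net


def enumerate_best_path(
    net: StreetNetwork, origin: str, dest: str, s: float
) -> tuple[float, tuple[str, ...]]:
    """Best (cost, edge-id sequence) over all simple paths, by brute force.

    Costs accumulate edge by edge in path order, mirroring how any
    label-setting search would accumulate them, so float sums are
    comparable with the implementation's.  Ties resolve to the
    lexicographically smallest edge-id sequence.
    """
    g = nx.Graph()
    for e in net.edges.values():
        g.add_edge(e.u, e.v, edge_id=e.id)
    best: tuple[float, tuple[str, ...]] | None = None
    for node_path in nx.all_simple_paths(g, origin, dest):
        seq = tuple(
            g.edges[u, v]["edge_id"] for u, v in zip(node_path, node_path[1:])
        )
        cost = 0.0
        for eid in seq:
            edge = net.edges[eid]
            ce = 1.0 - edge.gvi  # the package's GVI cost mapping, re-derived
            cost = cost + (edge.length + edge.length * ce * s)
        label = (cost, seq)
        if best is None or label < best:
            best = label
    assert best is not None, "disconnected pair in oracle"
    return best


def monte_carlo_jaccard(
    buf_a, buf_b, n_points: int = 1_000_000, seed: int = 0
) -> float:
    """Jaccard overlap of two polygons by uniform point sampling."""
    rng = np.random.default_rng(seed)
    minx = min(buf_a.bounds[0], buf_b.bounds[0])
    miny = min(buf_a.bounds[1], buf_b.bounds[1])
    maxx = max(buf_a.bounds[2], buf_b.bounds[2])
    maxy = max(buf_a.bounds[3], buf_b.bounds[3])
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    in_a = contains_xy(buf_a, xs, ys)
    in_b = contains_xy(buf_b, xs, ys)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union
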