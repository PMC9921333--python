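"""Street-network data model, GeoJSON I/O, validation and point snapping.

The network is an undirected graph of nodes (planar metric coordinates) and
exposure-attributed edges (polyline geometry, length, optional AQI / noise /
GVI values).  Cycling is assumed bidirectional, so every edge can be
traversed in either direction.  Coordinates must already be projected to a
planar CRS in metres; no coordinate transformation is performed here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point

logger = logging.getLogger(__name__)

EXPOSURE_TYPES = ("aqi", "noise", "gvi")

#: valid (inclusive) value ranges for each exposure attribute
EXPOSURE_RANGES: Mapping[str, tuple[float, float]] = {
    "aqi": (1.0, 5.0),
    "noise": (0.0, 120.0),
    "gvi": (0.0, 1.0),
}

#: edge attribute name per exposure type
EXPOSURE_ATTRS: Mapping[str, str] = {
    "aqi": "aqi",
    "noise": "noise_db",
    "gvi": "gvi",
}

LENGTH_RTOL = 1e-6


class NetworkError(Exception):
    """Base class for network construction / IO errors."""


class ValidationError(NetworkError):
    """Referential-integrity or attribute-range violation."""


class CRSError(NetworkError):
    """Coordinates look geographic (degrees) rather than planar metres."""


class SnapError(NetworkError):
    """Point snapping failed (e.g. empty network)."""


@dataclass(frozen=True)
class Node:
    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"node {self.id!r}: non-finite coordinates")


@dataclass
class Edge:
    """An undirected street segment between nodes ``u`` and ``v``.

    ``aqi`` (1-5 composite air-quality index), ``noise_db`` (Lden, dB) and
    ``gvi`` (green view fraction, 0-1) are ``None`` when unknown; missing
    values are never silently treated as zero.
    """

    id: str
    u: str
    v: str
    geometry: LineString
    length: float = 0.0
    aqi: float | None = None
    noise_db: float | None = None
    gvi: float | None = None

    def __post_init__(self) -> None:
        if len(self.geometry.coords) < 2:
            raise ValidationError(f"edge {self.id!r}: polyline needs >= 2 vertices")
        arc = self.geometry.length
        if self.length == 0.0:
            self.length = arc
        if arc <= 0:
            raise ValidationError(f"edge {self.id!r}: zero-length geometry")
        if not math.isclose(self.length, arc, rel_tol=LENGTH_RTOL):
            raise ValidationError(
                f"edge {self.id!r}: stored length {self.length} does not match "
                f"arc length {arc}"
            )
        for exp, attr in EXPOSURE_ATTRS.items():
            val = getattr(self, attr)
            if val is None:
                continue
            lo, hi = EXPOSURE_RANGES[exp]
            if not (lo <= val <= hi):
                raise ValidationError(
                    f"edge {self.id!r}: {attr}={val} outside [{lo}, {hi}]"
                )

    def exposure(self, exposure_type: str) -> float | None:
        return getattr(self, EXPOSURE_ATTRS[exposure_type])

    def set_exposure(self, exposure_type: str, value: float | None) -> None:
        setattr(self, EXPOSURE_ATTRS[exposure_type], value)


@dataclass(frozen=True)
class SnapResult:
    """Nearest node (routing terminal) and nearest edge (diagnostic)."""

    node_id: str
    edge_id: str
    node_distance: float
    edge_distance: float

    @property
    def snap_distance(self) -> float:
        return self.node_distance


class StreetNetwork:
    """Undirected street network backed by a :class:`networkx.Graph`."""

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[Edge] = ()):
        self.nodes: dict[str, Node] = {}
        self.edges: dict[str, Edge] = {}
        self.graph = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise ValidationError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        self.graph.add_node(node.id)

    def add_edge(self, edge: Edge) -> None:
        if edge.id in self.edges:
            raise ValidationError(f"duplicate edge id {edge.id!r}")
        for end in (edge.u, edge.v):
            if end not in self.nodes:
                raise ValidationError(
                    f"edge {edge.id!r} references undeclared node {end!r}"
                )
        self.edges[edge.id] = edge
        # parallel edges: keep the one with the smaller id deterministic in
        # the adjacency; all edges stay in self.edges
        if self.graph.has_edge(edge.u, edge.v):
            prev = self.graph.edges[edge.u, edge.v]["edge_id"]
            if edge.id < prev:
                self.graph.edges[edge.u, edge.v]["edge_id"] = edge.id
        else:
            self.graph.add_edge(edge.u, edge.v, edge_id=edge.id)

    # -- queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node_id: str):
        """Yield ``(neighbor_id, Edge)`` sorted by edge id (deterministic)."""
        out = []
        for nb in self.graph.neighbors(node_id):
            eid = self.graph.edges[node_id, nb]["edge_id"]
            out.append((nb, self.edges[eid]))
        out.sort(key=lambda t: t[1].id)
        return out

    def edge_between(self, u: str, v: str) -> Edge:
        return self.edges[self.graph.edges[u, v]["edge_id"]]

    def connected(self, u: str, v: str) -> bool:
        return nx.has_path(self.graph, u, v)

    def node_point(self, node_id: str) -> Point:
        n = self.nodes[node_id]
        return Point(n.x, n.y)

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [n.x for n in self.nodes.values()]
        ys = [n.y for n in self.nodes.values()]
        return min(xs), min(ys), max(xs), max(ys)

    def missing_count(self, exposure_type: str) -> int:
        return sum(1 for e in self.edges.values() if e.exposure(exposure_type) is None)

    def copy(self) -> "StreetNetwork":
        net = StreetNetwork()
        for n in self.nodes.values():
            net.add_node(n)
        for e in self.edges.values():
            net.add_edge(replace(e, geometry=LineString(e.geometry)))
        return net


# ---------------------------------------------------------------------------
# GeoJSON I/O


def _looks_geographic(coords: np.ndarray) -> bool:
    # a metric urban network virtually never fits inside lon/lat bounds
    return bool(
        coords.size
        and np.all(np.abs(coords[:, 0]) <= 180.0)
        and np.all(np.abs(coords[:, 1]) <= 90.0)
    )


def load_network(path) -> StreetNetwork:
    """Load a street network from a GeoJSON FeatureCollection.

    LineString features with properties ``{id, u, v, aqi?, noise_db?, gvi?}``
    define edges.  Point features with property ``id`` (optional in the
    file) declare nodes explicitly; when absent, nodes are inferred from
    edge endpoints, with coordinate consistency enforced across edges that
    share a node id.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"malformed GeoJSON in {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise NetworkError(f"{path}: expected a FeatureCollection")

    point_feats = []
    line_feats = []
    for feat in doc.get("features", []):
        gtype = feat.get("geometry", {}).get("type")
        if gtype == "Point":
            point_feats.append(feat)
        elif gtype == "LineString":
            line_feats.append(feat)
        else:
            raise NetworkError(f"unsupported geometry type {gtype!r}")
    if not line_feats:
        raise NetworkError(f"{path}: no LineString features")

    all_coords = np.array(
        [c for f in line_feats for c in f["geometry"]["coordinates"]], dtype=float
    )
    if _looks_geographic(all_coords):
        raise CRSError(
            f"{path}: coordinates fit in lon/lat bounds; planar metres required"
        )

    net = StreetNetwork()
    explicit_nodes = bool(point_feats)
    if explicit_nodes:
        for feat in point_feats:
            props = feat.get("properties") or {}
            x, y = feat["geometry"]["coordinates"][:2]
            net.add_node(Node(id=str(props["id"]), x=float(x), y=float(y)))

    inferred: dict[str, tuple[float, float]] = {}
    pending_edges: list[Edge] = []
    for feat in line_feats:
        props = feat.get("properties") or {}
        for key in ("id", "u", "v"):
            if key not in props:
                raise ValidationError(f"edge feature missing property {key!r}")
        coords = [(float(x), float(y)) for x, y in feat["geometry"]["coordinates"]]
        eid, u, v = str(props["id"]), str(props["u"]), str(props["v"])
        if not explicit_nodes:
            for nid, xy in ((u, coords[0]), (v, coords[-1])):
                if nid in inferred:
                    if not np.allclose(inferred[nid], xy):
                        raise ValidationError(
                            f"node {nid!r}: conflicting coordinates across edges"
                        )
                else:
                    inferred[nid] = xy

        def _opt(key: str) -> float | None:
            val = props.get(key)
            return None if val is None else float(val)

        edge = Edge(
            id=eid,
            u=u,
            v=v,
            geometry=LineString(coords),
            length=float(props["length"]) if props.get("length") is not None else 0.0,
            aqi=_opt("aqi"),
            noise_db=_opt("noise_db"),
            gvi=_opt("gvi"),
        )
        pending_edges.append(edge)

    if not explicit_nodes:
        for nid in sorted(inferred):
            x, y = inferred[nid]
            net.add_node(Node(id=nid, x=x, y=y))
    for edge in pending_edges:
        net.add_edge(edge)
    logger.info("loaded network: %d nodes, %d edges", len(net), net.n_edges)
    return net


def write_network(net: StreetNetwork, path) -> None:
    """Write a network as GeoJSON (Point node features + LineString edges)."""
    features = []
    for nid in sorted(net.nodes):
        n = net.nodes[nid]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [n.x, n.y]},
                "properties": {"id": n.id},
            }
        )
    for eid in sorted(net.edges):
        e = net.edges[eid]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(c) for c in e.geometry.coords],
                },
                "properties": {
                    "id": e.id,
                    "u": e.u,
                    "v": e.v,
                    "length": e.length,
                    "aqi": e.aqi,
                    "noise_db": e.noise_db,
                    "gvi": e.gvi,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Snapping


def snap_point(net: StreetNetwork, x: float, y: float) -> SnapResult:
    """Snap a coordinate to its nearest node and nearest edge.

    The nearest node is the routing terminal; the nearest edge is reported
    for diagnostics only.  Ties are broken by smallest id, so snapping is
    deterministic.
    """
    if not net.nodes or not net.edges:
        raise SnapError("cannot snap to an empty network")
    ids = sorted(net.nodes)
    coords = np.array([(net.nodes[i].x, net.nodes[i].y) for i in ids])
    d = np.hypot(coords[:, 0] - x, coords[:, 1] - y)
    best = float(d.min())
    # exact-distance tie-break by id: ids are pre-sorted, take first argmin
    node_id = ids[int(np.argmin(d))]

    p = Point(x, y)
    edge_id, edge_dist = None, math.inf
    for eid in sorted(net.edges):
        dist = net.edges[eid].geometry.distance(p)
        if dist < edge_dist:
            edge_id, edge_dist = eid, dist
    return SnapResult(
        node_id=node_id, edge_id=edge_id, node_distance=best, edge_distance=edge_dist
    )
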