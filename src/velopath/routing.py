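"""Exposure-adjusted least-cost routing.

Routing cost follows the environmental impedance function

    Ce = Ct + Ct * ce * s

where ``Ct`` is the base cost of an edge (its length in metres), ``ce`` the
normalised environmental cost coefficient in [0, 1] and ``s`` a sensitivity
coefficient weighting the environmental component.  ``s = 0`` collapses to
pure shortest-path routing; sweeping ``s`` over several orders of magnitude
produces alternative routes trading distance against exposure.  Among the
alternatives within a maximum detour fraction of the shortest route, the
exposure-optimal route is the one with the greatest reduction in mean AQI
or noise, or the greatest increase in mean greenery.

Dijkstra is implemented here (rather than delegated to networkx) because
batch reproducibility requires a deterministic tie-break among equal-cost
paths: labels are ordered by (cumulative cost, edge-id sequence), so the
lexicographically smallest edge-id sequence wins exact cost ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from heapq import heappop, heappush

import numpy as np

from .exposure import CoefficientMapping, DEFAULT_MAPPING
from .network import EXPOSURE_TYPES, StreetNetwork

logger = logging.getLogger(__name__)

#: default sensitivity sweep: the spatial variation of the three exposure
#: layers differs by orders of magnitude, so the sweep spans seven decades
DEFAULT_SENSITIVITIES = (0.1, 0.5, 1, 2, 5, 10, 100, 1000, 10_000, 100_000, 1_000_000)

DETOUR_RTOL = 1e-6


class RoutingError(Exception):
    pass


class UnreachableError(RoutingError):
    """Origin and destination lie in different connected components."""


@dataclass(frozen=True)
class RoutingConfig:
    sensitivities: tuple[float, ...] = DEFAULT_SENSITIVITIES
    max_detour: float = 0.15
    exposure_type: str = "noise"
    #: "exposure" picks the candidate with the best mean exposure within the
    #: detour cap; "cost" picks the lowest cumulative composite cost instead
    selection: str = "exposure"
    mapping: CoefficientMapping = DEFAULT_MAPPING

    def __post_init__(self) -> None:
        s = self.sensitivities
        if not s or any(b <= a for a, b in zip(s, s[1:])) or s[0] <= 0:
            raise RoutingError("sensitivities must be strictly positive and increasing")
        if self.max_detour <= 0:
            raise RoutingError("max_detour must be positive")
        if self.exposure_type not in EXPOSURE_TYPES:
            raise RoutingError(f"unknown exposure type {self.exposure_type!r}")
        if self.selection not in ("exposure", "cost"):
            raise RoutingError(f"unknown selection mode {self.selection!r}")


@dataclass
class Route:
    """An ordered edge sequence with exposure and cost diagnostics."""

    edge_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    length: float
    mean_aqi: float | None
    mean_noise_db: float | None
    mean_gvi: float | None
    composite_cost: float
    sensitivity_used: float  # 0 for the pure shortest path
    detour_fraction: float = 0.0

    def mean_exposure(self, exposure_type: str) -> float | None:
        return {
            "aqi": self.mean_aqi,
            "noise": self.mean_noise_db,
            "gvi": self.mean_gvi,
        }[exposure_type]


@dataclass
class OptimalRouteResult:
    """Shortest route vs the detour-constrained exposure-optimal route."""

    shortest: Route
    optimal: Route
    improved: bool
    exposure_change: float  # optimal minus shortest mean exposure
    exposure_type: str


def composite_edge_cost(ct: float, ce: float, s: float) -> float:
    """Exposure-adjusted edge cost ``Ct + Ct*ce*s``; always >= Ct."""
    if ct < 0 or ce < 0 or s < 0:
        raise RoutingError("Ct, ce and s must be non-negative")
    return ct + ct * ce * s


def _edge_weights(
    net: StreetNetwork,
    exposure_type: str | None,
    s: float,
    mapping: CoefficientMapping,
) -> dict[str, float]:
    weights = {}
    for eid, edge in net.edges.items():
        if s == 0 or exposure_type is None:
            ce = 0.0
        else:
            raw = edge.exposure(exposure_type)
            if raw is None:
                raise RoutingError(
                    f"edge {eid!r} is missing {exposure_type}; impute first"
                )
            ce = mapping(exposure_type, raw).value
        weights[eid] = composite_edge_cost(edge.length, ce, s)
    return weights


def least_cost_tree(
    net: StreetNetwork,
    origin: str,
    exposure_type: str | None,
    s: float,
    mapping: CoefficientMapping = DEFAULT_MAPPING,
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Single-source least-cost labels: node -> (cost, edge-id sequence).

    Labels are compared as (cost, sequence) tuples, so exact cost ties
    resolve to the lexicographically smallest edge-id sequence.  Edge
    weights are strictly positive, which makes the first settled label of
    a node optimal under this ordering.
    """
    if origin not in net.nodes:
        raise RoutingError(f"unknown origin node {origin!r}")
    weights = _edge_weights(net, exposure_type, s, mapping)
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    done: set[str] = set()
    heap: list[tuple[float, tuple[str, ...], str]] = [(0.0, (), origin)]
    while heap:
        cost, seq, u = heappop(heap)
        if u in done:
            continue
        done.add(u)
        best[u] = (cost, seq)
        for v, edge in net.neighbors(u):
            if v in done:
                continue
            label = (cost + weights[edge.id], seq + (edge.id,))
            if v not in best or label < best[v]:
                best[v] = label
                heappush(heap, (label[0], label[1], v))
    return {u: lab for u, lab in best.items() if u in done}


def _route_from_seq(
    net: StreetNetwork,
    origin: str,
    seq: tuple[str, ...],
    cost: float,
    s: float,
) -> Route:
    node_ids = [origin]
    total = 0.0
    sums = {exp: 0.0 for exp in EXPOSURE_TYPES}
    have = {exp: True for exp in EXPOSURE_TYPES}
    for eid in seq:
        edge = net.edges[eid]
        cur = node_ids[-1]
        node_ids.append(edge.v if edge.u == cur else edge.u)
        total += edge.length
        for exp in EXPOSURE_TYPES:
            val = edge.exposure(exp)
            if val is None:
                have[exp] = False
            else:
                sums[exp] += val * edge.length
    means = {
        exp: (sums[exp] / total if have[exp] and total > 0 else None)
        for exp in EXPOSURE_TYPES
    }
    return Route(
        edge_ids=tuple(seq),
        node_ids=tuple(node_ids),
        length=total,
        mean_aqi=means["aqi"],
        mean_noise_db=means["noise"],
        mean_gvi=means["gvi"],
        composite_cost=cost,
        sensitivity_used=s,
    )


def least_cost_path(
    net: StreetNetwork,
    origin: str,
    dest: str,
    exposure_type: str | None = None,
    s: float = 0.0,
    mapping: CoefficientMapping = DEFAULT_MAPPING,
) -> Route:
    """Least-cost route between two nodes under the impedance function.

    ``s = 0`` (or ``exposure_type=None``) yields the pure shortest path.
    """
    if origin == dest:
        raise RoutingError("origin and destination must differ")
    if dest not in net.nodes:
        raise RoutingError(f"unknown destination node {dest!r}")
    tree = least_cost_tree(net, origin, exposure_type, s, mapping)
    if dest not in tree:
        raise UnreachableError(f"no path from {origin!r} to {dest!r}")
    cost, seq = tree[dest]
    return _route_from_seq(net, origin, seq, cost, s)


def sensitivity_sweep(
    net: StreetNetwork,
    origin: str,
    dest: str,
    exposure_type: str,
    config: RoutingConfig | None = None,
) -> list[Route]:
    """Candidate routes for each sensitivity, deduplicated, detour-annotated.

    Each unique edge sequence is kept once, tagged with the smallest
    sensitivity that produced it; detour fractions are relative to the
    pure shortest (``s = 0``) route.
    """
    config = config or RoutingConfig(exposure_type=exposure_type)
    shortest = least_cost_path(net, origin, dest, None, 0.0, config.mapping)
    return _sweep_against(net, origin, dest, exposure_type, config, shortest)


def _sweep_against(
    net: StreetNetwork,
    origin: str,
    dest: str,
    exposure_type: str,
    config: RoutingConfig,
    shortest: Route,
) -> list[Route]:
    seen: dict[tuple[str, ...], Route] = {}
    for s in config.sensitivities:
        route = least_cost_path(net, origin, dest, exposure_type, s, config.mapping)
        if route.edge_ids not in seen:
            route.detour_fraction = (route.length - shortest.length) / shortest.length
            seen[route.edge_ids] = route
    return list(seen.values())


_SIGN = {"aqi": 1.0, "noise": 1.0, "gvi": -1.0}  # minimise aqi/noise, maximise gvi


def select_optimal(
    candidates: list[Route],
    shortest: Route,
    exposure_type: str,
    max_detour: float = 0.15,
    selection: str = "exposure",
) -> OptimalRouteResult:
    """Pick the exposure-optimal route within the detour cap.

    Among candidates with detour fraction <= ``max_detour`` (with a 1e-6
    relative tolerance on the boundary), the route with the best
    length-weighted mean of the optimised exposure wins — minimum for AQI
    and noise, maximum for greenery.  Ties break by shorter length, then
    by lower sensitivity.  Without a strict improvement over the shortest
    route the shortest route itself is returned (``improved=False``).
    """
    sign = _SIGN[exposure_type]
    cap = max_detour * (1.0 + DETOUR_RTOL)
    feasible = [c for c in candidates if c.detour_fraction <= cap]
    base = shortest.mean_exposure(exposure_type)
    if base is None:
        raise RoutingError(f"shortest route lacks {exposure_type} means")

    chosen = None
    if feasible:
        if selection == "cost":
            chosen = min(
                feasible,
                key=lambda c: (c.composite_cost, c.length, c.sensitivity_used),
            )
        else:
            chosen = min(
                feasible,
                key=lambda c: (
                    sign * c.mean_exposure(exposure_type),
                    c.length,
                    c.sensitivity_used,
                ),
            )
    if chosen is not None:
        change = chosen.mean_exposure(exposure_type) - base
        if sign * change < 0 and chosen.edge_ids != shortest.edge_ids:
            return OptimalRouteResult(
                shortest=shortest,
                optimal=chosen,
                improved=True,
                exposure_change=change,
                exposure_type=exposure_type,
            )
    return OptimalRouteResult(
        shortest=shortest,
        optimal=shortest,
        improved=False,
        exposure_change=0.0,
        exposure_type=exposure_type,
    )


def route_geometry(net: StreetNetwork, route: Route):
    """Concatenate edge polylines into one LineString, oriented along travel."""
    from shapely.geometry import LineString

    coords: list[tuple[float, float]] = []
    for eid, u in zip(route.edge_ids, route.node_ids[:-1]):
        edge = net.edges[eid]
        pts = list(edge.geometry.coords)
        start = net.nodes[u]
        # orient the polyline to start at the entry node
        if (pts[0][0] - start.x) ** 2 + (pts[0][1] - start.y) ** 2 > (
            pts[-1][0] - start.x
        ) ** 2 + (pts[-1][1] - start.y) ** 2:
            pts = pts[::-1]
        if coords:
            pts = pts[1:]
        coords.extend(pts)
    return LineString(coords)
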