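"""Batch routing and the end-to-end analysis pipeline.

Ties the stages together: snap stations to the network, route every
ordered OD station pair (shortest + the three exposure-optimal variants
via the sensitivity sweep), aggregate exposures to Voronoi catchments
unweighted and trip-weighted, and compute route-similarity and
exposure-correlation products.  Batch routing runs one single-source
least-cost tree per (origin, sensitivity, exposure) rather than one
Dijkstra per OD pair, which keeps full-matrix runs fast; results are
independent of traversal order by construction (deterministic tie-breaks
everywhere).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .network import StreetNetwork, snap_point, write_network
from .population import (
    ClassThresholds,
    Station,
    TripTable,
    aggregate_by_station,
    availability_and_change,
    detour_distribution,
    route_summary,
    voronoi_catchments,
)
from .routing import (
    OptimalRouteResult,
    Route,
    RoutingConfig,
    _route_from_seq,
    least_cost_tree,
    route_geometry,
    select_optimal,
)
from .similarity import (
    catchment_similarity,
    exposure_correlations,
    route_similarity_records,
)

logger = logging.getLogger(__name__)

EXPOSURES = ("aqi", "noise", "gvi")


@dataclass
class BatchResult:
    """All routing products for a full OD-pair matrix."""

    station_nodes: dict[str, str]
    results: dict[tuple[str, str], dict[str, OptimalRouteResult]]
    unconstrained_detours: dict[tuple[str, str], dict[str, float]]
    unreachable: list[tuple[str, str]]
    #: OD pairs whose selected optimal route used the largest sensitivity —
    #: a sign the sweep may not have converged for them
    max_sensitivity_hits: list[tuple[str, str, str]]

    @property
    def n_od_pairs(self) -> int:
        return len(self.results)


def snap_stations(net: StreetNetwork, stations: list[Station]) -> dict[str, str]:
    return {
        s.station_id: snap_point(net, s.x, s.y).node_id
        for s in sorted(stations, key=lambda s: s.station_id)
    }


def run_batch(
    net: StreetNetwork,
    stations: list[Station],
    config: RoutingConfig | None = None,
) -> BatchResult:
    """Route every ordered station pair: shortest + 3 optimal variants.

    For each exposure type the full sensitivity sweep is retained per
    pair, so both the detour-capped optimal route and the unconstrained
    maximal-improvement detour are available downstream.
    """
    config = config or RoutingConfig()
    nodes = snap_stations(net, stations)
    sids = sorted(nodes)
    results: dict[tuple[str, str], dict[str, OptimalRouteResult]] = {}
    unconstrained: dict[tuple[str, str], dict[str, float]] = {}
    unreachable: list[tuple[str, str]] = []
    max_hits: list[tuple[str, str, str]] = []
    top_s = config.sensitivities[-1]

    for origin_sid in sids:
        o_node = nodes[origin_sid]
        tree0 = least_cost_tree(net, o_node, None, 0.0, config.mapping)
        trees = {
            exp: [
                least_cost_tree(net, o_node, exp, s, config.mapping)
                for s in config.sensitivities
            ]
            for exp in EXPOSURES
        }
        for dest_sid in sids:
            if dest_sid == origin_sid:
                continue
            d_node = nodes[dest_sid]
            key = (origin_sid, dest_sid)
            if d_node == o_node or d_node not in tree0:
                unreachable.append(key)
                continue
            cost0, seq0 = tree0[d_node]
            shortest = _route_from_seq(net, o_node, seq0, cost0, 0.0)
            results[key] = {}
            unconstrained[key] = {}
            for exp in EXPOSURES:
                seen: dict[tuple, Route] = {}
                for s, tree in zip(config.sensitivities, trees[exp]):
                    cost, seq = tree[d_node]
                    if seq not in seen:
                        r = _route_from_seq(net, o_node, seq, cost, s)
                        r.detour_fraction = (r.length - shortest.length) / shortest.length
                        seen[seq] = r
                candidates = list(seen.values())
                res = select_optimal(
                    candidates, shortest, exp, config.max_detour, config.selection
                )
                results[key][exp] = res
                best_any = select_optimal(candidates, shortest, exp, math.inf)
                unconstrained[key][exp] = (
                    best_any.optimal.detour_fraction if best_any.improved else 0.0
                )
                if res.improved and res.optimal.sensitivity_used == top_s:
                    max_hits.append((origin_sid, dest_sid, exp))

    if unreachable:
        logger.warning("%d OD pairs unreachable; excluded", len(unreachable))
    if max_hits:
        logger.warning(
            "%d optimal routes used the largest sensitivity %g — the sweep "
            "may not have converged for them", len(max_hits), top_s,
        )
    return BatchResult(
        station_nodes=nodes,
        results=results,
        unconstrained_detours=unconstrained,
        unreachable=unreachable,
        max_sensitivity_hits=max_hits,
    )


def summaries_frame(
    net: StreetNetwork,
    batch: BatchResult,
    speed_kmh: float = 15.0,
    thresholds: ClassThresholds = ClassThresholds(),
) -> pd.DataFrame:
    """One row per (OD pair, route set) with exposure means and budgets."""
    rows = []
    for (o, d), per_exp in sorted(batch.results.items()):
        shortest = per_exp["aqi"].shortest
        variants = {"shortest": shortest}
        variants.update({exp: per_exp[exp].optimal for exp in EXPOSURES})
        for route_set, route in variants.items():
            rec = {
                "origin_station": o,
                "destination_station": d,
                "route_set": route_set,
                "improved": (
                    per_exp[route_set].improved if route_set in per_exp else np.nan
                ),
                "detour_fraction": route.detour_fraction,
                "sensitivity_used": route.sensitivity_used,
            }
            rec.update(route_summary(net, route, speed_kmh, thresholds))
            rows.append(rec)
    return pd.DataFrame(rows)


def optimal_geometries(net: StreetNetwork, batch: BatchResult):
    """OD pair -> exposure -> optimal-route geometry (shortest stands in
    when no improving route exists within the cap)."""
    return {
        key: {exp: route_geometry(net, per_exp[exp].optimal) for exp in EXPOSURES}
        for key, per_exp in batch.results.items()
    }


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineOutputs:
    summaries: pd.DataFrame
    table: pd.DataFrame
    catchments_unweighted: pd.DataFrame
    catchments_weighted: pd.DataFrame
    detour_hist: pd.DataFrame
    detour_shares: pd.DataFrame
    similarity_records: pd.DataFrame
    similarity_by_catchment: pd.DataFrame
    correlations: pd.DataFrame
    voronoi: dict
    batch: BatchResult
    manifest: dict


def run_pipeline(
    net: StreetNetwork,
    stations: list[Station],
    trips: TripTable,
    config: RoutingConfig | None = None,
    speed_kmh: float = 15.0,
    thresholds: ClassThresholds = ClassThresholds(),
    buffer_radius: float = 5.0,
    overlap_measure: str = "jaccard",
    boundary: tuple[float, float, float, float] | None = None,
) -> PipelineOutputs:
    """Route all OD pairs and compute every population-level product."""
    config = config or RoutingConfig()
    batch = run_batch(net, stations, config)
    summaries = summaries_frame(net, batch, speed_kmh, thresholds)

    routed_pairs = set(batch.results)
    trips_routed = TripTable(
        trips.df[
            trips.df.apply(
                lambda r: (r.origin_station, r.destination_station) in routed_pairs,
                axis=1,
            )
        ]
        if len(trips.df)
        else trips.df
    )

    table = availability_and_change(batch.results, trips_routed)
    catch_unw = aggregate_by_station(summaries, trips_routed, weighted=False)
    catch_w = aggregate_by_station(summaries, trips_routed, weighted=True)
    hist, shares = detour_distribution(
        batch.unconstrained_detours, trips_routed, config.max_detour
    )
    geoms = optimal_geometries(net, batch)
    sim_records = route_similarity_records(geoms, buffer_radius, overlap_measure)
    sim_catch = catchment_similarity(sim_records, trips_routed)
    corr = exposure_correlations(summaries)

    if boundary is None:
        minx, miny, maxx, maxy = net.bounds()
        pad = 0.05 * max(maxx - minx, maxy - miny)
        boundary = (minx - pad, miny - pad, maxx + pad, maxy + pad)
    cells = voronoi_catchments(stations, boundary)

    manifest = {
        "velopath_version": __version__,
        "n_nodes": len(net),
        "n_edges": net.n_edges,
        "n_stations": len(stations),
        "n_od_pairs": batch.n_od_pairs,
        "n_unreachable": len(batch.unreachable),
        "n_max_sensitivity_hits": len(batch.max_sensitivity_hits),
        "total_trips": trips_routed.total_trips,
        "sensitivities": list(config.sensitivities),
        "max_detour": config.max_detour,
        "selection": config.selection,
        "speed_kmh": speed_kmh,
        "thresholds": {
            "aqi_gt": thresholds.aqi_gt,
            "noise_gt_db": thresholds.noise_gt_db,
            "gvi_gt": thresholds.gvi_gt,
        },
        "buffer_radius_m": buffer_radius,
        "overlap_measure": overlap_measure,
        "boundary": list(boundary),
    }
    return PipelineOutputs(
        summaries=summaries,
        table=table,
        catchments_unweighted=catch_unw,
        catchments_weighted=catch_w,
        detour_hist=hist,
        detour_shares=shares,
        similarity_records=sim_records,
        similarity_by_catchment=sim_catch,
        correlations=corr,
        voronoi=cells,
        batch=batch,
        manifest=manifest,
    )


def write_outputs(out: PipelineOutputs, outdir, net: StreetNetwork | None = None) -> None:
    """Write all pipeline products (CSV / GeoJSON / manifest JSON)."""
    import os

    from shapely.geometry import mapping

    os.makedirs(outdir, exist_ok=True)

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    out.summaries.to_csv(p("route_summaries.csv"), index=False)
    out.table.to_csv(p("exposure_table.csv"), index=False)
    out.catchments_unweighted.to_csv(p("catchments_unweighted.csv"), index=False)
    out.catchments_weighted.to_csv(p("catchments_weighted.csv"), index=False)
    out.detour_hist.to_csv(p("detour_histogram.csv"), index=False)
    out.detour_shares.to_csv(p("detour_shares.csv"), index=False)
    out.similarity_records.to_csv(p("similarity_records.csv"), index=False)
    out.similarity_by_catchment.to_csv(p("similarity_by_catchment.csv"), index=False)
    out.correlations.to_csv(p("correlations.csv"), index=False)

    catch_props = {
        (r.station_id, r.route_set): r
        for r in out.catchments_weighted.itertuples()
    }
    features = []
    for sid in sorted(out.voronoi):
        props = {"station_id": sid}
        for route_set in ("shortest", "aqi", "noise", "gvi"):
            rec = catch_props.get((sid, route_set))
            if rec is not None:
                props[f"mean_aqi_{route_set}"] = rec.mean_aqi
                props[f"mean_noise_db_{route_set}"] = rec.mean_noise_db
                props[f"mean_gvi_{route_set}"] = rec.mean_gvi
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(out.voronoi[sid]),
                "properties": props,
            }
        )
    with open(p("catchments.geojson"), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    if net is not None:
        write_network(net, p("network.geojson"))
    with open(p("manifest.json"), "w") as fh:
        json.dump(out.manifest, fh, indent=2, sort_keys=True)
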