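"""Population-level aggregation of route exposures.

Bike-share trips give the population weight: every origin-destination (OD)
station pair contributes either equally (unweighted) or in proportion to
its realised trip count (trip-weighted).  Exposures are aggregated to
station catchments — Voronoi cells, the region closer to a station than to
any other — by the departure station of the trips.

Also computed here: per-route time budgets spent above exposure-class
thresholds (e.g. minutes per trip in the "noise > 65 dB" class), the share
of OD pairs for which an exposure-optimal route exists within the detour
cap, the mean exposure change when one does, and the distribution of
detour distances of unconstrained exposure-optimal routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .network import StreetNetwork
from .routing import OptimalRouteResult, Route

logger = logging.getLogger(__name__)

ROUTE_SETS = ("shortest", "aqi", "noise", "gvi")


class PopulationError(Exception):
    pass


@dataclass(frozen=True)
class Station:
    station_id: str
    x: float
    y: float


@dataclass(frozen=True)
class ClassThresholds:
    """Exposure-class cut-offs for time-budget statistics (strict '>')."""

    aqi_gt: float = 2.0
    noise_gt_db: float = 65.0
    gvi_gt: float = 0.2


def load_stations_csv(path) -> list[Station]:
    df = pd.read_csv(path, dtype={"station_id": str})
    stations = [
        Station(str(r.station_id), float(r.x), float(r.y)) for r in df.itertuples()
    ]
    if len({s.station_id for s in stations}) != len(stations):
        raise PopulationError("duplicate station ids")
    return stations


def write_stations_csv(stations: list[Station], path) -> None:
    pd.DataFrame(
        [(s.station_id, s.x, s.y) for s in stations],
        columns=["station_id", "x", "y"],
    ).to_csv(path, index=False)


class TripTable:
    """OD trip counts; self-loop rows are dropped with a logged count."""

    def __init__(self, df: pd.DataFrame, stations: list[Station] | None = None):
        df = df.copy()
        df["origin_station"] = df["origin_station"].astype(str)
        df["destination_station"] = df["destination_station"].astype(str)
        if (df["trip_count"] < 0).any():
            raise PopulationError("negative trip counts")
        self_loops = df["origin_station"] == df["destination_station"]
        if self_loops.any():
            logger.info("dropping %d self-loop OD rows", int(self_loops.sum()))
            df = df[~self_loops]
        if stations is not None:
            known = {s.station_id for s in stations}
            bad = (set(df["origin_station"]) | set(df["destination_station"])) - known
            if bad:
                raise PopulationError(f"trips reference unknown stations: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, stations: list[Station] | None = None) -> "TripTable":
        return cls(pd.read_csv(path), stations)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def total_trips(self) -> int:
        return int(self.df["trip_count"].sum())

    def pairs(self) -> list[tuple[str, str]]:
        return list(
            self.df[["origin_station", "destination_station"]].itertuples(
                index=False, name=None
            )
        )

    def count(self, origin: str, dest: str) -> int:
        m = (self.df["origin_station"] == origin) & (
            self.df["destination_station"] == dest
        )
        return int(self.df.loc[m, "trip_count"].sum())


def ordered_od_pair_count(n_stations: int) -> int:
    """Number of ordered OD pairs excluding self-pairs: k * (k - 1)."""
    if n_stations < 0:
        raise PopulationError("station count must be non-negative")
    return n_stations * (n_stations - 1)


# ---------------------------------------------------------------------------
# Per-route summaries


def route_summary(
    net: StreetNetwork,
    route: Route,
    speed_kmh: float = 15.0,
    thresholds: ClassThresholds = ClassThresholds(),
) -> dict:
    """Exposure means and exposure-class minute budgets for one route.

    Trip time assumes a constant cycling speed; an edge contributes its
    travel minutes to a class budget when its mean exposure exceeds the
    class threshold (strict '>').
    """
    if speed_kmh <= 0:
        raise PopulationError("speed must be positive")
    m_per_min = speed_kmh * 1000.0 / 60.0
    minutes = {"aqi_gt": 0.0, "noise_gt_db": 0.0, "gvi_gt": 0.0}
    for eid in route.edge_ids:
        edge = net.edges[eid]
        vals = {
            "aqi_gt": (edge.aqi, thresholds.aqi_gt),
            "noise_gt_db": (edge.noise_db, thresholds.noise_gt_db),
            "gvi_gt": (edge.gvi, thresholds.gvi_gt),
        }
        for key, (val, thr) in vals.items():
            if val is None:
                raise PopulationError(
                    f"edge {eid!r} missing exposure for class budget; impute first"
                )
            if val > thr:
                minutes[key] += edge.length / m_per_min
    return {
        "length_m": route.length,
        "total_minutes": route.length / m_per_min,
        "mean_aqi": route.mean_aqi,
        "mean_noise_db": route.mean_noise_db,
        "mean_gvi": route.mean_gvi,
        "minutes_aqi_gt": minutes["aqi_gt"],
        "minutes_noise_gt_db": minutes["noise_gt_db"],
        "minutes_gvi_gt": minutes["gvi_gt"],
        "speed_kmh": speed_kmh,
    }


# ---------------------------------------------------------------------------
# Voronoi catchments


def voronoi_catchments(
    stations: list[Station],
    boundary: tuple[float, float, float, float],
) -> dict[str, "object"]:
    """Voronoi cell per station, clipped to a rectangular study boundary.

    Every interior point of a cell is nearer (Euclidean) to its station
    than to any other; the cells partition the boundary exactly.
    """
    if not stations:
        raise PopulationError("need at least one station")
    coords = [(s.x, s.y) for s in stations]
    if len(set(coords)) != len(coords):
        raise PopulationError("duplicate station coordinates")
    env = box(*boundary)
    for s in stations:
        if not env.covers(Point(s.x, s.y)):
            raise PopulationError(f"station {s.station_id} outside boundary")
    if len(stations) == 1:
        return {stations[0].station_id: env}
    cells = voronoi_diagram(MultiPoint(coords), envelope=env)
    out: dict[str, object] = {}
    remaining = list(cells.geoms)
    for s in stations:
        p = Point(s.x, s.y)
        hit = min(remaining, key=lambda g: g.distance(p))
        out[s.station_id] = hit.intersection(env)
    if len(out) != len(stations):
        raise PopulationError("Voronoi cell assignment failed")
    return out


# ---------------------------------------------------------------------------
# Aggregation to departure stations


def aggregate_by_station(
    summaries: pd.DataFrame,
    trips: TripTable,
    weighted: bool,
) -> pd.DataFrame:
    """Mean exposures of departing trips per station and route set.

    ``summaries`` must hold one row per (origin_station,
    destination_station, route_set) with mean_aqi / mean_noise_db /
    mean_gvi / length_m columns.  Unweighted aggregation averages over OD
    pairs; trip-weighted aggregation weights each pair by its trip count.
    """
    routed = set(
        summaries[["origin_station", "destination_station"]].itertuples(
            index=False, name=None
        )
    )
    missing = [p for p in trips.pairs() if p not in routed]
    if missing:
        raise PopulationError(f"trips reference unrouted OD pairs: {missing[:5]}")

    df = summaries.merge(
        trips.df, on=["origin_station", "destination_station"], how="left"
    )
    df["trip_count"] = df["trip_count"].fillna(0).astype(float)
    value_cols = ["mean_aqi", "mean_noise_db", "mean_gvi", "length_m"]

    records = []
    for (station, route_set), grp in df.groupby(
        ["origin_station", "route_set"], sort=True
    ):
        if weighted:
            w = grp["trip_count"].to_numpy()
            if w.sum() == 0:
                continue
        else:
            w = np.ones(len(grp))
        rec = {
            "station_id": station,
            "route_set": route_set,
            "trip_weighted": weighted,
            "n_od_pairs": len(grp),
            "n_trips": int(grp["trip_count"].sum()),
        }
        for col in value_cols:
            rec[col] = float(np.average(grp[col].to_numpy(), weights=w))
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Availability of exposure-optimal routes, Table-style summary


def availability_and_change(
    results: dict[tuple[str, str], dict[str, OptimalRouteResult]],
    trips: TripTable,
) -> pd.DataFrame:
    """Share of OD pairs/trips with an improving optimal route, and the
    conditional mean exposure change, mean distance and mean additional
    distance — unweighted and trip-weighted rows per exposure type, plus
    the shortest-route reference rows.
    """
    counts = {
        (o, d): c
        for o, d, c in trips.df[
            ["origin_station", "destination_station", "trip_count"]
        ].itertuples(index=False, name=None)
    }
    pairs = sorted(results)
    rows = []
    for weighted in (False, True):
        w = np.array(
            [counts.get(p, 0) if weighted else 1.0 for p in pairs], dtype=float
        )
        if w.sum() == 0:
            continue
        # shortest reference
        any_exp = next(iter(results[pairs[0]]))
        shortest = [results[p][any_exp].shortest for p in pairs]
        rows.append(
            {
                "route_set": "shortest",
                "trip_weighted": weighted,
                "share_improved_pct": np.nan,
                "mean_exposure_change": np.nan,
                "mean_aqi": _wmean([r.mean_aqi for r in shortest], w),
                "mean_noise_db": _wmean([r.mean_noise_db for r in shortest], w),
                "mean_gvi": _wmean([r.mean_gvi for r in shortest], w),
                "mean_distance_m": _wmean([r.length for r in shortest], w),
                "mean_additional_distance_m": np.nan,
                "n_improved": 0,
                "n": len(pairs),
            }
        )
        for exp in ("aqi", "noise", "gvi"):
            res = [results[p][exp] for p in pairs]
            improved = np.array([r.improved for r in res], dtype=bool)
            share = 100.0 * float(w[improved].sum()) / float(w.sum())
            if improved.any():
                wi = w[improved]
                # guard: all-improving pairs may carry zero trips
                wi_ok = wi.sum() > 0
                changes = np.array([r.exposure_change for r in res])[improved]
                extra = np.array(
                    [r.optimal.length - r.shortest.length for r in res]
                )[improved]
                mean_change = (
                    float(np.average(changes, weights=wi)) if wi_ok else np.nan
                )
                mean_extra = float(np.average(extra, weights=wi)) if wi_ok else np.nan
            else:
                mean_change = np.nan
                mean_extra = np.nan
            opt = [r.optimal for r in res]
            rows.append(
                {
                    "route_set": exp,
                    "trip_weighted": weighted,
                    "share_improved_pct": share,
                    "mean_exposure_change": mean_change,
                    "mean_aqi": _wmean([r.mean_aqi for r in opt], w),
                    "mean_noise_db": _wmean([r.mean_noise_db for r in opt], w),
                    "mean_gvi": _wmean([r.mean_gvi for r in opt], w),
                    "mean_distance_m": _wmean([r.length for r in opt], w),
                    "mean_additional_distance_m": mean_extra,
                    "n_improved": int(improved.sum()),
                    "n": len(pairs),
                }
            )
    return pd.DataFrame(rows)


def _wmean(values, w) -> float:
    vals = np.array([np.nan if v is None else v for v in values], dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any() or w[ok].sum() == 0:
        return float("nan")
    return float(np.average(vals[ok], weights=np.asarray(w)[ok]))


# ---------------------------------------------------------------------------
# Detour distributions


def detour_distribution(
    unconstrained_detours: dict[tuple[str, str], dict[str, float]],
    trips: TripTable,
    max_detour: float = 0.15,
    bin_width: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of detour fractions of unconstrained optimal routes.

    ``unconstrained_detours`` maps OD pair -> exposure type -> the detour
    fraction of the maximal-improvement route ignoring the detour cap.
    Returns (histogram, shares): the histogram of detour fractions per
    exposure type (unweighted and trip-weighted counts), and the share of
    OD pairs / trips whose maximal-improvement route lies within the cap.
    """
    counts = {
        (o, d): c
        for o, d, c in trips.df[
            ["origin_station", "destination_station", "trip_count"]
        ].itertuples(index=False, name=None)
    }
    pairs = sorted(unconstrained_detours)
    hist_rows, share_rows = [], []
    for exp in ("aqi", "noise", "gvi"):
        det = np.array([unconstrained_detours[p][exp] for p in pairs])
        w = np.array([counts.get(p, 0) for p in pairs], dtype=float)
        top = max(float(det.max()), max_detour) if len(det) else max_detour
        edges = np.arange(0.0, top + bin_width, bin_width)
        if edges[-1] < top:
            edges = np.append(edges, top)
        idx = np.clip(np.digitize(det, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            mask = idx == b
            hist_rows.append(
                {
                    "exposure_type": exp,
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "count": int(mask.sum()),
                    "trip_weighted_count": float(w[mask].sum()),
                }
            )
        within = det <= max_detour * (1.0 + 1e-6)
        share_rows.append(
            {
                "exposure_type": exp,
                "share_within_pct": 100.0 * within.mean() if len(det) else np.nan,
                "trip_weighted_share_within_pct": (
                    100.0 * w[within].sum() / w.sum() if w.sum() else np.nan
                ),
                "n": len(det),
            }
        )
    return pd.DataFrame(hist_rows), pd.DataFrame(share_rows)
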