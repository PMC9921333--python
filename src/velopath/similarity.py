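"""Spatial similarity of exposure-optimal routes and exposure correlations.

Two routes are spatially compared by buffering each polyline by a small
radius (5 m by default) and measuring the overlap of the buffer polygons.
The default overlap measure is the Jaccard index, area(A ∩ B)/area(A ∪ B);
intersection-over-mean-area is available as an alternative since the
"shared proportion" denominator is a genuine modelling choice — outputs
are labelled with the measure used.

Exposure linkage across routes is measured with the Pearson correlation of
route-mean AQI, noise and GVI values over all OD pairs, per route set
(shortest, AQI-optimal, noise-optimal, GVI-optimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString

logger = logging.getLogger(__name__)

EXPOSURE_PAIRS = (("aqi", "noise"), ("aqi", "gvi"), ("noise", "gvi"))
MEAN_COLS = {"aqi": "mean_aqi", "noise": "mean_noise_db", "gvi": "mean_gvi"}


class SimilarityError(Exception):
    pass


def buffer_route(geometry: LineString, radius: float = 5.0):
    """Planar buffer with round joins and round end caps."""
    if radius <= 0:
        raise SimilarityError("buffer radius must be positive")
    if geometry.length <= 0:
        raise SimilarityError("cannot buffer a zero-length geometry")
    return geometry.buffer(radius, quad_segs=16, cap_style="round", join_style="round")


def shared_route_proportion(buf_a, buf_b, measure: str = "jaccard") -> float:
    """Overlap fraction of two route buffers, in [0, 1], symmetric.

    ``measure="jaccard"``: area(A ∩ B) / area(A ∪ B).
    ``measure="mean"``:    area(A ∩ B) / mean(area(A), area(B)).
    """
    if buf_a.is_empty or buf_b.is_empty or not buf_a.is_valid or not buf_b.is_valid:
        raise SimilarityError("invalid or empty buffer polygon")
    inter = buf_a.intersection(buf_b).area
    if measure == "jaccard":
        denom = buf_a.union(buf_b).area
    elif measure == "mean":
        denom = 0.5 * (buf_a.area + buf_b.area)
    else:
        raise SimilarityError(f"unknown overlap measure {measure!r}")
    return min(inter / denom, 1.0) if denom > 0 else 0.0


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN when either input has
    zero variance (flagged with a warning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise SimilarityError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance input: Pearson r undefined")
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Pipeline-level products


def route_similarity_records(
    geometries: dict[tuple[str, str], dict[str, LineString]],
    radius: float = 5.0,
    measure: str = "jaccard",
) -> pd.DataFrame:
    """Pairwise buffer-overlap proportions per OD pair.

    ``geometries`` maps OD pair -> exposure type ("aqi"/"noise"/"gvi") ->
    route geometry; when an exposure had no improving route the shortest
    route's geometry stands in for that exposure's optimal route.
    """
    rows = []
    for (origin, dest), geoms in sorted(geometries.items()):
        buffers = {exp: buffer_route(g, radius) for exp, g in geoms.items()}
        for a, b in EXPOSURE_PAIRS:
            rows.append(
                {
                    "origin_station": origin,
                    "destination_station": dest,
                    "pair_type": f"{a}-{b}",
                    "shared_proportion": shared_route_proportion(
                        buffers[a], buffers[b], measure
                    ),
                    "measure": measure,
                }
            )
    return pd.DataFrame(rows)


def catchment_similarity(
    records: pd.DataFrame,
    trips,
) -> pd.DataFrame:
    """Trip-weighted mean shared proportion per departure station and pair."""
    counts = trips.df.rename(columns={"trip_count": "_w"})
    df = records.merge(
        counts, on=["origin_station", "destination_station"], how="left"
    )
    df["_w"] = df["_w"].fillna(0).astype(float)
    rows = []
    for (station, pair), grp in df.groupby(["origin_station", "pair_type"], sort=True):
        w = grp["_w"].to_numpy()
        unweighted = float(grp["shared_proportion"].mean())
        weighted = (
            float(np.average(grp["shared_proportion"], weights=w))
            if w.sum() > 0
            else float("nan")
        )
        rows.append(
            {
                "station_id": station,
                "pair_type": pair,
                "mean_shared_proportion": unweighted,
                "trip_weighted_mean_shared_proportion": weighted,
                "n_od_pairs": len(grp),
            }
        )
    return pd.DataFrame(rows)


def exposure_correlations(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between route-mean exposures, per route set.

    ``summaries`` holds one row per (OD pair, route_set) with mean
    exposure columns; each route set (shortest and the three optimal
    variants) yields three correlation records (AQI-noise, AQI-GVI,
    noise-GVI).
    """
    rows = []
    for route_set, grp in summaries.groupby("route_set", sort=True):
        for a, b in EXPOSURE_PAIRS:
            x = grp[MEAN_COLS[a]].to_numpy(dtype=float)
            y = grp[MEAN_COLS[b]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            r = pearson_r(x[ok], y[ok]) if ok.sum() >= 3 else float("nan")
            rows.append(
                {
                    "route_set": route_set,
                    "pair": f"{a}-{b}",
                    "r": r,
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)
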