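"""Attach exposure values to network edges and normalise them into costs.

Three exposure sources are supported, mirroring the layers a city typically
publishes:

* an air-quality index raster (regular grid, AQI 1-5, ESRI ASCII format);
* a noise polygon layer (Lden dB bands as planar polygons);
* a per-edge greenery table (Green View Index, fraction of visible
  vegetation in street-level imagery, 0-1).

Each raw exposure value is normalised into an environmental cost
coefficient ``ce`` in [0, 1] that feeds the impedance function of the
routing module: 0 means no environmental penalty, 1 the maximum penalty.
Greenery is a benefit, so its coefficient is inverted (greener = cheaper).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from shapely.geometry import LineString
from shapely.ops import unary_union
from shapely.prepared import prep

from .network import EXPOSURE_RANGES, StreetNetwork

logger = logging.getLogger(__name__)


class ExposureError(Exception):
    pass


# ---------------------------------------------------------------------------
# Raster grid (ESRI ASCII)


@dataclass
class RasterGrid:
    """North-up regular grid of AQI values (row 0 = northernmost row)."""

    origin_x: float  # x of the lower-left corner
    origin_y: float  # y of the lower-left corner
    cell_size: float
    values: np.ndarray  # 2-D, row-major, row 0 at the top (north)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ExposureError("cell_size must be positive")
        valid = self.values[self.values != self.nodata]
        if valid.size and (valid.min() < 1.0 or valid.max() > 5.0):
            raise ExposureError("AQI raster values must lie in [1, 5]")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def sample(self, x: float, y: float) -> float | None:
        """Value of the cell containing (x, y); None outside / nodata."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row_from_bottom = int(math.floor((y - self.origin_y) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            return None
        val = self.values[row, col]
        return None if val == self.nodata else float(val)


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ExposureError(f"{path}: missing ESRI ASCII header field {key}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(grid.origin_x)!r}\n")
        fh.write(f"yllcorner {float(grid.origin_y)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def sample_raster_along_edge(
    grid: RasterGrid, geometry: LineString, interval: float = 5.0
) -> float | None:
    """Mean grid value at points every ``interval`` m along the polyline.

    Endpoints are always included.  Nodata / out-of-grid samples are
    dropped; if every sample is nodata the edge value is missing (None).
    The default 5 m interval is well below typical cell sizes (13 m for
    the AQI layer), making the mean an accurate length weighting.
    """
    if interval <= 0:
        raise ExposureError("sampling interval must be positive")
    length = geometry.length
    if length <= 0:
        raise ExposureError("cannot sample a zero-length geometry")
    n = max(1, int(math.ceil(length / interval)))
    distances = np.linspace(0.0, length, n + 1)
    samples = []
    for d in distances:
        p = geometry.interpolate(float(d))
        val = grid.sample(p.x, p.y)
        if val is not None:
            samples.append(val)
    if not samples:
        logger.warning("edge entirely over nodata / outside raster extent")
        return None
    return float(np.mean(samples))


# ---------------------------------------------------------------------------
# Noise polygons


@dataclass
class NoisePolygonLayer:
    """Lden dB polygons; overlapping polygons resolve to the max dB.

    The max-wins rule is the conservative, health-oriented reading: at a
    point covered by several modelled noise bands the loudest applies.
    """

    polygons: list  # list of (shapely polygon, lden_db)
    background_db: float = 40.0

    def __post_init__(self) -> None:
        for _, db in self.polygons:
            if not (0.0 <= db <= 120.0):
                raise ExposureError(f"Lden {db} dB outside [0, 120]")


def load_noise_geojson(path, background_db: float = 40.0) -> NoisePolygonLayer:
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    polys = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        polys.append((geom, float(feat["properties"]["lden_db"])))
    return NoisePolygonLayer(polygons=polys, background_db=background_db)


def write_noise_geojson(layer: NoisePolygonLayer, path) -> None:
    import json

    from shapely.geometry import mapping

    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"lden_db": db},
        }
        for geom, db in layer.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def assign_noise(layer: NoisePolygonLayer, geometry: LineString) -> float:
    """Length-weighted arithmetic mean Lden along a polyline.

    Portions covered by several polygons take the maximum dB among them;
    uncovered portions contribute the configurable background level.
    Averaging is arithmetic in dB (an energetic mean in pascals is offered
    by :func:`assign_noise_energetic`), matching how mean route noise is
    conventionally reported and thresholded.
    """
    return _assign_noise(layer, geometry, energetic=False)


def assign_noise_energetic(layer: NoisePolygonLayer, geometry: LineString) -> float:
    """Energetic (logarithmic) length-weighted mean Lden along a polyline."""
    return _assign_noise(layer, geometry, energetic=True)


def _assign_noise(
    layer: NoisePolygonLayer, geometry: LineString, energetic: bool
) -> float:
    total = geometry.length
    if total <= 0:
        raise ExposureError("cannot assign noise to a zero-length geometry")
    # max-wins overlap: peel the line from the loudest polygon downwards
    contributions: list[tuple[float, float]] = []  # (length, dB)
    remaining = geometry
    for geom, db in sorted(layer.polygons, key=lambda t: -t[1]):
        if remaining.is_empty:
            break
        seg = remaining.intersection(geom)
        if not seg.is_empty and seg.length > 0:
            contributions.append((seg.length, db))
            remaining = remaining.difference(geom)
    if not remaining.is_empty and remaining.length > 0:
        contributions.append((remaining.length, layer.background_db))
    lengths = np.array([l for l, _ in contributions])
    dbs = np.array([d for _, d in contributions])
    w = lengths / lengths.sum()
    if energetic:
        return float(10.0 * np.log10(np.sum(w * 10.0 ** (dbs / 10.0))))
    return float(np.sum(w * dbs))


# ---------------------------------------------------------------------------
# GVI table


@dataclass
class GviTable:
    values: Mapping[str, float]  # edge_id -> gvi in [0, 1]

    def __post_init__(self) -> None:
        for eid, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ExposureError(f"GVI {v} for edge {eid!r} outside [0, 1]")


def load_gvi_csv(path) -> GviTable:
    import pandas as pd

    df = pd.read_csv(path, dtype={"edge_id": str})
    return GviTable(values=dict(zip(df["edge_id"], df["gvi"].astype(float))))


def attach_gvi(table: GviTable, net: StreetNetwork) -> StreetNetwork:
    """Attach GVI values by edge id; unmatched edges stay missing.

    Table entries whose edge id does not exist in the network are ignored
    with a logged count (they typically come from a larger source extent).
    """
    unknown = set(table.values) - set(net.edges)
    if unknown:
        logger.warning("GVI table has %d ids not in the network; ignored", len(unknown))
    for eid, edge in net.edges.items():
        if eid in table.values:
            edge.gvi = float(table.values[eid])
        else:
            edge.gvi = None
    return net


# ---------------------------------------------------------------------------
# Imputation


def impute_missing(net: StreetNetwork, exposure_type: str) -> StreetNetwork:
    """Fill missing edge values with the length-weighted network median.

    The length-weighted median is the value at which half the valued
    network length lies at or below; it is robust to a few extreme edges
    and keeps the imputed value inside the observed range.
    """
    valued = [
        (e.length, e.exposure(exposure_type))
        for e in net.edges.values()
        if e.exposure(exposure_type) is not None
    ]
    if not valued:
        raise ExposureError(
            f"cannot impute {exposure_type}: no edge carries a value"
        )
    order = np.argsort([v for _, v in valued], kind="stable")
    lengths = np.array([valued[i][0] for i in order])
    values = np.array([valued[i][1] for i in order])
    cum = np.cumsum(lengths)
    median = float(values[np.searchsorted(cum, 0.5 * cum[-1])])
    n_imputed = 0
    for e in net.edges.values():
        if e.exposure(exposure_type) is None:
            e.set_exposure(exposure_type, median)
            n_imputed += 1
    if n_imputed:
        logger.info(
            "imputed %s on %d/%d edges (length-weighted median %.4g)",
            exposure_type, n_imputed, net.n_edges, median,
        )
    return net


# ---------------------------------------------------------------------------
# Cost coefficients


@dataclass(frozen=True)
class CostCoefficient:
    """Normalised environmental cost ``ce`` in [0, 1] for one exposure."""

    exposure_type: str
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ExposureError(f"cost coefficient {self.value} outside [0, 1]")


@dataclass(frozen=True)
class CoefficientMapping:
    """Raw-exposure -> ce normalisations (config-overridable).

    * AQI 1 (good) .. 5 (very poor) maps linearly to 0..1.
    * Noise ramps linearly from ``noise_lo`` to ``noise_hi`` dB, clamped;
      the defaults (45-75) place the 55 dB high-daytime-noise threshold at
      ce = 1/3.
    * GVI is a benefit: ce = 1 - GVI, so greener streets are cheaper.
    """

    noise_lo: float = 45.0
    noise_hi: float = 75.0

    def __call__(self, exposure_type: str, value: float) -> CostCoefficient:
        lo, hi = EXPOSURE_RANGES[exposure_type]
        if not (lo <= value <= hi):
            raise ExposureError(
                f"{exposure_type} value {value} outside valid range [{lo}, {hi}]"
            )
        if exposure_type == "aqi":
            ce = (value - 1.0) / 4.0
        elif exposure_type == "noise":
            ce = min(max((value - self.noise_lo) / (self.noise_hi - self.noise_lo), 0.0), 1.0)
        elif exposure_type == "gvi":
            ce = 1.0 - value
        else:
            raise ExposureError(f"unknown exposure type {exposure_type!r}")
        return CostCoefficient(exposure_type=exposure_type, value=ce)


DEFAULT_MAPPING = CoefficientMapping()


def cost_coefficient(exposure_type: str, value: float) -> CostCoefficient:
    """Normalise a raw exposure value with the default mapping."""
    return DEFAULT_MAPPING(exposure_type, value)
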