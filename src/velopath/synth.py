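"""Synthetic city generator.

Produces statistically realistic inputs for the whole pipeline without any
external download: a jittered grid street network, three cross-correlated
exposure surfaces (AQI, Lden noise, GVI), docking stations densest near
the city centre, and a gravity-model trip table.

The exposure surfaces are smoothed Gaussian random fields linearly mixed
(Cholesky) so that AQI and noise are positively correlated while GVI is
negatively correlated with both — the structure observed along real
cycling routes, where traffic produces pollution and noise together and
vegetated streets carry less traffic.  A radial "city-centre" gradient
additionally raises AQI and noise and lowers greenery toward the centre.

Everything is driven by one seeded :class:`numpy.random.Generator`, so an
identical :class:`CityConfig` yields bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from .exposure import NoisePolygonLayer, RasterGrid
from .network import Edge, Node, StreetNetwork
from .population import Station, TripTable

logger = logging.getLogger(__name__)

#: default cross-correlation targets for the three exposure fields,
#: chosen near the correlations observed along shortest cycling routes
DEFAULT_TARGET_CORR = {"aqi-noise": 0.7, "aqi-gvi": -0.5, "noise-gvi": -0.4}

#: planar offset so synthetic coordinates never fit lon/lat bounds
BASE_XY = 10_000.0


class SynthError(Exception):
    pass


@dataclass(frozen=True)
class CityConfig:
    """Study conditions for one synthetic city.

    Defaults describe a compact bike-share service area: a 12 x 12 node
    grid at 100 m spacing (~1.2 km side), 20 docking stations and 50,000
    trips over the season — the real system's structure (242 stations,
    3.1 M trips) at desk scale.
    """

    grid_n: int = 12
    spacing: float = 100.0
    jitter: float = 10.0
    seed: int = 0
    field_smoothing: float = 2.0  # Gaussian kernel sigma, in lattice cells
    target_corr: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_CORR))
    centre_amp: float = 1.0  # strength of the radial city-centre gradient
    n_stations: int = 20
    gravity_beta: float = 1e-3  # distance decay, 1/m (decay length 1 km)
    total_trips: int = 50_000
    ring_road: bool = False  # plant a quiet-and-green ring around a loud core

    def __post_init__(self) -> None:
        if self.grid_n < 2:
            raise SynthError("grid_n must be >= 2")
        if self.spacing <= 0:
            raise SynthError("spacing must be positive")
        if self.total_trips < 0:
            raise SynthError("total_trips must be >= 0")
        for k, v in self.target_corr.items():
            if not (-1.0 < v < 1.0):
                raise SynthError(f"target correlation {k}={v} outside (-1, 1)")
        if self.n_stations > self.grid_n**2:
            raise SynthError("more stations than nodes")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Network


def generate_network(cfg: CityConfig) -> StreetNetwork:
    """Jittered grid graph: grid_n^2 nodes, 2*grid_n*(grid_n-1) edges."""
    rng = cfg.rng()
    n = cfg.grid_n
    jitter = min(cfg.jitter, 0.45 * cfg.spacing)  # keep the grid planar
    xs = BASE_XY + np.arange(n) * cfg.spacing
    ys = BASE_XY + np.arange(n) * cfg.spacing
    dx = rng.uniform(-jitter, jitter, size=(n, n))
    dy = rng.uniform(-jitter, jitter, size=(n, n))

    net = StreetNetwork()
    def nid(r: int, c: int) -> str:
        return f"n{r:03d}_{c:03d}"

    for r in range(n):
        for c in range(n):
            net.add_node(Node(id=nid(r, c), x=float(xs[c] + dx[r, c]),
                              y=float(ys[r] + dy[r, c])))
    eidx = 0
    for r in range(n):
        for c in range(n):
            for (r2, c2) in ((r, c + 1), (r + 1, c)):
                if r2 >= n or c2 >= n:
                    continue
                a, b = net.nodes[nid(r, c)], net.nodes[nid(r2, c2)]
                net.add_edge(
                    Edge(
                        id=f"e{eidx:05d}",
                        u=a.id,
                        v=b.id,
                        geometry=LineString([(a.x, a.y), (b.x, b.y)]),
                    )
                )
                eidx += 1
    return net


# ---------------------------------------------------------------------------
# Exposure fields


def _corr_matrix(target: dict) -> np.ndarray:
    c = np.array(
        [
            [1.0, target["aqi-noise"], target["aqi-gvi"]],
            [target["aqi-noise"], 1.0, target["noise-gvi"]],
            [target["aqi-gvi"], target["noise-gvi"], 1.0],
        ]
    )
    if np.linalg.eigvalsh(c).min() <= 0:
        raise SynthError("target correlation matrix is not positive definite")
    return c


def _standardise(f: np.ndarray) -> np.ndarray:
    sd = f.std()
    if sd < 1e-12:
        return np.zeros_like(f)  # degenerate (e.g. infinite smoothing)
    return (f - f.mean()) / sd


def _lattice(cfg: CityConfig, net: StreetNetwork):
    minx, miny, maxx, maxy = net.bounds()
    cell = cfg.spacing / 2.0
    pad = cell
    ox, oy = minx - pad, miny - pad
    ncols = int(np.ceil((maxx + pad - ox) / cell)) + 1
    nrows = int(np.ceil((maxy + pad - oy) / cell)) + 1
    return ox, oy, cell, nrows, ncols


def generate_exposure_fields(cfg: CityConfig, net: StreetNetwork) -> StreetNetwork:
    """Attach correlated AQI / noise / GVI values to every edge.

    Three iid normal lattices are smoothed, standardised, mixed through
    the Cholesky factor of the target correlation matrix, shifted by the
    radial centre gradient, and mapped into valid ranges (AQI ~ 1.9 mean,
    noise ~ 62 dB, GVI ~ 0.25).  Each edge takes the lattice value at its
    midpoint.  If smoothing flattens a lattice completely (the infinite-
    smoothing limit) the whole surface degenerates to a constant, centre
    gradient included.
    """
    rng = cfg.rng()
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from jitter draws
    ox, oy, cell, nrows, ncols = _lattice(cfg, net)

    raw = rng.standard_normal(size=(3, nrows, ncols))
    # a correlation length at or beyond the lattice extent leaves no
    # spatial variation: the limit is a constant field by construction
    degenerate = cfg.field_smoothing >= max(nrows, ncols)
    if degenerate:
        std = np.zeros_like(raw)
    else:
        smooth = np.stack(
            [gaussian_filter(raw[i], sigma=cfg.field_smoothing, mode="reflect")
             for i in range(3)]
        )
        std = np.stack([_standardise(s) for s in smooth])

    L = np.linalg.cholesky(_corr_matrix(cfg.target_corr))
    z = np.einsum("ij,jrc->irc", L, std)

    # radial centre gradient: loud/polluted core, greener periphery
    if not degenerate and cfg.centre_amp != 0:
        yy, xx = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
        r = np.hypot(xx - cx, yy - cy)
        g = _standardise(-(r / max(r.max(), 1.0)))
        z[0] += cfg.centre_amp * g
        z[1] += cfg.centre_amp * g
        z[2] -= cfg.centre_amp * g
        z = np.stack([_standardise(f) if f.std() > 1e-12 else f for f in z])

    aqi = np.clip(1.9 + 0.5 * z[0], 1.0, 5.0)
    noise = np.clip(62.0 + 7.0 * z[1], 45.0, 80.0)
    gvi = np.clip(0.25 + 0.12 * z[2], 0.0, 0.6)

    def at(x: float, y: float, grid: np.ndarray) -> float:
        c = int(np.clip((x - ox) // cell, 0, ncols - 1))
        r = int(np.clip((y - oy) // cell, 0, nrows - 1))
        return float(grid[nrows - 1 - r, c])  # stored north-up

    # lattices are built south-up here; flip to the north-up convention
    aqi_nu, noise_nu, gvi_nu = aqi[::-1], noise[::-1], gvi[::-1]
    for edge in net.edges.values():
        mid = edge.geometry.interpolate(0.5, normalized=True)
        edge.aqi = at(mid.x, mid.y, aqi_nu)
        edge.noise_db = at(mid.x, mid.y, noise_nu)
        edge.gvi = at(mid.x, mid.y, gvi_nu)

    if cfg.ring_road:
        _plant_ring_road(cfg, net)

    # stash the lattices so matching rasters / polygons can be emitted
    net._synthetic_fields = {  # type: ignore[attr-defined]
        "origin": (ox, oy),
        "cell": cell,
        "aqi": aqi_nu.copy(),
        "noise": noise_nu.copy(),
        "gvi": gvi_nu.copy(),
    }
    return net


def _plant_ring_road(cfg: CityConfig, net: StreetNetwork) -> None:
    """Plant a loud, polluted, grey core and a quiet green ring around it."""
    minx, miny, maxx, maxy = net.bounds()
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    half = max(maxx - minx, maxy - miny) / 2.0
    for edge in net.edges.values():
        mid = edge.geometry.interpolate(0.5, normalized=True)
        rnorm = np.hypot(mid.x - cx, mid.y - cy) / half
        if rnorm < 0.45:
            edge.noise_db, edge.aqi, edge.gvi = 76.0, 3.2, 0.05
        elif 0.55 <= rnorm <= 0.85:
            edge.noise_db, edge.aqi, edge.gvi = 46.0, 1.2, 0.55


def aqi_raster(net: StreetNetwork) -> RasterGrid:
    """ESRI-ASCII-ready AQI raster matching the generated lattice."""
    f = getattr(net, "_synthetic_fields", None)
    if f is None:
        raise SynthError("generate_exposure_fields must run first")
    return RasterGrid(
        origin_x=f["origin"][0],
        origin_y=f["origin"][1],
        cell_size=f["cell"],
        values=f["aqi"],
    )


def noise_polygons(net: StreetNetwork, band_db: float = 5.0) -> NoisePolygonLayer:
    """Noise layer: lattice cells quantised into dB bands and unioned."""
    f = getattr(net, "_synthetic_fields", None)
    if f is None:
        raise SynthError("generate_exposure_fields must run first")
    ox, oy = f["origin"]
    cell = f["cell"]
    noise = f["noise"]  # north-up
    nrows, ncols = noise.shape
    bands: dict[float, list] = {}
    for r in range(nrows):
        for c in range(ncols):
            db = float(np.floor(noise[r, c] / band_db) * band_db + band_db / 2.0)
            y0 = oy + (nrows - 1 - r) * cell
            x0 = ox + c * cell
            bands.setdefault(db, []).append(box(x0, y0, x0 + cell, y0 + cell))
    polys = []
    for db in sorted(bands):
        merged = unary_union(bands[db])
        geoms = getattr(merged, "geoms", [merged])
        for g in geoms:
            polys.append((g, db))
    return NoisePolygonLayer(polygons=polys)


# ---------------------------------------------------------------------------
# Stations and trips


def generate_stations_and_trips(
    cfg: CityConfig, net: StreetNetwork
) -> tuple[list[Station], TripTable]:
    """Stations on distinct nodes (denser near the centre) and a gravity
    trip table: counts drawn multinomially over ordered OD pairs with
    weights exp(-gravity_beta * distance), self-pairs excluded."""
    import pandas as pd

    rng = cfg.rng()
    rng = np.random.default_rng(rng.integers(2**31) + 1)
    node_ids = sorted(net.nodes)
    coords = np.array([(net.nodes[i].x, net.nodes[i].y) for i in node_ids])
    centre = coords.mean(axis=0)
    d = np.hypot(*(coords - centre).T)
    scale = max(d.max(), 1.0) / 2.0
    p = np.exp(-d / scale)
    p /= p.sum()
    chosen = rng.choice(len(node_ids), size=cfg.n_stations, replace=False, p=p)
    chosen = np.sort(chosen)
    stations = [
        Station(station_id=f"s{j:03d}", x=float(coords[i, 0]), y=float(coords[i, 1]))
        for j, i in enumerate(chosen)
    ]

    pairs = [
        (a.station_id, b.station_id)
        for a in stations
        for b in stations
        if a.station_id != b.station_id
    ]
    if pairs and cfg.total_trips > 0:
        sxy = {s.station_id: (s.x, s.y) for s in stations}
        dist = np.array(
            [np.hypot(sxy[o][0] - sxy[d_][0], sxy[o][1] - sxy[d_][1]) for o, d_ in pairs]
        )
        w = np.exp(-cfg.gravity_beta * dist)
        w /= w.sum()
        counts = rng.multinomial(cfg.total_trips, w)
    else:
        counts = np.zeros(len(pairs), dtype=int)
    df = pd.DataFrame(
        {
            "origin_station": [o for o, _ in pairs],
            "destination_station": [d_ for _, d_ in pairs],
            "trip_count": counts,
        }
    )
    return stations, TripTable(df, stations)


def generate_city(cfg: CityConfig) -> tuple[StreetNetwork, list[Station], TripTable]:
    """Full synthetic city: network with exposures, stations, trips."""
    net = generate_network(cfg)
    generate_exposure_fields(cfg, net)
    stations, trips = generate_stations_and_trips(cfg, net)
    logger.info(
        "synthetic city: %d nodes, %d edges, %d stations, %d trips",
        len(net), net.n_edges, len(stations), trips.total_trips,
    )
    return net, stations, trips


def config_to_yaml(cfg: CityConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_from_yaml(path) -> CityConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return CityConfig(**data)
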