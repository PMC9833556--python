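"""Synthetic geography, surveys, ports and landings.

This module fabricates the four inputs the allocation pipeline consumes —
an EEZ polygon with per-state coastal water strips, seasonal bottom-trawl
survey CPUE records, fishing-port locations, and port-level commercial
landings — with the statistical structure the downstream analysis assumes:
a unimodal (Gaussian) stock density whose centre drifts poleward year by
year and sits further poleward in fall than in spring, observed with
multiplicative lognormal noise at randomly placed survey stations.

The geometry is deliberately idealized: a rectangular EEZ east of a
straight meridian coastline, subdivided latitudinally into equal state
strips.  Every geometric quantity is therefore analytically checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "SEASONS",
    "Geography",
    "StockScenario",
    "GeometryError",
    "make_geography",
    "stock_center",
    "expected_cpue",
    "simulate_surveys",
    "simulate_ports_landings",
    "default_geography",
    "default_scenario",
    "write_geography",
    "read_geography",
]

#: the two bottom-trawl survey campaigns, in simulation order
SEASONS = ("fall", "spring")


class GeometryError(ValueError):
    """Raised for empty or degenerate geometries."""


@dataclass(frozen=True)
class Geography:
    """Idealized coastal geography.

    Attributes
    ----------
    eez : shapely.Polygon
        The exclusive economic zone, a rectangle east of the coastline.
    state_waters : tuple of (state_id, shapely.Polygon)
        One statutory coastal strip per state, ordered south to north.
    coastline_meridian : float
        Longitude of the idealized straight coastline (decimal degrees).
    """

    eez: Polygon
    state_waters: tuple
    coastline_meridian: float

    @property
    def state_ids(self) -> tuple:
        return tuple(sid for sid, _ in self.state_waters)

    def state_polygon(self, state_id: str) -> Polygon:
        for sid, poly in self.state_waters:
            if sid == state_id:
                return poly
        raise KeyError(state_id)


@dataclass(frozen=True)
class StockScenario:
    """Parameters of one simulated stock.

    The expected CPUE field at time ``t`` is an axis-aligned Gaussian bump

        peak_cpue * exp(-1/2 [(lon-c_lon)^2/sd_lon^2 + (lat-c_lat)^2/sd_lat^2])

    whose centre latitude is ``center0_lat + drift*(t - t0)``, plus
    ``seasonal_offset`` in fall.  Observed CPUE multiplies the expectation
    by a LogNormal(0, noise_sd) draw, so values are strictly positive and
    right-skewed, like trawl-survey catch rates.

    Units: positions and spreads in decimal degrees, drift in degrees
    latitude per year, CPUE in kg/ha.
    """

    stock_id: str
    center0: tuple  # (lon, lat) at the first scenario year
    drift: float  # deg latitude / year, poleward
    seasonal_offset: float  # deg latitude added in fall
    spread: tuple  # (sd_lon, sd_lat), degrees
    peak_cpue: float  # kg/ha at the centre, noise-free
    noise_sd: float  # sigma of the multiplicative lognormal noise
    years: tuple  # inclusive (first, last)
    stations_per_year: int  # stations per year *per season*
    seed: int

    def __post_init__(self):
        sd_lon, sd_lat = self.spread
        if sd_lon <= 0 or sd_lat <= 0:
            raise ValueError("spread components must be > 0")
        if self.peak_cpue <= 0:
            raise ValueError("peak_cpue must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stations_per_year < 3:
            raise ValueError("stations_per_year must be >= 3")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")

    @property
    def year_list(self) -> list:
        return list(range(self.years[0], self.years[1] + 1))


def make_geography(
    n_states: int,
    lat_range: tuple,
    eez_width: float = 3.0,
    state_waters_width: float = 0.2,
    seed: int = 0,
    coastline_meridian: float = -74.0,
) -> Geography:
    """Build the idealized geography.

    The EEZ is a rectangle ``eez_width`` degrees wide east of the
    coastline meridian spanning ``lat_range``; it is subdivided into
    ``n_states`` equal-height strips of width ``state_waters_width``
    hugging the coast, labelled ``S01`` (southernmost) upward.

    ``seed`` is accepted for API uniformity; the construction is fully
    deterministic.
    """
    del seed
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    lat0, lat1 = lat_range
    if not lat1 > lat0:
        raise ValueError("lat_range must span > 0 degrees")
    if eez_width <= 0 or state_waters_width <= 0:
        raise ValueError("widths must be > 0")

    lon0 = coastline_meridian
    eez = box(lon0, lat0, lon0 + eez_width, lat1)
    height = (lat1 - lat0) / n_states
    strips = []
    for k in range(n_states):
        sid = f"S{k + 1:02d}"
        strips.append(
            (sid, box(lon0, lat0 + k * height, lon0 + state_waters_width, lat0 + (k + 1) * height))
        )
    return Geography(eez=eez, state_waters=tuple(strips), coastline_meridian=lon0)


def stock_center(scen: StockScenario, year: int, season: str) -> tuple:
    """Centre (lon, lat) of the expected CPUE field for one year-season."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    lon, lat = scen.center0
    lat = lat + scen.drift * (year - scen.years[0])
    if season == "fall":
        lat += scen.seasonal_offset
    return (lon, lat)


def expected_cpue(scen: StockScenario, lon, lat, year: int, season: str):
    """Noise-free expected CPUE (kg/ha) at positions for one year-season."""
    c_lon, c_lat = stock_center(scen, year, season)
    sd_lon, sd_lat = scen.spread
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    z = ((lon - c_lon) / sd_lon) ** 2 + ((lat - c_lat) / sd_lat) ** 2
    return scen.peak_cpue * np.exp(-0.5 * z)


def simulate_surveys(geo: Geography, scen: StockScenario) -> pd.DataFrame:
    """Simulate trawl-survey records for every year x season.

    Stations are uniform inside the EEZ.  Observed CPUE is the Gaussian
    expectation at the station times a LogNormal(0, noise_sd) multiplier.

    Returns a DataFrame with columns
    ``stock, year, season, lon, lat, cpue_kg_ha`` (decimal degrees, kg/ha),
    byte-reproducible for a fixed scenario seed.
    """
    if geo.eez.is_empty:
        raise GeometryError("EEZ polygon is empty")
    rng = np.random.default_rng(scen.seed)
    minx, miny, maxx, maxy = geo.eez.bounds
    rows = []
    n = scen.stations_per_year
    for year in scen.year_list:
        for season in SEASONS:
            # rejection sampling; exits first pass for rectangular EEZs
            lon = np.empty(0)
            lat = np.empty(0)
            while lon.size < n:
                cand_lon = rng.uniform(minx, maxx, size=2 * n)
                cand_lat = rng.uniform(miny, maxy, size=2 * n)
                ok = shapely.covers(geo.eez, shapely.points(cand_lon, cand_lat))
                lon = np.concatenate([lon, cand_lon[ok]])[:n]
                lat = np.concatenate([lat, cand_lat[ok]])[:n]
            mu = expected_cpue(scen, lon, lat, year, season)
            noise = (
                rng.lognormal(mean=0.0, sigma=scen.noise_sd, size=n)
                if scen.noise_sd > 0
                else np.ones(n)
            )
            cpue = mu * noise
            for i in range(n):
                rows.append((scen.stock_id, year, season, lon[i], lat[i], cpue[i]))
    return pd.DataFrame(rows, columns=["stock", "year", "season", "lon", "lat", "cpue_kg_ha"])


def _neighborhood_mean_cpue(scen, lon, lat, year, radius=0.5, k=5):
    """Mean expected CPUE over a small square neighborhood of a point,
    averaged over both seasons (a cheap proxy for the Gaussian integral)."""
    offs = np.linspace(-radius, radius, k)
    gx, gy = np.meshgrid(lon + offs, lat + offs)
    vals = [expected_cpue(scen, gx, gy, year, s).mean() for s in SEASONS]
    return float(np.mean(vals))


def simulate_ports_landings(
    geo: Geography,
    scenarios,
    ports_per_state=3,
    landings_years: tuple | None = None,
    seed: int = 0,
    landings_scale: float = 1e4,
    landings_noise_sd: float = 0.3,
):
    """Simulate fishing ports on the coastline and port-level landings.

    Ports are placed on the coastline meridian at latitudes drawn uniformly
    within each state's band.  Annual landings of each stock at each port
    are proportional to the stock's expected CPUE averaged over a small
    neighborhood of the port (both seasons), times a lognormal draw — so
    ports near the stock's centre land most of the catch.

    Parameters
    ----------
    scenarios : StockScenario or sequence of StockScenario
    ports_per_state : int or mapping state_id -> int
    landings_years : inclusive (first, last); default = last 10 scenario years

    Returns
    -------
    (ports, landings) : pair of DataFrames with columns
        ``port, state, lon, lat`` and ``stock, port, year, landings_kg``.
    """
    if isinstance(scenarios, StockScenario):
        scenarios = [scenarios]
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario required")
    if landings_years is None:
        y1 = min(s.years[1] for s in scenarios)
        landings_years = (max(y1 - 9, max(s.years[0] for s in scenarios)), y1)
    for s in scenarios:
        if landings_years[0] < s.years[0] or landings_years[1] > s.years[1]:
            raise ValueError("landings_years must lie within every scenario's years")

    rng = np.random.default_rng(seed)
    port_rows = []
    for sid, poly in geo.state_waters:
        n_ports = ports_per_state[sid] if isinstance(ports_per_state, Mapping) else ports_per_state
        if n_ports < 0:
            raise ValueError("ports_per_state must be >= 0")
        _, lat_lo, _, lat_hi = poly.bounds
        lats = np.sort(rng.uniform(lat_lo, lat_hi, size=n_ports))
        for k in range(n_ports):
            port_rows.append((f"{sid}_P{k + 1}", sid, geo.coastline_meridian, lats[k]))
    ports = pd.DataFrame(port_rows, columns=["port", "state", "lon", "lat"])

    landing_rows = []
    years = range(landings_years[0], landings_years[1] + 1)
    for scen in scenarios:
        for _, p in ports.iterrows():
            for year in years:
                base = _neighborhood_mean_cpue(scen, p["lon"], p["lat"], year)
                kg = base * landings_scale * rng.lognormal(0.0, landings_noise_sd)
                landing_rows.append((scen.stock_id, p["port"], year, kg))
    landings = pd.DataFrame(landing_rows, columns=["stock", "port", "year", "landings_kg"])
    return ports, landings


# ---------------------------------------------------------------------------
# Study conditions: the default synthetic domain and stock


def default_geography() -> Geography:
    """11 states spanning 33.8-45.2 deg N along a straight coast at 74 deg W.

    The state-waters strips are 0.2 deg wide — wider than the statutory
    3 nm — so that a 0.3 deg analysis grid resolves at least one column of
    coastal cells per state.
    """
    return make_geography(
        n_states=11, lat_range=(33.8, 45.2), eez_width=3.0, state_waters_width=0.2
    )


def default_scenario(stock_id: str = "scup_like", seed: int = 7) -> StockScenario:
    """A scup-like stock: 40 survey years, 0.1 deg/yr poleward drift and a
    1.5 deg poleward fall displacement, centred 1.5 deg offshore."""
    return StockScenario(
        stock_id=stock_id,
        center0=(-72.5, 37.0),
        drift=0.1,
        seasonal_offset=1.5,
        spread=(1.0, 1.5),
        peak_cpue=50.0,
        noise_sd=0.6,
        years=(1980, 2019),
        stations_per_year=150,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O


def write_geography(geo: Geography, path) -> None:
    """Write the geography as one GeoJSON FeatureCollection: an ``eez``
    feature plus one feature per state carrying a ``state`` property."""
    features = [
        {"type": "Feature", "properties": {"role": "eez"}, "geometry": mapping(geo.eez)}
    ]
    for sid, poly in geo.state_waters:
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "state_waters", "state": sid},
                "geometry": mapping(poly),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"coastline_meridian": geo.coastline_meridian},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_geography(path) -> Geography:
    with open(path) as fh:
        doc = json.load(fh)
    eez = None
    strips = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if props.get("role") == "eez":
            eez = geom
        else:
            strips.append((props["state"], geom))
    if eez is None:
        raise GeometryError(f"no EEZ feature in {path}")
    strips.sort(key=lambda sp: sp[1].centroid.y)
    meridian = doc.get("properties", {}).get("coastline_meridian", eez.bounds[0])
    return Geography(eez=eez, state_waters=tuple(strips), coastline_meridian=meridian)
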