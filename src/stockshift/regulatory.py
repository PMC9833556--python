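"""Regulatory-unit construction over a gridded EEZ.

Federal waters are not subdivided among states, so putative per-state
regulatory units must be constructed.  Two bracketing designs are
implemented:

* **state-waters expansion** — each state's statutory coastal strip is
  dilated (morphological buffer) until the union of dilated strips covers
  the whole EEZ, then clipped to the EEZ;
* **fishing-ports buffering** — the top quantile of ports by landed
  weight of a stock is selected, a radial buffer is drawn around each
  port, clipped to the EEZ, and attributed to the port's state.

Both designs are rasterized onto a regular lon/lat grid by cell-centre
membership; a cell claimed by k states carries weight 1/k for each
(equal-split overlap rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .synthetic import Geography, GeometryError

__all__ = [
    "GridSpec",
    "RegulatoryUnits",
    "EmptyPortUniverseError",
    "build_grid",
    "find_covering_radius",
    "expand_state_waters",
    "select_top_ports",
    "expand_fishing_ports",
    "threshold_sensitivity",
    "units_to_frame",
    "frame_to_units",
]

#: analysis grid resolution, degrees
DEFAULT_RESOLUTION = 0.3
#: convergence tolerance of the covering-radius search, degrees
RADIUS_TOL = 1e-3


class EmptyPortUniverseError(ValueError):
    """No port has nonzero landings of the requested stock."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid; cell (i, j) spans the half-open box
    [origin_lon + i*res, origin_lon + (i+1)*res) x
    [origin_lat + j*res, origin_lat + (j+1)*res).

    ``cells`` holds the (i, j) indices whose centre lies inside the EEZ.
    """

    resolution: float
    origin: tuple  # (lon, lat) of the lower-left corner of cell (0, 0)
    n_lon: int
    n_lat: int
    cells: frozenset

    @property
    def sorted_cells(self) -> list:
        return sorted(self.cells)

    def cell_center(self, i: int, j: int) -> tuple:
        ox, oy = self.origin
        return (ox + (i + 0.5) * self.resolution, oy + (j + 0.5) * self.resolution)

    def centers(self, cells=None) -> np.ndarray:
        """(n, 2) array of centres for ``cells`` (default: all, sorted)."""
        cells = self.sorted_cells if cells is None else list(cells)
        ox, oy = self.origin
        idx = np.asarray(cells, dtype=float).reshape(-1, 2)
        return np.column_stack(
            [ox + (idx[:, 0] + 0.5) * self.resolution, oy + (idx[:, 1] + 0.5) * self.resolution]
        )


@dataclass(frozen=True)
class RegulatoryUnits:
    """Per-cell state ownership weights under one unit design.

    ``weights`` maps cell (i, j) -> {state_id: weight}; weights of an
    owned cell sum to 1, a cell shared by k states carrying 1/k each.
    Cells absent from the mapping have no owner.
    """

    method: str
    weights: dict

    def state_cell_totals(self) -> dict:
        """Summed cell weights per state (the 'area' each state owns)."""
        totals: dict = {}
        for wmap in self.weights.values():
            for sid, w in wmap.items():
                totals[sid] = totals.get(sid, 0.0) + w
        return totals

    def owned_cells(self, state_id: str) -> set:
        return {c for c, wmap in self.weights.items() if state_id in wmap}


def build_grid(eez: Polygon, resolution: float = DEFAULT_RESOLUTION, origin=None) -> GridSpec:
    """Grid the EEZ: keep every cell whose centre lies inside (or on the
    boundary of) the EEZ polygon.  ``origin`` defaults to the lower-left
    corner of the EEZ bounding box."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if eez is None or eez.is_empty or eez.area == 0:
        raise GeometryError("degenerate EEZ polygon")
    minx, miny, maxx, maxy = eez.bounds
    ox, oy = (minx, miny) if origin is None else origin
    n_lon = max(1, math.ceil((maxx - ox) / resolution - 1e-9))
    n_lat = max(1, math.ceil((maxy - oy) / resolution - 1e-9))
    ii, jj = np.meshgrid(np.arange(n_lon), np.arange(n_lat), indexing="ij")
    cx = ox + (ii.ravel() + 0.5) * resolution
    cy = oy + (jj.ravel() + 0.5) * resolution
    inside = shapely.covers(eez, shapely.points(cx, cy))
    cells = frozenset(zip(ii.ravel()[inside].tolist(), jj.ravel()[inside].tolist()))
    return GridSpec(resolution=resolution, origin=(ox, oy), n_lon=n_lon, n_lat=n_lat, cells=cells)


def find_covering_radius(geo: Geography, tol: float = RADIUS_TOL) -> float:
    """Smallest dilation radius (to ``tol`` degrees, by doubling then
    bisection) such that the union of all state strips buffered by it
    covers the EEZ."""
    if not geo.state_waters:
        raise GeometryError("geography has no state waters")
    strips = [poly for _, poly in geo.state_waters]
    if any(p.is_empty for p in strips):
        raise GeometryError("empty state-waters polygon")

    def covered(r: float) -> bool:
        return unary_union([p.buffer(r, quad_segs=16) for p in strips]).covers(geo.eez)

    hi = tol
    while not covered(hi):
        hi *= 2.0
        if hi > 1e4:
            raise GeometryError("no finite dilation radius covers the EEZ")
    lo = hi / 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if covered(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _weights_from_owner_sets(owner_lists: dict) -> dict:
    """cell -> sorted owner list  =>  cell -> {state: 1/k}."""
    weights = {}
    for cell, owners in owner_lists.items():
        if owners:
            k = len(owners)
            weights[cell] = {sid: 1.0 / k for sid in sorted(owners)}
    return weights


def expand_state_waters(geo: Geography, grid: GridSpec) -> RegulatoryUnits:
    """State-waters expansion design.

    Every strip is dilated symmetrically by the common covering radius
    (see :func:`find_covering_radius`) and clipped to the EEZ.  A point
    lies in the dilation of a polygon by r exactly when its distance to
    the polygon is <= r, so cell membership is evaluated with the exact
    distance test rather than a discretized buffer; clipping is implicit
    because grid cells already lie inside the EEZ.  Cells owned by nobody
    (possible only within the radius-search tolerance) fall to the
    state(s) at minimum centre-to-strip distance.  Every EEZ cell ends up
    owned and per-cell weights sum to 1.
    """
    radius = find_covering_radius(geo)
    cells = grid.sorted_cells
    centers = grid.centers(cells)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    sids = [sid for sid, _ in geo.state_waters]
    dists = np.column_stack([shapely.distance(pts, strip) for _, strip in geo.state_waters])

    owners: dict = {}
    for n, c in enumerate(cells):
        own = {sids[k] for k in range(len(sids)) if dists[n, k] <= radius}
        if not own:
            dmin = dists[n].min()
            own = {sids[k] for k in range(len(sids)) if dists[n, k] <= dmin + 1e-12}
        owners[c] = own
    return RegulatoryUnits(method="state_waters", weights=_weights_from_owner_sets(owners))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_top_ports(
    landings: pd.DataFrame,
    ports: pd.DataFrame,
    stock: str,
    period: tuple,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Select the top quantile of ports by landed weight of one stock.

    Per-port landings are averaged over the period (total landings in the
    period divided by the number of period years); ports with zero average
    for the stock are dropped from the universe before the quantile is
    taken.  ``round(threshold * n)`` ports (half-up, floor 1) with the
    largest averages are returned, ties broken by larger total landings
    across all stocks in the period, then by port name.

    Returns the selected rows of ``ports`` (plus ``avg_landings_kg``),
    ranked best-first.  Invariant to the row order of both inputs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    y0, y1 = period
    if y1 < y0:
        raise ValueError("period is empty")
    n_years = y1 - y0 + 1
    in_period = landings[(landings["year"] >= y0) & (landings["year"] <= y1)]
    stock_avg = (
        in_period[in_period["stock"] == stock].groupby("port")["landings_kg"].sum() / n_years
    )
    stock_avg = stock_avg[stock_avg > 0]
    if stock_avg.empty:
        raise EmptyPortUniverseError(f"no port has landings of stock {stock!r} in {period}")
    all_stock_tot = in_period.groupby("port")["landings_kg"].sum()

    n_sel = max(1, _round_half_up(threshold * len(stock_avg)))
    ranking = sorted(
        stock_avg.index,
        key=lambda p: (-stock_avg[p], -all_stock_tot.get(p, 0.0), p),
    )
    chosen = ranking[:n_sel]
    out = ports.set_index("port").loc[chosen].reset_index()
    out["avg_landings_kg"] = [stock_avg[p] for p in chosen]
    return out


def _as_state_waters(state_waters) -> list:
    if state_waters is None:
        return []
    if isinstance(state_waters, Geography):
        return list(state_waters.state_waters)
    return list(state_waters)


def expand_fishing_ports(
    ports: pd.DataFrame,
    grid: GridSpec,
    eez: Polygon,
    radius: float,
    state_waters=None,
) -> RegulatoryUnits:
    """Fishing-ports buffering design.

    A circular buffer of ``radius`` degrees around each selected port,
    clipped to the EEZ, is attributed to the port's state; same-state
    buffers merge before weighting.  A centre lies in the merged buffer
    exactly when its distance to the nearest of the state's ports is
    <= radius, so membership uses the exact distance test (clipping is
    implicit: grid cells already lie inside the EEZ).  When
    ``state_waters`` (a :class:`~stockshift.synthetic.Geography` or
    (state, polygon) pairs) is given, each state additionally keeps the
    cells of its statutory waters, so port-less states retain their
    coastal strip.  Cells claimed by k distinct states take weight 1/k
    each; cells in no buffer have no owner.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(ports) == 0:
        raise ValueError("ports must be non-empty")
    del eez  # membership needs no clipping: grid cells are inside the EEZ
    cells = grid.sorted_cells
    centers = grid.centers(cells)
    pts = shapely.points(centers[:, 0], centers[:, 1])

    member: dict = {}
    for sid, group in ports.groupby("state"):
        px = group["lon"].to_numpy(dtype=float)
        py = group["lat"].to_numpy(dtype=float)
        dmin = np.min(
            np.hypot(centers[:, 0:1] - px[None, :], centers[:, 1:2] - py[None, :]), axis=1
        )
        member[sid] = dmin <= radius
    for sid, strip in _as_state_waters(state_waters):
        in_strip = shapely.covers(strip, pts)
        member[sid] = (member[sid] | in_strip) if sid in member else in_strip

    owners: dict = {c: set() for c in cells}
    for sid in sorted(member):
        for c, ok in zip(cells, member[sid]):
            if ok:
                owners[c].add(sid)
    return RegulatoryUnits(method="fishing_ports", weights=_weights_from_owner_sets(owners))


def threshold_sensitivity(
    landings: pd.DataFrame,
    ports: pd.DataFrame,
    grid: GridSpec,
    eez: Polygon,
    radius: float,
    thresholds: Iterable,
    stock: str,
    period: tuple,
    state_waters=None,
) -> pd.DataFrame:
    """Sweep the port-selection quantile and report each state's holdings.

    For each threshold, runs :func:`select_top_ports` then
    :func:`expand_fishing_ports` and reports, per state, the number of
    owned grid cells (``n_cells``) and the summed cell weights
    (``weight_total``).  Owned-cell counts are non-decreasing in the
    threshold; weighted totals need not be, because newly shared cells
    split their weight.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    all_states = sorted(
        set(ports["state"]) | {sid for sid, _ in _as_state_waters(state_waters)}
    )
    rows = []
    for th in thresholds:
        selected = select_top_ports(landings, ports, stock, period, threshold=th)
        units = expand_fishing_ports(selected, grid, eez, radius, state_waters=state_waters)
        totals = units.state_cell_totals()
        for sid in all_states:
            rows.append(
                {
                    "threshold": th,
                    "state": sid,
                    "n_cells": len(units.owned_cells(sid)),
                    "weight_total": totals.get(sid, 0.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular I/O


def units_to_frame(units: RegulatoryUnits) -> pd.DataFrame:
    rows = [
        (units.method, i, j, sid, w)
        for (i, j) in sorted(units.weights)
        for sid, w in sorted(units.weights[(i, j)].items())
    ]
    return pd.DataFrame(rows, columns=["method", "cell_i", "cell_j", "state", "weight"])


def frame_to_units(frame: pd.DataFrame) -> RegulatoryUnits:
    methods = frame["method"].unique()
    if len(methods) != 1:
        raise ValueError("frame must contain exactly one method")
    weights: dict = {}
    for row in frame.itertuples(index=False):
        weights.setdefault((int(row.cell_i), int(row.cell_j)), {})[row.state] = float(row.weight)
    return RegulatoryUnits(method=str(methods[0]), weights=weights)
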