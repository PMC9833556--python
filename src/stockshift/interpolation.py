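"""Triangular-irregular-surface (Delaunay piecewise-linear) interpolation.

Scattered survey CPUE for one stock x year x season is triangulated
(Delaunay) and evaluated at grid-cell centres with the unique linear
interpolant of the containing triangle (barycentric weights).  Centres
outside the convex hull of the stations are *missing* — the survey says
nothing there — and are treated as zero CPUE by the downstream allocation
sums.

Triangulation is done in raw lon/lat degrees, mirroring the planar
treatment appropriate at mid-latitudes over a narrow band; positions
within 1e-9 deg are merged (mean CPUE) before triangulating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .regulatory import GridSpec

__all__ = [
    "GriddedSurface",
    "InsufficientSupportError",
    "interpolate_tis",
    "batch_interpolate",
    "surface_to_frame",
    "surfaces_to_frame",
    "frame_to_surfaces",
]

logger = logging.getLogger(__name__)

#: positions closer than this (degrees) are treated as repeat tows at one site
SNAP_TOL = 1e-9


class InsufficientSupportError(ValueError):
    """Fewer than 3 distinct, non-collinear stations in a group."""


@dataclass(frozen=True)
class GriddedSurface:
    """Interpolated CPUE field of one stock-year-season on a grid.

    ``values`` is an (n_lon, n_lat) array in kg/ha; NaN marks cells that
    are outside the EEZ grid or outside the survey's convex hull.
    """

    stock: str
    year: int
    season: str
    grid: GridSpec
    values: np.ndarray

    def defined_cells(self) -> list:
        return [c for c in self.grid.sorted_cells if not np.isnan(self.values[c])]

    def total(self) -> float:
        """Coast-wide sum of defined CPUE (missing counted as zero)."""
        return float(np.nansum(self.values))


def _merge_duplicates(lon, lat, cpue):
    """Average CPUE over repeat tows at (numerically) identical sites."""
    key = np.round(np.column_stack([lon, lat]) / SNAP_TOL).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    sums = np.bincount(inv, weights=cpue)
    counts = np.bincount(inv)
    return lon[first], lat[first], sums / counts


def interpolate_tis(points: pd.DataFrame, grid: GridSpec, *, label=None) -> GriddedSurface:
    """Interpolate one stock-year-season of survey points onto the grid.

    ``points`` needs columns ``lon, lat`` and ``cpue_kg_ha`` (or ``cpue``);
    ``stock/year/season`` are taken from the frame when present or from
    ``label=(stock, year, season)``.

    Raises :class:`InsufficientSupportError` when fewer than three
    distinct sites remain after duplicate merging or all sites are
    collinear (no triangulation exists).
    """
    if label is None:
        label = (
            str(points["stock"].iloc[0]),
            int(points["year"].iloc[0]),
            str(points["season"].iloc[0]),
        )
    stock, year, season = label
    col = "cpue_kg_ha" if "cpue_kg_ha" in points.columns else "cpue"
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    cpue = points[col].to_numpy(dtype=float)
    lon, lat, cpue = _merge_duplicates(lon, lat, cpue)

    if lon.size < 3:
        raise InsufficientSupportError(
            f"{stock}/{year}/{season}: {lon.size} distinct station(s), need >= 3"
        )
    try:
        tri = Delaunay(np.column_stack([lon, lat]))
    except QhullError as exc:
        raise InsufficientSupportError(
            f"{stock}/{year}/{season}: stations are collinear or degenerate"
        ) from exc

    interp = LinearNDInterpolator(tri, cpue)
    cells = grid.sorted_cells
    centers = grid.centers(cells)
    vals = interp(centers[:, 0], centers[:, 1])

    field = np.full((grid.n_lon, grid.n_lat), np.nan)
    for c, v in zip(cells, vals):
        field[c] = v
    return GriddedSurface(stock=stock, year=year, season=season, grid=grid, values=field)


def batch_interpolate(surveys: pd.DataFrame, grid: GridSpec):
    """Interpolate every (stock, year, season) group of a survey table.

    Groups that cannot support a triangulation are skipped, logged, and
    recorded in the returned skip report.

    Returns
    -------
    (surfaces, skips) : list of :class:`GriddedSurface` and a DataFrame
        with columns ``stock, year, season, reason``.
    """
    surfaces = []
    skip_rows = []
    for (stock, year, season), group in surveys.groupby(
        ["stock", "year", "season"], sort=True
    ):
        try:
            surfaces.append(
                interpolate_tis(group, grid, label=(str(stock), int(year), str(season)))
            )
        except InsufficientSupportError as exc:
            logger.warning("skipping group: %s", exc)
            skip_rows.append((stock, year, season, str(exc)))
    skips = pd.DataFrame(skip_rows, columns=["stock", "year", "season", "reason"])
    return surfaces, skips


# ---------------------------------------------------------------------------
# Tabular I/O (long format; missing cells omitted)


def surface_to_frame(surface: GriddedSurface) -> pd.DataFrame:
    rows = [
        (surface.stock, surface.year, surface.season, i, j, surface.values[i, j])
        for (i, j) in surface.defined_cells()
    ]
    return pd.DataFrame(rows, columns=["stock", "year", "season", "cell_i", "cell_j", "cpue"])


def surfaces_to_frame(surfaces) -> pd.DataFrame:
    frames = [surface_to_frame(s) for s in surfaces]
    if not frames:
        return pd.DataFrame(columns=["stock", "year", "season", "cell_i", "cell_j", "cpue"])
    return pd.concat(frames, ignore_index=True)


def frame_to_surfaces(frame: pd.DataFrame, grid: GridSpec) -> list:
    surfaces = []
    for (stock, year, season), group in frame.groupby(["stock", "year", "season"], sort=True):
        field = np.full((grid.n_lon, grid.n_lat), np.nan)
        for row in group.itertuples(index=False):
            field[int(row.cell_i), int(row.cell_j)] = float(row.cpue)
        surfaces.append(
            GriddedSurface(
                stock=str(stock), year=int(year), season=str(season), grid=grid, values=field
            )
        )
    return surfaces
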