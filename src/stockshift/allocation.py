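"""Allocation proportions and change statistics.

Each interpolated surface is allocated to states through the regulatory
unit weights: a state's proportion

    alpha_state = sum_cells w(cell, state) * cpue(cell) / sum_cells cpue(cell)

with missing cells counting zero and the coast-wide denominator including
cells owned by nobody.  Proportions are held as fractions internally and
rendered as percentages only at I/O boundaries.

Change statistics follow the quota-allocation convention: the percent
change of a state's share between a historical reference period and the
recent period,

    delta_alpha = (alpha_current - alpha_reference) / |alpha_reference| * 100,

its contrast between unit designs (fishing ports minus state waters,
computed on the spring surveys),

    delta_reg = delta_fp - delta_sw,

and its contrast between survey seasons,

    delta_seas = delta_fall - delta_spring.

A zero reference share makes delta_alpha undefined; undefined values are
carried as NaN and propagate through the contrasts, never silently
replaced by 0 or infinity.
"""

from __future__ import annotations

import math
import warnings
from collections import namedtuple
from importlib import resources

import numpy as np
import pandas as pd

from .interpolation import GriddedSurface
from .regulatory import RegulatoryUnits

__all__ = [
    "UndefinedProportionsError",
    "MissingPeriodError",
    "SchemaError",
    "allocate_proportions",
    "allocation_summary",
    "build_proportion_series",
    "period_mean",
    "PeriodMean",
    "delta_alpha",
    "delta_alpha_contrasts",
    "running_mean",
    "compare_to_quota",
    "load_quota_table",
]


class UndefinedProportionsError(ValueError):
    """Coast-wide CPUE total is zero; proportions are undefined."""


class MissingPeriodError(ValueError):
    """No year of the requested period has an entry."""


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


def allocate_proportions(surface: GriddedSurface, units: RegulatoryUnits) -> dict:
    """Proportion of the surface's coast-wide CPUE in each state's unit.

    Returns {state_id: alpha} with alpha a fraction in [0, 1]; states
    owning no cells simply do not appear (their alpha is 0).
    """
    alphas, _ = allocation_summary(surface, units)
    return alphas


def allocation_summary(surface: GriddedSurface, units: RegulatoryUnits):
    """Like :func:`allocate_proportions` but also returns the unallocated
    share (CPUE in cells owned by no state, over the coast-wide total)."""
    total = surface.total()
    if total <= 0:
        raise UndefinedProportionsError(
            f"coast-wide CPUE total is 0 for {surface.stock}/{surface.year}/{surface.season}"
        )
    num: dict = {}
    allocated = 0.0
    for cell, wmap in units.weights.items():
        v = surface.values[cell]
        if np.isnan(v):
            continue
        allocated += v
        for sid, w in wmap.items():
            num[sid] = num.get(sid, 0.0) + w * v
    alphas = {sid: s / total for sid, s in sorted(num.items())}
    return alphas, (total - allocated) / total


def build_proportion_series(surfaces, units_list, states=None) -> pd.DataFrame:
    """Allocate every surface under every unit design.

    Returns the long proportion table with columns
    ``stock, season, method, state, year, alpha`` — one row per state in
    ``states`` (default: every state appearing in any unit design), with
    alpha = 0 where a state owns no CPUE.
    """
    if isinstance(units_list, RegulatoryUnits):
        units_list = [units_list]
    if states is None:
        states = sorted({sid for u in units_list for w in u.weights.values() for sid in w})
    rows = []
    for units in units_list:
        for surf in surfaces:
            alphas = allocate_proportions(surf, units)
            for sid in states:
                rows.append(
                    (surf.stock, surf.season, units.method, sid, surf.year, alphas.get(sid, 0.0))
                )
    return pd.DataFrame(rows, columns=["stock", "season", "method", "state", "year", "alpha"])


PeriodMean = namedtuple("PeriodMean", ["value", "n_used", "n_missing"])


def period_mean(series: pd.DataFrame, key: tuple, years: tuple) -> PeriodMean:
    """Arithmetic mean of alpha over the available years of a range.

    ``key`` is (stock, season, method, state); ``years`` an inclusive
    (first, last).  Years of the range absent from the series (e.g.
    skipped interpolations) are excluded from the mean and counted in
    ``n_missing``.  Raises :class:`MissingPeriodError` when no year of the
    range has an entry.
    """
    stock, season, method, state = key
    y0, y1 = years
    sub = series[
        (series["stock"] == stock)
        & (series["season"] == season)
        & (series["method"] == method)
        & (series["state"] == state)
        & (series["year"] >= y0)
        & (series["year"] <= y1)
    ]
    n_used = len(sub)
    if n_used == 0:
        raise MissingPeriodError(f"no entries for {key} in {years}")
    return PeriodMean(float(sub["alpha"].mean()), n_used, (y1 - y0 + 1) - n_used)


def delta_alpha(alpha_current: float, alpha_reference: float) -> float:
    """Percent change of a share between two periods.

    Returns ``(alpha_current - alpha_reference) / |alpha_reference| * 100``,
    or NaN when the reference is zero (or either operand is NaN) — the
    change is then undefined, not zero and not infinite.  Scale-invariant:
    fractions and percentages as inputs give the same result.
    """
    if math.isnan(alpha_current) or math.isnan(alpha_reference) or alpha_reference == 0:
        return math.nan
    return (alpha_current - alpha_reference) / abs(alpha_reference) * 100.0


def delta_alpha_contrasts(
    series: pd.DataFrame,
    reference_periods: dict,
    current_period: tuple,
    seasonal_method: str = "state_waters",
) -> pd.DataFrame:
    """Per stock x state change statistics and their contrasts.

    For every stock (with its own reference period) and state, computes
    delta_alpha per method x season from period means of ``series``, then

    * ``delta_fp``, ``delta_sw``: fishing-ports and state-waters changes
      on the *spring* surveys, and ``delta_reg = delta_fp - delta_sw``;
    * ``delta_f``, ``delta_s``: fall and spring changes under
      ``seasonal_method``, and ``delta_seas = delta_f - delta_s``.

    Undefined operands (zero or missing reference) yield NaN cells.
    Returns one row per (stock, state) with those six columns.
    """
    def _delta(stock, season, method, state, ref):
        try:
            a_ref = period_mean(series, (stock, season, method, state), ref).value
            a_cur = period_mean(series, (stock, season, method, state), current_period).value
        except MissingPeriodError:
            return math.nan
        return delta_alpha(a_cur, a_ref)

    stocks = sorted(series["stock"].unique())
    states = sorted(series["state"].unique())
    missing = set(stocks) - set(reference_periods)
    if missing:
        raise SchemaError(f"no reference period for stock(s): {sorted(missing)}")
    rows = []
    for stock in stocks:
        ref = tuple(reference_periods[stock])
        for state in states:
            d_fp = _delta(stock, "spring", "fishing_ports", state, ref)
            d_sw = _delta(stock, "spring", "state_waters", state, ref)
            d_f = _delta(stock, "fall", seasonal_method, state, ref)
            d_s = _delta(stock, "spring", seasonal_method, state, ref)
            rows.append(
                {
                    "stock": stock,
                    "state": state,
                    "delta_fp": d_fp,
                    "delta_sw": d_sw,
                    "delta_reg": d_fp - d_sw,
                    "delta_f": d_f,
                    "delta_s": d_s,
                    "delta_seas": d_f - d_s,
                }
            )
    return pd.DataFrame(rows)


def running_mean(series: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Trailing running mean of alpha per (stock, season, method, state).

    Each output year is labelled by the final year of its window and is
    emitted only when all ``window`` calendar years are present (gaps from
    skipped interpolations break the window).  A window longer than every
    group yields an empty table with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for key, group in series.groupby(["stock", "season", "method", "state"], sort=True):
        g = group.set_index("year")["alpha"].sort_index()
        full = g.reindex(range(int(g.index.min()), int(g.index.max()) + 1))
        roll = full.rolling(window, min_periods=window).mean().dropna()
        for year, val in roll.items():
            out.append((*key, int(year), float(val)))
    result = pd.DataFrame(out, columns=["stock", "season", "method", "state", "year", "alpha"])
    if result.empty:
        warnings.warn(f"running-mean window {window} exceeds every series length")
    return result


def load_quota_table() -> pd.DataFrame:
    """Current MAFMC state-by-state commercial quota percentages (shipped
    reference table; for comparison outputs only)."""
    with resources.files("stockshift.data").joinpath("mafmc_quota.csv").open() as fh:
        return pd.read_csv(fh)


def compare_to_quota(alpha_table: pd.DataFrame, quota: pd.DataFrame) -> pd.DataFrame:
    """Difference between modelled shares and current quota percentages.

    ``alpha_table`` needs columns ``stock, state, method, season, alpha``
    (fractions); ``quota`` needs ``state, stock, quota_pct`` summing to
    ~100 per stock.  Returns the same rows with ``alpha_pct`` and
    ``diff_pct = alpha_pct - quota_pct``.
    """
    for col in ("state", "stock", "quota_pct"):
        if col not in quota.columns:
            raise SchemaError(f"quota table lacks column {col!r}")
    sums = quota.groupby("stock")["quota_pct"].sum()
    bad = sums[(sums - 100.0).abs() > 1.0]
    if not bad.empty:
        raise SchemaError(f"quota percentages do not sum to ~100 for: {list(bad.index)}")
    unknown = set(quota["state"]) - set(alpha_table["state"])
    if unknown:
        raise SchemaError(f"quota table has unknown state(s): {sorted(unknown)}")
    merged = alpha_table.merge(quota, on=["state", "stock"], how="left")
    if merged["quota_pct"].isna().any():
        raise SchemaError("missing quota entries for some state x stock pairs")
    merged["alpha_pct"] = merged["alpha"] * 100.0
    merged["diff_pct"] = merged["alpha_pct"] - merged["quota_pct"]
    return merged.drop(columns=["alpha"])
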