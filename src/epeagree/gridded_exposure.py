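"""Gridded product processing: hourly aggregation, area-weighted
polygon averaging, and grid-derived thresholds."""

from __future__ import annotations

import warnings

import numpy as np
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .errors import EpeAgreeError
from .station_exposure import local_percentile_threshold
from .types import DailyGrid, ExposureUnit, GridSpec, HourlyGrid, PrecipSeries

__all__ = [
    "hourly_to_daily",
    "intersection_weights",
    "area_weighted_average",
    "unit_series_from_grid",
    "grid_percentile_threshold",
]


def hourly_to_daily(hg: HourlyGrid) -> DailyGrid:
    """Per-pixel daily sums of 24 hourly layers.

    A pixel-day with any missing hour is missing (NaN propagates through
    the plain sum).
    """
    if hg.values.ndim != 4 or hg.values.shape[1] != 24:
        raise EpeAgreeError("hourly grid must have exactly 24 hour layers per day")
    return DailyGrid(hg.spec, hg.dates, hg.values.sum(axis=1))


def intersection_weights(
    polygon: BaseGeometry, spec: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cells intersecting ``polygon`` and their intersection areas.

    Returns (rows, cols, areas); cells with zero-area overlap are
    dropped.  Cells are prefiltered by the polygon bounding box so cost
    scales with the overlap, not the grid.
    """
    minx, miny, maxx, maxy = polygon.bounds
    j0 = max(0, int(np.floor((minx - spec.x0) / spec.dx)))
    j1 = min(spec.n_cols, int(np.ceil((maxx - spec.x0) / spec.dx)))
    i0 = max(0, int(np.floor((miny - spec.y0) / spec.dy)))
    i1 = min(spec.n_rows, int(np.ceil((maxy - spec.y0) / spec.dy)))
    rows, cols, areas = [], [], []
    for i in range(i0, i1):
        for j in range(j0, j1):
            cell = box(*spec.cell_bounds(i, j))
            a = polygon.intersection(cell).area
            if a > 0:
                rows.append(i)
                cols.append(j)
                areas.append(a)
    return (
        np.array(rows, dtype=int),
        np.array(cols, dtype=int),
        np.array(areas, dtype=float),
    )


def area_weighted_average(
    polygon: BaseGeometry, grid: DailyGrid, day: int
) -> float:
    """Spatially weighted average of cell values over the polygon.

    Weights are the areas of each cell's intersection with the polygon;
    when some intersecting cells are missing that day, weights are
    renormalised over the non-missing ones.  Returns NaN (with a
    warning) if every intersecting cell is missing.
    """
    rows, cols, areas = intersection_weights(polygon, grid.spec)
    if rows.size == 0:
        raise EpeAgreeError("polygon does not intersect the grid extent")
    vals = grid.values[day, rows, cols]
    ok = ~np.isnan(vals)
    if not ok.any():
        warnings.warn(f"all intersecting cells missing on day {day}", stacklevel=2)
        return float("nan")
    return float(np.average(vals[ok], weights=areas[ok]))


def unit_series_from_grid(
    units: list[ExposureUnit], grid: DailyGrid
) -> dict[str, PrecipSeries]:
    """Per-unit daily series of area-weighted grid averages.

    Intersection weights are computed once per unit; days with no valid
    intersecting cell propagate as missing.
    """
    out = {}
    for unit in units:
        rows, cols, areas = intersection_weights(unit.polygon, grid.spec)
        if rows.size == 0:
            raise EpeAgreeError(
                f"{unit.unit_id}: polygon does not intersect the grid extent"
            )
        vals = grid.values[:, rows, cols]  # (n_days, n_cells)
        ok = ~np.isnan(vals)
        # renormalise over non-missing cells; all-missing day -> NaN
        w = np.where(ok, areas[None, :], 0.0)
        den = w.sum(axis=1)
        num = (np.nan_to_num(vals) * w).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            series = np.where(den > 0, num / den, np.nan)
        out[unit.unit_id] = PrecipSeries(unit.unit_id, grid.dates, series)
    return out


def grid_percentile_threshold(
    series: PrecipSeries, q: float = 0.99, wet_min_mm: float = 0.0,
    threshold_population: str = "wet_days",
) -> float:
    """EPE threshold from a unit's grid-derived series.

    By default restricted to wet days for comparability with the
    station-based thresholds; ``threshold_population='all_days'`` uses
    every non-missing day instead.
    """
    if threshold_population == "wet_days":
        return local_percentile_threshold(series, q, wet_min_mm)
    if threshold_population == "all_days":
        v = series.values[~np.isnan(series.values) & ~series.qc_flags]
        if v.size == 0:
            raise EpeAgreeError(f"{series.source_id}: no valid days")
        return float(np.quantile(v, q, method="linear"))
    raise ValueError("threshold_population must be 'wet_days' or 'all_days'")
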