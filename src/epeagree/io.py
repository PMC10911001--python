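"""Serialization of units, station records, grids and results.

Formats: exposure units as a GeoJSON FeatureCollection with attribute
properties; station and per-unit daily series as long CSV; grids as
NetCDF (classic format via xarray's scipy backend) with the grid
geometry stored as global attributes; EPE matrices as long CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import shape, mapping

from .types import (
    DailyGrid,
    EPEDefinition,
    EPEMatrix,
    ExposureUnit,
    GridSpec,
    HourlyGrid,
    PrecipSeries,
    Station,
    StationNetwork,
)

_UNIT_FIELDS = [
    "pct_minority",
    "pct_black",
    "pct_native_american",
    "pct_asian",
    "pct_hispanic",
    "pct_poverty",
    "svi",
    "urbanicity",
    "pop_density",
    "prominence_km",
]


def write_units_geojson(units: list[ExposureUnit], path: str | Path) -> None:
    features = []
    for u in units:
        props = {"unit_id": u.unit_id}
        for f in _UNIT_FIELDS:
            v = getattr(u, f)
            if isinstance(v, float) and np.isnan(v):
                v = None
            props[f] = v
        features.append(
            {"type": "Feature", "geometry": mapping(u.polygon), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_units_geojson(path: str | Path) -> list[ExposureUnit]:
    data = json.loads(Path(path).read_text())
    units = []
    for feat in data["features"]:
        props = dict(feat["properties"])
        uid = props.pop("unit_id")
        kwargs = {}
        for f in _UNIT_FIELDS:
            v = props.get(f)
            kwargs[f] = (np.nan if v is None else v) if f != "urbanicity" else v
        units.append(ExposureUnit(uid, shape(feat["geometry"]), **kwargs))
    return units


def write_station_csv(
    network: StationNetwork, series_path: str | Path, meta_path: str | Path
) -> None:
    rows = []
    for s in network.stations:
        ser = s.series
        for d, v, f in zip(ser.dates, ser.values, ser.qc_flags):
            rows.append(
                {
                    "station_id": s.station_id,
                    "date": d.strftime("%Y-%m-%d"),
                    "prcp_mm": "" if np.isnan(v) else v,
                    "qc_flag": int(f),
                }
            )
    pd.DataFrame(rows).to_csv(series_path, index=False)
    pd.DataFrame(
        [{"station_id": s.station_id, "x": s.x, "y": s.y} for s in network.stations]
    ).to_csv(meta_path, index=False)


def read_station_csv(
    series_path: str | Path, meta_path: str | Path, crs: str = "planar_km"
) -> StationNetwork:
    series = pd.read_csv(series_path, parse_dates=["date"])
    meta = pd.read_csv(meta_path).set_index("station_id")
    stations = []
    for sid, grp in series.groupby("station_id", sort=True):
        grp = grp.sort_values("date")
        ps = PrecipSeries(
            str(sid),
            pd.DatetimeIndex(grp["date"]),
            grp["prcp_mm"].to_numpy(dtype=float),
            grp["qc_flag"].to_numpy(dtype=bool),
        )
        stations.append(
            Station(str(sid), float(meta.loc[sid, "x"]), float(meta.loc[sid, "y"]), ps)
        )
    return StationNetwork(stations, crs=crs)


def _spec_attrs(spec: GridSpec) -> dict:
    return {
        "x0": spec.x0, "y0": spec.y0, "dx": spec.dx, "dy": spec.dy,
        "n_rows": spec.n_rows, "n_cols": spec.n_cols,
    }


def _spec_from_attrs(attrs) -> GridSpec:
    return GridSpec(
        float(attrs["x0"]), float(attrs["y0"]), float(attrs["dx"]),
        float(attrs["dy"]), int(attrs["n_rows"]), int(attrs["n_cols"]),
    )


def write_grid_netcdf(grid: DailyGrid | HourlyGrid, path: str | Path) -> None:
    if isinstance(grid, HourlyGrid):
        dims = ("day", "hour", "y", "x")
    else:
        dims = ("day", "y", "x")
    ds = xr.Dataset(
        {"prcp_mm": (dims, grid.values)},
        coords={"day": grid.dates},
        attrs=_spec_attrs(grid.spec),
    )
    ds.to_netcdf(path, engine="scipy")


def read_daily_grid(path: str | Path) -> DailyGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return DailyGrid(
        _spec_from_attrs(ds.attrs),
        pd.DatetimeIndex(ds["day"].values),
        ds["prcp_mm"].values,
    )


def read_hourly_grid(path: str | Path) -> HourlyGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return HourlyGrid(
        _spec_from_attrs(ds.attrs),
        pd.DatetimeIndex(ds["day"].values),
        ds["prcp_mm"].values,
    )


def write_series_csv(series: dict[str, PrecipSeries], path: str | Path) -> None:
    """Per-unit daily series, long format (unit_id, date, prcp_mm).

    Schema is identical for station-assigned and grid-derived series so
    downstream code is source-agnostic.
    """
    frames = []
    for uid in sorted(series):
        s = series[uid]
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": uid,
                    "date": s.dates.strftime("%Y-%m-%d"),
                    "prcp_mm": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> dict[str, PrecipSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("date")
        out[str(uid)] = PrecipSeries(
            str(uid), pd.DatetimeIndex(grp["date"]), grp["prcp_mm"].to_numpy(float)
        )
    return out


def write_epe_matrices_csv(matrices: list[EPEMatrix], path: str | Path) -> None:
    frames = []
    for m in matrices:
        n_u, n_d = m.indicator.shape
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": np.repeat(m.unit_ids, n_d),
                    "date": np.tile(m.dates.strftime("%Y-%m-%d"), n_u),
                    "source": m.source,
                    "definition": m.definition.kind,
                    "epe": m.indicator.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epe_matrices_csv(path: str | Path) -> list[EPEMatrix]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for (source, kind), grp in df.groupby(["source", "definition"], sort=True):
        pivot = grp.pivot(index="unit_id", columns="date", values="epe").sort_index()
        out.append(
            EPEMatrix(
                [str(u) for u in pivot.index],
                pd.DatetimeIndex(pivot.columns),
                str(source),
                EPEDefinition(str(kind)),
                pivot.to_numpy(float),
            )
        )
    return out
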