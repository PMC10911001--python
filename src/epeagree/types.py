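"""Core data containers shared across the pipeline.

Precipitation is always in millimetres, coordinates in kilometres on a
planar frame (synthetic regions) or degrees lon/lat (real extracts);
missing values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import AlignmentError

__all__ = [
    "PrecipSeries",
    "Station",
    "StationNetwork",
    "GridSpec",
    "DailyGrid",
    "HourlyGrid",
    "ExposureUnit",
    "EPEDefinition",
    "EPEMatrix",
    "DistanceProfile",
    "Contingency2x2",
    "KappaResult",
    "MatchedStrata",
]

CRS = Literal["planar_km", "lonlat"]


@dataclass
class PrecipSeries:
    """Daily precipitation record for one station or exposure unit.

    Parameters
    ----------
    source_id : str
        Station or unit identifier.
    dates : pandas.DatetimeIndex
        Strictly increasing day index.
    values : ndarray of float
        Daily precipitation in mm; NaN marks a missing day.
    qc_flags : ndarray of bool, optional
        True where the day's value carries a quality flag.  Defaults to
        all-clean.
    """

    source_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    qc_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        if len(self.dates) > 1 and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if len(self.dates) != len(set(self.dates)):
            raise ValueError("dates must be strictly increasing (no duplicates)")
        if self.qc_flags is None:
            self.qc_flags = np.zeros(len(self.values), dtype=bool)
        else:
            self.qc_flags = np.asarray(self.qc_flags, dtype=bool)
            if len(self.qc_flags) != len(self.values):
                raise ValueError("qc_flags length mismatch")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("non-missing precipitation values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "PrecipSeries":
        return PrecipSeries(
            self.source_id, self.dates.copy(), self.values.copy(), self.qc_flags.copy()
        )


@dataclass
class Station:
    station_id: str
    x: float
    y: float
    series: PrecipSeries


@dataclass
class StationNetwork:
    """A set of stations with unique identifiers and a shared date index."""

    stations: list[Station]
    crs: CRS = "planar_km"

    def __post_init__(self) -> None:
        ids = [s.station_id for s in self.stations]
        if len(ids) != len(set(ids)):
            raise ValueError("station_ids must be unique")

    def __len__(self) -> int:
        return len(self.stations)

    @property
    def station_ids(self) -> list[str]:
        return [s.station_id for s in self.stations]

    @property
    def coords(self) -> np.ndarray:
        """(n_stations, 2) array of x/y (or lon/lat) coordinates."""
        return np.array([[s.x, s.y] for s in self.stations], dtype=float)

    @property
    def dates(self) -> pd.DatetimeIndex:
        if not self.stations:
            raise ValueError("empty network has no date index")
        d0 = self.stations[0].series.dates
        for s in self.stations[1:]:
            if not d0.equals(s.series.dates):
                raise AlignmentError("stations do not share a common date index")
        return d0

    def value_matrix(self, apply_qc: bool = True) -> np.ndarray:
        """(n_days, n_stations) value matrix; flagged days NaN if apply_qc."""
        cols = []
        for s in self.stations:
            v = s.series.values.copy()
            if apply_qc:
                v[s.series.qc_flags] = np.nan
            cols.append(v)
        return np.column_stack(cols)

    def subset(self, ids: list[str]) -> "StationNetwork":
        keep = set(ids)
        return StationNetwork(
            [s for s in self.stations if s.station_id in keep], crs=self.crs
        )


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster.

    Cell (i, j) spans the half-open rectangle
    [x0 + j*dx, x0 + (j+1)*dx) x [y0 + i*dy, y0 + (i+1)*dy).
    """

    x0: float
    y0: float
    dx: float
    dy: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.dy

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.dx,
            self.y0 + self.n_rows * self.dy,
        )

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        return (
            self.x0 + j * self.dx,
            self.y0 + i * self.dy,
            self.x0 + (j + 1) * self.dx,
            self.y0 + (i + 1) * self.dy,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        j = int(np.floor((x - self.x0) / self.dx))
        i = int(np.floor((y - self.y0) / self.dy))
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return i, j


@dataclass
class DailyGrid:
    """Daily precipitation raster: values shaped (n_days, n_rows, n_cols)."""

    spec: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("DailyGrid values must be (day, row, col)")
        if self.values.shape != (len(self.dates), self.spec.n_rows, self.spec.n_cols):
            raise ValueError("DailyGrid values shape does not match spec/dates")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite < -1e-12).any():
            raise ValueError("precipitation must be non-negative")


@dataclass
class HourlyGrid:
    """Hourly precipitation raster: values shaped (n_days, 24, n_rows, n_cols)."""

    spec: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1] != 24:
            raise ValueError("HourlyGrid values must be (day, 24, row, col)")
        if self.values.shape[0] != len(self.dates):
            raise ValueError("HourlyGrid day dimension does not match dates")


URBANICITY_LEVELS = ("rural", "urban cluster", "urban")


@dataclass
class ExposureUnit:
    """Polygonal exposure-assessment unit (census-tract analogue).

    Demographic shares are percentages in [0, 100]; ``svi`` is a percentile
    rank in [0, 1]; ``pop_density`` is in 1,000 persons per square km;
    ``prominence_km`` is the within-unit elevation range.
    """

    unit_id: str
    polygon: Polygon
    pct_minority: float = np.nan
    pct_black: float = np.nan
    pct_native_american: float = np.nan
    pct_asian: float = np.nan
    pct_hispanic: float = np.nan
    pct_poverty: float = np.nan
    svi: float = np.nan
    urbanicity: str | None = None
    pop_density: float = np.nan
    prominence_km: float = np.nan

    def __post_init__(self) -> None:
        for name in (
            "pct_minority",
            "pct_black",
            "pct_native_american",
            "pct_asian",
            "pct_hispanic",
            "pct_poverty",
        ):
            v = getattr(self, name)
            if not np.isnan(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if not np.isnan(self.svi) and not (0.0 <= self.svi <= 1.0):
            raise ValueError(f"svi must lie in [0, 1], got {self.svi}")
        if self.urbanicity is not None and self.urbanicity not in URBANICITY_LEVELS:
            raise ValueError(f"urbanicity must be one of {URBANICITY_LEVELS}")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class EPEDefinition:
    """Extreme-precipitation-event definition.

    ``percentile_99`` uses a locally derived wet-day 99th-percentile
    threshold; ``absolute`` uses a fixed cut of more than one inch
    (25.4 mm) of daily precipitation.
    """

    kind: Literal["percentile_99", "absolute"]
    absolute_threshold_mm: float = 25.4

    def __post_init__(self) -> None:
        if self.kind not in ("percentile_99", "absolute"):
            raise ValueError("kind must be 'percentile_99' or 'absolute'")
        if self.absolute_threshold_mm <= 0:
            raise ValueError("absolute_threshold_mm must be > 0")


@dataclass
class EPEMatrix:
    """Unit x day binary EPE indicators for one source and one definition.

    ``indicator`` is float-coded: 1.0 (EPE), 0.0 (no EPE), NaN (missing).
    """

    unit_ids: list[str]
    dates: pd.DatetimeIndex
    source: str
    definition: EPEDefinition
    indicator: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=float)
        if self.indicator.shape != (len(self.unit_ids), len(self.dates)):
            raise ValueError("indicator must be (n_units, n_days)")
        finite = self.indicator[~np.isnan(self.indicator)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("indicators must be 0, 1, or NaN")

    def aligned_with(self, other: "EPEMatrix") -> None:
        if self.unit_ids != other.unit_ids or not self.dates.equals(other.dates):
            raise AlignmentError("EPE matrices are not aligned on units/dates")


DISTANCE_STRATA = ("0–7 km", "7–30 km", ">30 km")


@dataclass
class DistanceProfile:
    """Mean daily distance (km) from a unit centroid to the nearest
    operating station, with its distance stratum.

    Stratum convention: [0, 7) -> "0-7 km", [7, 30] -> "7-30 km",
    (30, inf) -> ">30 km".
    """

    unit_id: str
    mean_daily_distance_km: float
    stratum: str = field(init=False)

    def __post_init__(self) -> None:
        if self.mean_daily_distance_km < 0:
            raise ValueError("distance must be >= 0")
        self.stratum = distance_stratum(self.mean_daily_distance_km)


def distance_stratum(d_km: float) -> str:
    """Map a mean distance to its stratum label ([0,7), [7,30], (30,inf))."""
    if d_km < 7.0:
        return DISTANCE_STRATA[0]
    if d_km <= 30.0:
        return DISTANCE_STRATA[1]
    return DISTANCE_STRATA[2]


@dataclass(frozen=True)
class Contingency2x2:
    """Paired 2x2 agreement counts (rater A x rater B, EPE=1/0)."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for v in (self.n11, self.n10, self.n01, self.n00):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)

    def __add__(self, other: "Contingency2x2") -> "Contingency2x2":
        return Contingency2x2(
            self.n11 + other.n11,
            self.n10 + other.n10,
            self.n01 + other.n01,
            self.n00 + other.n00,
        )


@dataclass
class KappaResult:
    """Cohen's kappa with its asymptotic SE, 95% CI and Landis-Koch band."""

    kappa: float
    p_o: float
    p_e: float
    se: float
    ci95: tuple[float, float]
    n: int
    label: str
    defined: bool
    table: Contingency2x2 | None = None


@dataclass
class MatchedStrata:
    """Referent / covariate-matched / unmatched unit partition."""

    referent: list[str]
    matched: list[str]
    unmatched: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.referent), set(self.matched), set(self.unmatched)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("referent/matched/unmatched must be disjoint")
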