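"""Self-contained synthetic study region generator.

Emulates the data regime the agreement analysis needs: a square planar
region tessellated into square tracts with spatially autocorrelated
demographics and a social-vulnerability percentile; a smooth elevation
surface; a "truth" daily precipitation field with correlated wet/dry
occurrence and gamma-marginal wet amounts; a station network whose
siting density can be biased away from high-vulnerability tracts; and
two derived gridded products — a fine station-interpolated product
(inverse-distance weighting, the stylized analogue of an interpolated
climate surface) and a coarse assimilation-style product (block-averaged
truth with multiplicative noise, disaggregated to 24 hourly layers).

Every draw is controlled by ``RegionConfig.seed``; independent substreams
are derived with fixed spawn keys so each stage is individually
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box

from .distances import euclidean_km
from .errors import ConfigurationError, InterpolationError
from .fields import exponential_gaussian_field
from .types import (
    DailyGrid,
    ExposureUnit,
    GridSpec,
    HourlyGrid,
    PrecipSeries,
    Station,
    StationNetwork,
)

__all__ = [
    "RegionConfig",
    "SyntheticRegion",
    "generate_region",
    "generate_truth_field",
    "place_stations",
    "derive_products",
]

# fixed substream keys so stages are individually reproducible
_STREAMS = {
    "demographics": 0,
    "elevation": 1,
    "truth": 2,
    "stations": 3,
    "observations": 4,
    "products": 5,
}

_MEAN_OUTAGE_DAYS = 10.0


@dataclass(frozen=True)
class RegionConfig:
    """Declarative configuration of a synthetic study region.

    Defaults describe the standard biased-siting regime used throughout:
    a 120 km square with 12x12 tracts, two years of days, 30 stations
    whose placement avoids high-SVI tracts, a 30 km spatial correlation
    length (the scale at which a single station's influence decays), and
    a wet-day gamma amount distribution typical of mid-latitude daily
    precipitation.
    """

    region_size_km: float = 120.0
    n_tracts_side: int = 12
    n_days: int = 730
    n_stations: int = 30
    siting_bias: float = 8.0
    wet_prob: float = 0.35
    spatial_range_km: float = 30.0
    gamma_shape: float = 0.8
    gamma_scale: float = 8.0
    obs_noise_sd: float = 0.5
    missing_rate: float = 0.05
    qc_flag_rate: float = 0.005
    seed: int = 0
    fine_cell_km: float = 2.0
    coarse_cell_km: float = 12.0
    assim_noise_sd: float = 0.3
    hourly_alpha: float = 0.3
    start_date: str = "2011-01-01"

    def __post_init__(self) -> None:
        def bad(name, why):
            raise ConfigurationError(f"{name}: {why}")

        if self.region_size_km <= 0:
            bad("region_size_km", "must be positive")
        if self.n_tracts_side < 2:
            bad("n_tracts_side", "must be >= 2")
        if self.n_days < 1:
            bad("n_days", "must be >= 1")
        if self.n_stations < 1:
            bad("n_stations", "must be >= 1")
        if self.siting_bias < 0:
            bad("siting_bias", "must be >= 0")
        for name in ("wet_prob",):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0) and v != 0.0:
                bad(name, "must lie in [0, 1)")
        for name in ("missing_rate", "qc_flag_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad(name, "must lie in [0, 1]")
        for name in ("spatial_range_km", "gamma_shape", "gamma_scale",
                     "fine_cell_km", "coarse_cell_km"):
            if getattr(self, name) <= 0:
                bad(name, "must be positive")
        if self.obs_noise_sd < 0:
            bad("obs_noise_sd", "must be >= 0")
        if self.assim_noise_sd < 0:
            bad("assim_noise_sd", "must be >= 0")
        n_fine = self.region_size_km / self.fine_cell_km
        if abs(n_fine - round(n_fine)) > 1e-9:
            bad("fine_cell_km", "must divide region_size_km")
        ratio = self.coarse_cell_km / self.fine_cell_km
        if abs(ratio - round(ratio)) > 1e-9:
            bad("coarse_cell_km", "must be an integer multiple of fine_cell_km")
        n_coarse = self.region_size_km / self.coarse_cell_km
        if abs(n_coarse - round(n_coarse)) > 1e-9:
            bad("coarse_cell_km", "must divide region_size_km")
        if self.n_days < 365:
            warnings.warn(
                "n_days < 365: percentile thresholds may be unstable",
                stacklevel=2,
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the seed."""
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    @property
    def fine_spec(self) -> GridSpec:
        n = int(round(self.region_size_km / self.fine_cell_km))
        return GridSpec(0.0, 0.0, self.fine_cell_km, self.fine_cell_km, n, n)

    @property
    def coarse_spec(self) -> GridSpec:
        n = int(round(self.region_size_km / self.coarse_cell_km))
        return GridSpec(0.0, 0.0, self.coarse_cell_km, self.coarse_cell_km, n, n)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticRegion:
    """Everything the downstream pipeline needs, in one bundle."""

    config: RegionConfig
    units: list[ExposureUnit]
    elevation: np.ndarray  # (n_rows, n_cols) km, on the fine grid
    truth: DailyGrid
    stations: StationNetwork
    interp_product: DailyGrid = field(default=None)  # type: ignore[assignment]
    assim_product: HourlyGrid = field(default=None)  # type: ignore[assignment]


def _tract_polygons(cfg: RegionConfig) -> list:
    side = cfg.region_size_km / cfg.n_tracts_side
    polys = []
    for i in range(cfg.n_tracts_side):
        for j in range(cfg.n_tracts_side):
            polys.append(box(j * side, i * side, (j + 1) * side, (i + 1) * side))
    return polys


def _generate_units(cfg: RegionConfig) -> list[ExposureUnit]:
    """Tracts with spatially smooth Dirichlet-style demographics.

    Race composition comes from a softmax over correlated Gaussian logit
    surfaces (white / Black / Native American / Asian / other), Hispanic
    ethnicity from a separate logistic surface; percent minority is the
    complement of the non-Hispanic-white share.  SVI is the percentile
    rank of a poverty + minority composite, so its marginal over units is
    uniform by construction.
    """
    rng = cfg.rng("demographics")
    n = cfg.n_tracts_side
    side = cfg.region_size_km / n
    # 8 smooth logit surfaces at tract resolution
    g = exponential_gaussian_field(8, n, n, side, cfg.spatial_range_km, rng)
    g = g.reshape(8, n * n)

    logit_mu = {"white": 1.5, "black": -0.5, "native_american": -2.0,
                "asian": -1.2, "other": -1.5}
    logit_sd = {"white": 1.0, "black": 1.8, "native_american": 2.2,
                "asian": 1.5, "other": 1.0}
    logits = np.stack(
        [logit_mu[k] + logit_sd[k] * g[i]
         for i, k in enumerate(logit_mu)]
    )
    # the Native American logit carries a dominant tract-level nugget on
    # top of its smooth surface: high-NA tracts occur as scattered
    # pockets, giving every realization genuine share variation whose
    # association with station access is driven by vulnerability-biased
    # siting rather than by shared smooth geography
    logits[2] = -2.0 + 2.2 * rng.standard_normal(n * n)
    shares = np.exp(logits - logits.max(axis=0))
    shares /= shares.sum(axis=0)
    pct_white, pct_black, pct_na, pct_asian, _ = 100.0 * shares

    pct_hispanic = 100.0 / (1.0 + np.exp(-(-2.0 + 1.5 * g[5])))
    nh_white = pct_white * (1.0 - pct_hispanic / 100.0)
    pct_minority = 100.0 - nh_white

    def _z(v):
        return (v - v.mean()) / (v.std() + 1e-12)

    # poverty tracks minority share plus its own surface, with an extra
    # Native-American term emulating the high poverty of reservation
    # tracts — the pathway through which siting bias reaches NA share
    minority_z = _z(pct_minority)
    na_z = _z(pct_na)
    pct_poverty = 100.0 / (
        1.0 + np.exp(-(-1.6 + 1.0 * g[6] + 0.4 * minority_z + 0.5 * na_z))
    )

    density = np.exp(-1.0 + 1.2 * g[7])  # 1,000 persons / km^2

    # SVI composite: socioeconomic + minority-status domains, the latter
    # carrying an explicit Native-American component
    composite = _z(pct_poverty) + _z(pct_minority) + 1.0 * na_z
    order = np.argsort(composite, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(composite))
    svi = (rank + 0.5) / len(composite)

    terciles = np.quantile(density, [1 / 3, 2 / 3])
    urb = np.where(
        density <= terciles[0],
        "rural",
        np.where(density <= terciles[1], "urban cluster", "urban"),
    )

    polys = _tract_polygons(cfg)
    units = []
    for k, poly in enumerate(polys):
        units.append(
            ExposureUnit(
                unit_id=f"T{k:04d}",
                polygon=poly,
                pct_minority=float(pct_minority[k]),
                pct_black=float(pct_black[k]),
                pct_native_american=float(pct_na[k]),
                pct_asian=float(pct_asian[k]),
                pct_hispanic=float(pct_hispanic[k]),
                pct_poverty=float(pct_poverty[k]),
                svi=float(svi[k]),
                urbanicity=str(urb[k]),
                pop_density=float(density[k]),
            )
        )
    return units


def _generate_elevation(cfg: RegionConfig) -> np.ndarray:
    """Smooth elevation surface (km) on the fine grid, floored at sea level."""
    rng = cfg.rng("elevation")
    spec = cfg.fine_spec
    g = exponential_gaussian_field(
        1, spec.n_rows, spec.n_cols, spec.dx, max(cfg.spatial_range_km, 20.0), rng
    )[0]
    return np.clip(0.6 + 0.35 * g, 0.0, None)


def generate_truth_field(config: RegionConfig) -> DailyGrid:
    """Simulate the daily "truth" precipitation field on the fine grid.

    Wet/dry occurrence is a thresholded correlated Gaussian field with
    marginal wet probability ``wet_prob``; wet amounts are a Gaussian
    copula transform to the gamma(shape, scale) marginal, so extremes are
    spatially coherent and dry cells are exactly zero.
    """
    rng = config.rng("truth")
    spec = config.fine_spec
    if config.wet_prob == 0.0:
        values = np.zeros((config.n_days, spec.n_rows, spec.n_cols))
        return DailyGrid(spec, config.dates, values)

    g_occ = exponential_gaussian_field(
        config.n_days, spec.n_rows, spec.n_cols, spec.dx,
        config.spatial_range_km, rng,
    )
    g_amt = exponential_gaussian_field(
        config.n_days, spec.n_rows, spec.n_cols, spec.dx,
        config.spatial_range_km, rng,
    )
    wet = g_occ > stats.norm.ppf(1.0 - config.wet_prob)
    values = np.zeros_like(g_amt)
    u = stats.norm.cdf(g_amt[wet])
    values[wet] = stats.gamma.ppf(u, config.gamma_shape, scale=config.gamma_scale)
    return DailyGrid(spec, config.dates, values)


def _outage_mask(n_days: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask (True = station down) built from geometric-length blocks."""
    mask = np.zeros(n_days, dtype=bool)
    if rate <= 0:
        return mask
    p_start = min(1.0, rate / _MEAN_OUTAGE_DAYS)
    starts = np.flatnonzero(rng.random(n_days) < p_start)
    for s in starts:
        length = rng.geometric(1.0 / _MEAN_OUTAGE_DAYS)
        mask[s : s + length] = True
    return mask


def place_stations(
    units: list[ExposureUnit],
    elevation: np.ndarray,
    config: RegionConfig,
    truth: DailyGrid | None = None,
) -> StationNetwork:
    """Sample station locations with SVI-dependent siting intensity.

    Placement probability per tract is proportional to
    exp(-siting_bias * SVI), so positive bias thins the network in
    high-vulnerability tracts.  Each station receives an operational
    outage mask (geometric-length blocks, station-specific rates spread
    around ``missing_rate``) and QC flags; observed values are the truth
    field at the station's cell plus truncated Gaussian gauge noise.
    """
    rng = config.rng("stations")
    svi = np.array([u.svi for u in units])
    weights = np.exp(-config.siting_bias * svi)
    weights /= weights.sum()
    tract_idx = rng.choice(len(units), size=config.n_stations, p=weights)

    side = config.region_size_km / config.n_tracts_side
    xy = np.empty((config.n_stations, 2))
    for k, t in enumerate(tract_idx):
        minx, miny, maxx, maxy = units[t].polygon.bounds
        xy[k] = [
            minx + rng.random() * (maxx - minx),
            miny + rng.random() * (maxy - miny),
        ]
    del side

    obs_rng = config.rng("observations")
    if truth is None:
        truth = generate_truth_field(config)
    spec = truth.spec
    dates = truth.dates

    stations = []
    for k in range(config.n_stations):
        i, j = spec.cell_of(xy[k, 0], xy[k, 1])
        base = truth.values[:, i, j].copy()
        if config.obs_noise_sd > 0:
            noise = obs_rng.normal(0.0, config.obs_noise_sd, size=len(base))
            base = np.where(base > 0, np.clip(base + noise, 0.0, None), 0.0)
        # two-tier station quality: half the network runs near-complete
        # records, the rest suffers heavier outages, so the 99%
        # completeness screen splits the network by construction
        if obs_rng.random() < 0.5:
            rate = 0.1 * config.missing_rate
        else:
            rate = min(0.5, config.missing_rate * (0.5 + obs_rng.exponential(1.0)))
        down = _outage_mask(len(base), rate, obs_rng)
        values = base.copy()
        values[down] = np.nan
        flags = obs_rng.random(len(base)) < config.qc_flag_rate
        flags &= ~down
        series = PrecipSeries(f"S{k:03d}", dates, values, flags)
        stations.append(Station(f"S{k:03d}", float(xy[k, 0]), float(xy[k, 1]), series))
    return StationNetwork(stations, crs="planar_km")


def derive_products(
    truth: DailyGrid,
    network: StationNetwork,
    config: RegionConfig,
) -> tuple[DailyGrid, HourlyGrid]:
    """Build the two stylized gridded products.

    interp_product: inverse-distance-weighted (power 2) interpolation of
    each day's clean station observations onto the fine grid — the
    station-derived analogue of an interpolated climate surface.

    assim_product: truth block-averaged to the coarse grid, perturbed by
    mean-preserving multiplicative lognormal noise, then split into 24
    hourly layers by Dirichlet simplex weights that sum exactly to the
    daily value.
    """
    rng = config.rng("products")
    spec = truth.spec
    n_days = truth.values.shape[0]

    # --- IDW interpolation onto the fine grid ---
    xc, yc = np.meshgrid(spec.x_centers, spec.y_centers)
    cells = np.column_stack([xc.ravel(), yc.ravel()])
    dist = euclidean_km(cells, network.coords)
    exact = dist < 1e-9
    with np.errstate(divide="ignore"):
        w_all = 1.0 / dist**2
    vals = network.value_matrix(apply_qc=True)  # (n_days, n_stations)
    avail = ~np.isnan(vals)

    interp = np.empty((n_days, spec.n_rows, spec.n_cols))
    for d in range(n_days):
        a = avail[d]
        if not a.any():
            date = truth.dates[d].date()
            raise InterpolationError(
                f"no operating station with data on {date}; network degenerate"
            )
        w = w_all[:, a]
        v = vals[d, a]
        finite = np.isfinite(w)
        num = np.where(finite, w, 0.0) @ v
        den = np.where(finite, w, 0.0).sum(axis=1)
        day_field = num / den
        hit = exact[:, a]
        if hit.any():
            rows, cols_ = np.nonzero(hit)
            day_field[rows] = v[cols_]
        interp[d] = day_field.reshape(spec.n_rows, spec.n_cols)
    interp_product = DailyGrid(spec, truth.dates, interp)

    # --- coarse assimilation-style product ---
    cspec = config.coarse_spec
    f = int(round(cspec.dx / spec.dx))
    nr, nc = cspec.n_rows, cspec.n_cols
    block = truth.values.reshape(n_days, nr, f, nc, f).mean(axis=(2, 4))
    if config.assim_noise_sd > 0:
        z = rng.standard_normal(block.shape)
        s = config.assim_noise_sd
        block = block * np.exp(s * z - s**2 / 2.0)
    hourly = disaggregate_hourly(block, config.hourly_alpha, rng)
    assim_product = HourlyGrid(cspec, truth.dates, hourly)
    return interp_product, assim_product


def disaggregate_hourly(
    daily: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Split a (day, row, col) field into 24 hourly layers by Dirichlet
    simplex weights, conserving each daily total."""
    n_days, nr, nc = daily.shape
    gamma_w = rng.gamma(alpha, size=(n_days, 24, nr, nc))
    wsum = gamma_w.sum(axis=1, keepdims=True)
    # degenerate all-zero draws (possible underflow at tiny alpha) -> uniform
    flat = wsum <= 0
    if flat.any():
        gamma_w = np.where(np.broadcast_to(flat, gamma_w.shape), 1.0, gamma_w)
        wsum = gamma_w.sum(axis=1, keepdims=True)
    return daily[:, None, :, :] * gamma_w / wsum


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Generate the full synthetic region: units, elevation, truth field,
    station network, and the two derived gridded products.  Deterministic
    given ``config.seed``."""
    units = _generate_units(config)
    elevation = _generate_elevation(config)
    truth = generate_truth_field(config)
    stations = place_stations(units, elevation, config, truth=truth)
    interp, assim = derive_products(truth, stations, config)
    return SyntheticRegion(
        config=config,
        units=units,
        elevation=elevation,
        truth=truth,
        stations=stations,
        interp_product=interp,
        assim_product=assim,
    )
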