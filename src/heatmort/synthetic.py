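"""Synthetic study region with known ground truth.

Emulates the statistical structure of the data a national heat-mortality
analysis rests on — a spatial universe of districts grouped into states,
annual population snapshots by sex and 5-year age band, daily station and
district temperatures with seasonal, autoregressive and urban-heat-island
structure, and Poisson death counts whose temperature response is a known
:class:`TrueRiskModel` — so every downstream stage (interpolation, exposure
fitting, attribution, projection) has a recovery test against ground truth.

What it deliberately does *not* emulate: real geography or population
pyramids, sub-daily temperature structure, reporting delays, or epidemic
shocks; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from pydantic import BaseModel, ConfigDict, model_validator

from .containers import (
    FIVE_YEAR_EDGES,
    FIVE_YEAR_LABELS,
    SEXES,
    STREAMS,
    aggregate_to_stream,
    band_midpoints,
    daily_index,
    stratified_daily,
)
from .exposure import build_lag_matrix, interpolate_population_daily

__all__ = [
    "RegionConfig", "TrueRiskModel", "BaselineSpec", "Region",
    "TemperatureFields", "SyntheticTruth",
    "generate_region", "generate_temperature_fields",
    "generate_mortality_counts", "build_reporting_tables",
]


class RegionConfig(BaseModel):
    """Configuration of the synthetic study region.

    Defaults describe a small country-like region: a handful of states, a
    few hundred thousand inhabitants per district, a temperate seasonal
    climate with autocorrelated weather, and a moderate daily-mean urban
    heat-island offset.
    """

    model_config = ConfigDict(extra="forbid")

    n_states: int = 5
    n_districts: int = 20
    n_stations: int = 30
    bbox: tuple[float, float, float, float] = (6.0, 47.0, 15.0, 55.0)  # lon0, lat0, lon1, lat1
    urban_fraction: float = 0.25
    heat_island_amplitude: float = 10.0  # deg C; urban offsets reach up to this
    years: tuple[int, int] = (2015, 2020)
    seed: int = 0
    # population
    district_pop_mean: float = 200_000.0
    old_age_share: float = 0.13  # national share of the 75+ population
    # weather
    t_mean: float = 9.5
    seasonal_amplitude: float = 9.0
    peak_doy: int = 196  # mid-July
    lon_gradient: float = 0.1   # deg C per degree longitude
    lat_gradient: float = -0.6  # deg C per degree latitude (warmer south)
    ar_phi: float = 0.7
    ar_sigma: float = 2.0
    station_noise_sd: float = 0.5
    grid_resolution: float = 0.5  # degrees

    @model_validator(mode="after")
    def _check(self):
        if self.n_districts < self.n_states:
            raise ValueError("n_districts must be >= n_states")
        if self.heat_island_amplitude < 0:
            raise ValueError("heat_island_amplitude must be >= 0")
        lon0, lat0, lon1, lat1 = self.bbox
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError("bbox is degenerate")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must be in [0, 1]")
        return self


@dataclass
class TrueRiskModel:
    """Ground-truth exposure-response: f(T) = 1 + slope * max(0, w.T - thr)^p.

    ``lag_weights`` distribute the effect over the current and preceding
    days and must sum to 1; ``dow_factors`` are seven multiplicative
    reporting factors with mean exactly 1.
    """

    lag_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.3, 0.2]))
    threshold: float = 20.0
    slope: float = 0.04      # risk per (deg C above threshold)^exponent
    exponent: float = 1.2
    dow_factors: np.ndarray = field(default_factory=lambda: _default_dow())

    def __post_init__(self):
        self.lag_weights = np.asarray(self.lag_weights, dtype=float)
        self.dow_factors = np.asarray(self.dow_factors, dtype=float)
        if not np.isclose(self.lag_weights.sum(), 1.0):
            raise ValueError("lag_weights must sum to 1")
        if self.exponent < 1.0:
            raise ValueError("exponent must be >= 1")
        if self.dow_factors.shape != (7,) or not np.isclose(
                self.dow_factors.mean(), 1.0):
            raise ValueError("dow_factors must be 7 values with mean exactly 1")
        if (self.dow_factors <= 0).any():
            raise ValueError("dow_factors must be positive")

    def risk_factor(self, temps: np.ndarray) -> np.ndarray:
        """Evaluate f on a daily series (T,) or (T, I); >= 1 everywhere."""
        lagged = build_lag_matrix(np.asarray(temps, dtype=float),
                                  len(self.lag_weights) - 1)
        eff = lagged @ self.lag_weights
        return 1.0 + self.slope * np.maximum(eff - self.threshold, 0.0) ** self.exponent


def _default_dow() -> np.ndarray:
    f = np.array([1.03, 1.01, 1.00, 0.99, 0.97, 0.98, 1.02])
    return f / f.mean()


@dataclass
class BaselineSpec:
    """Gompertz-type per-stratum daily death rates, log-linear in time.

    rate(age, sex, t) = a * exp(b * age_mid) * sex_factor * exp(trend * tau)
    per person-year, divided by 365.25 for the daily rate; ``tau`` is years
    since the calendar start.
    """

    gompertz_a: float = 2e-5     # per person-year at age 0
    gompertz_b: float = 0.1      # per year of age
    male_factor: float = 1.4
    annual_trend: float = -0.005  # log-rate change per year

    def daily_rates(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """(T, S, A) per-person-day rates."""
        mids = band_midpoints(FIVE_YEAR_EDGES)
        base = self.gompertz_a * np.exp(self.gompertz_b * mids)  # (A,)
        sex_f = np.array([1.0, self.male_factor])
        tau = (dates - dates[0]).days.values / 365.25
        rates = (base[None, None, :] * sex_f[None, :, None]
                 * np.exp(self.annual_trend * tau)[:, None, None]) / 365.25
        if (rates < 0).any():
            raise ValueError("negative baseline rate")
        return rates


@dataclass
class Region:
    """Districts plus annual population snapshots."""

    districts: pd.DataFrame  # district, state, lon, lat, urban, heat_island_scale
    population_snapshots: xr.DataArray  # (year, district, sex, age)
    config: RegionConfig


@dataclass
class TemperatureFields:
    station_temps: xr.DataArray   # (time, station) with lon/lat coords
    district_temps: xr.DataArray  # (time, district), noise-free truth
    grid_temps: xr.DataArray      # (time, lat, lon)


@dataclass
class SyntheticTruth:
    """Ground-truth mortality surfaces for recovery tests."""

    district_temps: xr.DataArray
    expected_deaths: xr.DataArray  # (time, district, sex, age)
    realized_deaths: xr.DataArray  # integer Poisson draws, same index
    true_excess: xr.DataArray      # expected minus capped-expected
    cap_c: float
    risk_model: TrueRiskModel
    baseline: BaselineSpec


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _national_pyramid(old_age_share: float) -> np.ndarray:
    """5-year-band population weights with an exact 75+ share."""
    base = np.array([1.0] * 12  # 0-60 in 5-year steps
                    + [0.9, 0.85, 0.8, 0.7, 0.55, 0.35, 0.15, 0.04])
    old = np.zeros_like(base)
    old[15:] = base[15:]   # bands from 75 upward
    young = base - old
    w = (young / young.sum() * (1 - old_age_share)
         + old / old.sum() * old_age_share)
    return w / w.sum()


def generate_region(config: RegionConfig) -> Region:
    """Create districts, state memberships, and annual population snapshots.

    Districts receive uniform reference coordinates inside the bounding box
    and are grouped into longitudinally contiguous states.  The largest
    ``urban_fraction`` of districts is flagged urban.  Population snapshots
    are dated Dec 31 of each year from the year before the calendar start
    through the last year, so daily interpolation covers the whole range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_districts
    lon0, lat0, lon1, lat1 = config.bbox
    lon = rng.uniform(lon0, lon1, n)
    lat = rng.uniform(lat0, lat1, n)
    ids = [f"D{i:03d}" for i in range(n)]

    # contiguous longitude bands as states
    order = np.argsort(lon)
    state_of = np.empty(n, dtype=int)
    for rank, j in enumerate(order):
        state_of[j] = min(rank * config.n_states // n, config.n_states - 1)
    states = [f"S{k:02d}" for k in state_of]

    sizes = rng.lognormal(np.log(config.district_pop_mean) - 0.18, 0.6, n)
    n_urban = int(np.ceil(config.urban_fraction * n)) if config.urban_fraction > 0 else 0
    urban = np.zeros(n, dtype=bool)
    if n_urban:
        urban[np.argsort(sizes)[-n_urban:]] = True
    hi_scale = np.where(urban, rng.uniform(0.3, 1.0, n), 0.0)

    districts = pd.DataFrame({
        "district": ids, "state": states, "lon": lon, "lat": lat,
        "urban": urban, "heat_island_scale": hi_scale,
    })

    pyramid = _national_pyramid(config.old_age_share)  # (A,)
    sex_split = np.tile([[0.5], [0.5]], (1, len(pyramid)))
    sex_split[:, 15:] = [[0.58], [0.42]]  # female excess at old ages
    years = np.arange(config.years[0] - 1, config.years[1] + 1)
    growth = rng.normal(0.002, 0.003, n)
    # mild per-district pyramid noise, renormalized so shares stay close
    noise = rng.normal(1.0, 0.03, size=(n, len(pyramid)))
    A = len(pyramid)
    pop = np.empty((len(years), n, 2, A))
    for i in range(n):
        w = np.maximum(pyramid * noise[i], 1e-12)
        w = w / w.sum()
        for yi, y in enumerate(years):
            total = sizes[i] * (1 + growth[i]) ** (y - years[0])
            pop[yi, i] = sex_split * (total * w)[None, :]
    snapshots = xr.DataArray(
        pop, dims=("year", "district", "sex", "age"),
        coords={"year": years, "district": ids, "sex": list(SEXES),
                "age": FIVE_YEAR_LABELS},
    )
    return Region(districts=districts, population_snapshots=snapshots,
                  config=config)


def _field_values(config: RegionConfig, lon: np.ndarray, lat: np.ndarray,
                  dates: pd.DatetimeIndex, anomaly: np.ndarray) -> np.ndarray:
    """Deterministic field + shared anomaly at given points: (T, n_points)."""
    lon0, lat0, lon1, lat1 = config.bbox
    doy = dates.dayofyear.values
    seasonal = config.t_mean + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_doy) / 365.25)
    spatial = (config.lon_gradient * (lon - (lon0 + lon1) / 2)
               + config.lat_gradient * (lat - (lat0 + lat1) / 2))
    return seasonal[:, None] + spatial[None, :] + anomaly[:, None]


def generate_temperature_fields(region: Region,
                                config: RegionConfig | None = None
                                ) -> TemperatureFields:
    """Daily mean temperatures for stations, districts and a regular grid.

    The field is a seasonal sinusoid (peaking mid-July) plus a smooth
    spatial gradient plus a single AR(1) weather anomaly shared across the
    region.  District series are the noise-free truth at the district's
    reference point plus its constant heat-island offset; station series add
    independent Gaussian measurement noise.
    """
    config = config or region.config
    dates = daily_index(*config.years)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    T = len(dates)
    anomaly = np.empty(T)
    eps = rng.normal(0.0, config.ar_sigma, T)
    anomaly[0] = eps[0] / np.sqrt(max(1 - config.ar_phi ** 2, 1e-12))
    for t in range(1, T):
        anomaly[t] = config.ar_phi * anomaly[t - 1] + eps[t]

    d = region.districts
    district_vals = _field_values(config, d["lon"].values, d["lat"].values,
                                  dates, anomaly)
    district_vals += (config.heat_island_amplitude
                      * d["heat_island_scale"].values)[None, :]
    district_temps = xr.DataArray(
        district_vals, dims=("time", "district"),
        coords={"time": dates, "district": list(d["district"])})

    lon0, lat0, lon1, lat1 = config.bbox
    st_lon = rng.uniform(lon0, lon1, config.n_stations)
    st_lat = rng.uniform(lat0, lat1, config.n_stations)
    st_vals = _field_values(config, st_lon, st_lat, dates, anomaly)
    st_vals += rng.normal(0.0, config.station_noise_sd, st_vals.shape)
    station_ids = [f"W{j:03d}" for j in range(config.n_stations)]
    station_temps = xr.DataArray(
        st_vals, dims=("time", "station"),
        coords={"time": dates, "station": station_ids,
                "lon": ("station", st_lon), "lat": ("station", st_lat)})

    g_lon = np.arange(lon0, lon1 + 1e-9, config.grid_resolution)
    g_lat = np.arange(lat0, lat1 + 1e-9, config.grid_resolution)
    glon, glat = np.meshgrid(g_lon, g_lat)
    g_vals = _field_values(config, glon.ravel(), glat.ravel(), dates, anomaly)
    grid_temps = xr.DataArray(
        g_vals.reshape(T, len(g_lat), len(g_lon)),
        dims=("time", "lat", "lon"),
        coords={"time": dates, "lat": g_lat, "lon": g_lon})

    return TemperatureFields(station_temps=station_temps,
                             district_temps=district_temps,
                             grid_temps=grid_temps)


def generate_mortality_counts(region: Region, district_temps: xr.DataArray,
                              truth: TrueRiskModel | None = None,
                              baseline: BaselineSpec | None = None,
                              cap_c: float = 20.0) -> SyntheticTruth:
    """Expected and Poisson-realized deaths under the ground-truth risk model.

    expected = baseline(t) x population(t) x f_true(lagged T) x dow(weekday);
    ``true_excess`` is expected minus the expectation under the capped
    temperature series (cap applied before lag construction).
    """
    truth = truth or TrueRiskModel()
    baseline = baseline or BaselineSpec()
    dates = pd.DatetimeIndex(district_temps.coords["time"].values)
    ids = [str(x) for x in district_temps.coords["district"].values]

    pop = interpolate_population_daily(region.population_snapshots, dates)
    pop = pop.sel(district=ids).transpose("time", "district", "sex", "age").values
    rates = baseline.daily_rates(dates)  # (T, S, A)
    dow = truth.dow_factors[dates.weekday.values]

    temps = np.asarray(district_temps.values, dtype=float)
    f_obs = truth.risk_factor(temps)                       # (T, I)
    f_cap = truth.risk_factor(np.minimum(temps, cap_c))    # (T, I)

    core = rates[:, None, :, :] * pop * dow[:, None, None, None]
    expected = core * f_obs[:, :, None, None]
    capped_expected = core * f_cap[:, :, None, None]

    rng = np.random.default_rng(np.random.SeedSequence([region.config.seed, 3]))
    realized = rng.poisson(expected).astype(np.int64)

    return SyntheticTruth(
        district_temps=district_temps,
        expected_deaths=stratified_daily(expected, dates, ids),
        realized_deaths=stratified_daily(realized, dates, ids),
        true_excess=stratified_daily(expected - capped_expected, dates, ids),
        cap_c=cap_c, risk_model=truth, baseline=baseline)


def build_reporting_tables(truth: SyntheticTruth,
                           district_states: pd.Series | dict
                           ) -> dict[str, pd.DataFrame]:
    """The three aggregation streams of the realized deaths.

    Returns daily x state x sex, ISO-weekly x state x sex x broad-age, and
    ISO-weekly x national x sex x fine-age tables; each cell is the exact sum
    of the daily district records it covers, partial edge weeks dropped.
    """
    return {s: aggregate_to_stream(truth.realized_deaths, s, district_states)
            for s in STREAMS}
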