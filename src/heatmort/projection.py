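"""Climate-scenario projection of annual heat-related excess mortality.

A fitted mortality ensemble and a fitted interpolator are applied to each
member of a climate-projection temperature ensemble: member grid
temperatures are downscaled to districts (no bias correction), daily excess
is computed via the capped-temperature counterfactual with population and
baseline mortality frozen at a reference date, summed per calendar year, and
summarized across members by the median and the empirical 10th/90th
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .containers import BROAD_EDGES, band_projection
from .exposure import build_lag_matrix

__all__ = ["ClimateEnsemble", "ProjectionSummary", "project_scenario",
           "apply_demographic_scenario", "annual_excess_frozen"]


@dataclass
class ClimateEnsemble:
    """member x day x grid-point daily mean temperatures for one scenario."""

    scenario: str
    temps: np.ndarray           # (n_members, n_days, n_points)
    dates: pd.DatetimeIndex
    coords: np.ndarray          # (n_points, 2) lon/lat

    def __post_init__(self):
        self.temps = np.asarray(self.temps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.temps.ndim != 3:
            raise ValueError("temps must be (member, day, point)")
        if self.temps.shape[1] != len(self.dates):
            raise ValueError("temps and dates disagree on day count")
        if self.temps.shape[2] != self.coords.shape[0]:
            raise ValueError("temps and coords disagree on grid points")

    @property
    def n_members(self) -> int:
        return self.temps.shape[0]

    @classmethod
    def from_netcdf_dataset(cls, ds: xr.Dataset, var: str = "tmean"):
        """Build from a (member, time, lat, lon) dataset, flattening the grid."""
        da = ds[var].transpose("member", "time", "lat", "lon")
        lat = ds["lat"].values
        lon = ds["lon"].values
        glon, glat = np.meshgrid(lon, lat)
        coords = np.column_stack([glon.ravel(), glat.ravel()])
        temps = da.values.reshape(da.shape[0], da.shape[1], -1)
        return cls(scenario=str(ds.attrs.get("scenario", "unknown")),
                   temps=temps, dates=pd.DatetimeIndex(ds["time"].values),
                   coords=coords)


@dataclass
class ProjectionSummary:
    """Per-year median and 10th/90th percentile excess across members."""

    scenario: str
    years: np.ndarray
    median: np.ndarray
    p10: np.ndarray
    p90: np.ndarray
    per_member: np.ndarray  # (n_members, n_years)
    per_million: np.ndarray | None = None

    def __post_init__(self):
        if not (np.all(self.p10 <= self.median + 1e-12)
                and np.all(self.median <= self.p90 + 1e-12)):
            raise ValueError("percentile ordering violated (p10 <= median <= p90)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "median": self.median,
                           "p10": self.p10, "p90": self.p90})
        if self.per_million is not None:
            df["median_per_million"] = self.per_million
        return df

    def factor_increase(self, reference_years=(2015, 2024),
                        final_decade: int = 10) -> float:
        """Last-decade median annual excess divided by the reference-period
        median of the same scenario."""
        ref = np.median(self.per_member[:, np.isin(
            self.years, np.arange(reference_years[0], reference_years[1] + 1))])
        last = np.median(self.per_member[:, -final_decade:])
        return float(last / ref) if ref > 0 else np.nan


def annual_excess_frozen(instance, district_temps: np.ndarray,
                         dates: pd.DatetimeIndex, weights_gsa: np.ndarray,
                         cap_c: float = 20.0, dow: bool = False) -> pd.Series:
    """Calendar-year sums of daily national excess with frozen demography.

    ``weights_gsa`` is the per-(district, sex, broad-group) product of the
    frozen baseline rate and static population, ``sum_{age in g} rate(s, age)
    * pop(i, s, age)`` with shape (n_districts, n_sex, n_groups).  Because
    baseline and population are constant in time, the daily national excess
    reduces to a weighted sum of response-factor differences, which keeps
    century-scale member loops cheap.
    """
    temps = np.asarray(district_temps, dtype=float)
    lag = build_lag_matrix(temps, instance.lag_days)
    lag_cap = build_lag_matrix(np.minimum(temps, cap_c), instance.lag_days)
    df = instance.response_factors(lag) - instance.response_factors(lag_cap)
    daily = np.einsum("tisg,isg->t", df, weights_gsa)
    if dow:
        daily = daily * instance.dow_factors_[dates.weekday.values]
    s = pd.Series(daily, index=dates)
    return s.groupby(s.index.year).sum()


def _frozen_weights(instance, population_base: xr.DataArray,
                    baseline_ref_date) -> np.ndarray:
    pop = population_base.transpose("district", "sex", "age").values
    ref = pd.DatetimeIndex([pd.Timestamp(baseline_ref_date)])
    rates = instance.baseline_rates(ref)[0]  # (S, A)
    proj = band_projection(BROAD_EDGES)      # (G, A)
    return np.einsum("isa,sa,ga->isg", pop, rates, proj)


def project_scenario(ensemble, interpolator, climate: ClimateEnsemble,
                     population_base: xr.DataArray, baseline_ref_date,
                     cap_c: float = 20.0, dow: bool = False,
                     per_million: bool = False) -> ProjectionSummary:
    """Project annual excess mortality for one scenario ensemble.

    Population is static (``population_base``: district x sex x age) and the
    baseline mortality rate is frozen at ``baseline_ref_date``; each member
    is downscaled with the fitted interpolator (no bias correction), excess
    is the capped-temperature counterfactual difference summed per calendar
    year, and the member distribution is summarized per year by its median
    and empirical (linearly interpolated) 10th/90th percentiles.
    """
    instances = getattr(ensemble, "instances_", None) or [ensemble]
    weights = [_frozen_weights(inst, population_base, baseline_ref_date)
               for inst in instances]
    years = np.unique(climate.dates.year)
    per_member = np.zeros((climate.n_members, len(years)))
    for m in range(climate.n_members):
        dt = interpolator.downscale_member(climate.temps[m], climate.coords)
        annual = None
        for inst, w in zip(instances, weights):
            a = annual_excess_frozen(inst, dt, climate.dates, w,
                                     cap_c=cap_c, dow=dow)
            annual = a if annual is None else annual + a
        per_member[m] = (annual / len(instances)).reindex(years).values
    median = np.quantile(per_member, 0.5, axis=0)
    p10 = np.quantile(per_member, 0.10, axis=0)
    p90 = np.quantile(per_member, 0.90, axis=0)
    pm = None
    if per_million:
        total_pop = float(population_base.sum())
        pm = median / total_pop * 1e6
    return ProjectionSummary(scenario=climate.scenario, years=years,
                             median=median, p10=p10, p90=p90,
                             per_member=per_member, per_million=pm)


def apply_demographic_scenario(population_base: xr.DataArray,
                               national_projection: xr.DataArray) -> xr.DataArray:
    """Scale district populations so national age-band totals follow a
    projection while each band's geographical distribution stays fixed at
    the base year.

    ``population_base`` has dims (district, sex, age); ``national_projection``
    has dims (year, sex, age) (or (year, age), applied to both sexes
    proportionally).  Returns (year, district, sex, age); the district sums
    match the projection exactly.
    """
    if "sex" not in national_projection.dims:
        base_sex_share = population_base.sum("district") \
            / population_base.sum(["district", "sex"])
        national_projection = national_projection * base_sex_share
    if list(national_projection.coords["age"].values) != \
            list(population_base.coords["age"].values):
        raise ValueError("age bands of projection and base population differ")
    national_base = population_base.sum("district")
    share = population_base / national_base
    out = share * national_projection
    return out.transpose("year", "district", "sex", "age")
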