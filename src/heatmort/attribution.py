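"""Heat-related excess mortality via the capped-temperature counterfactual.

Excess deaths on a day are the difference between the model's expected
deaths under the observed temperature history and under a counterfactual in
which the daily mean temperature series is capped (default 20 deg C) before
the lag vectors are built.  Any period in which observed and capped series
coincide over the full lag window therefore has exactly zero excess.
Summaries cover warm-day counts, per-million rates, heatwave event windows
and the within-year concentration of excess deaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["AttributionConfig", "cap_series", "excess_mortality",
           "warm_day_count", "event_summary", "event_share",
           "concentration_stats"]


@dataclass
class AttributionConfig:
    """Settings of the counterfactual attribution.

    ``cap_c`` is the temperature cap (deg C) defining no-heat baseline
    conditions; ``top_k`` the number of highest-excess days used by the
    concentration statistics; ``clip_negative`` optionally clips daily excess
    at zero for map-style reporting (estimates themselves are unclipped).
    """

    cap_c: float = 20.0
    per_million: bool = True
    event_window: tuple[str, str] | None = None
    top_k: int = 10
    clip_negative: bool = False

    def __post_init__(self):
        if not np.isfinite(self.cap_c):
            raise ValueError("cap_c must be finite")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def cap_series(temps: xr.DataArray | np.ndarray, cap_c: float = 20.0):
    """Elementwise min(T, cap); the counterfactual input series."""
    if isinstance(temps, xr.DataArray):
        return temps.clip(max=cap_c)
    return np.minimum(np.asarray(temps, dtype=float), cap_c)


def excess_mortality(ensemble, district_temps: xr.DataArray,
                     population_daily: xr.DataArray,
                     config: AttributionConfig | None = None,
                     baseline_frozen_at=None, dow: bool = True) -> xr.DataArray:
    """Daily stratified excess deaths (time, district, sex, age).

    Computed per ensemble instance as E(T) - E(min(T, cap)) and averaged;
    by linearity this equals the difference of the ensemble-mean
    expectations, which the tests assert.
    """
    config = config or AttributionConfig()
    instances = getattr(ensemble, "instances_", None) or [ensemble]
    acc = None
    for inst in instances:
        e_obs = inst.predict_expected(district_temps, population_daily,
                                      baseline_frozen_at=baseline_frozen_at,
                                      dow=dow)
        e_cap = inst.predict_expected(district_temps, population_daily,
                                      cap_c=config.cap_c,
                                      baseline_frozen_at=baseline_frozen_at,
                                      dow=dow)
        diff = e_obs - e_cap
        acc = diff if acc is None else acc + diff
    out = acc / len(instances)
    if config.clip_negative:
        out = out.clip(min=0.0)
    return out


def warm_day_count(district_temps: xr.DataArray,
                   threshold: float = 20.0) -> pd.DataFrame:
    """Days per district and calendar year with mean temperature strictly
    above the threshold."""
    dates = pd.DatetimeIndex(district_temps.coords["time"].values)
    warm = (np.asarray(district_temps.values, dtype=float) > threshold)
    df = pd.DataFrame(warm.astype(int),
                      index=dates,
                      columns=[str(d) for d in
                               district_temps.coords["district"].values])
    out = df.groupby(df.index.year).sum()
    out.index.name = "year"
    return out


def event_share(window_total: float, annual_total: float) -> float:
    """A window's percentage share of the annual excess total."""
    if annual_total == 0:
        return np.nan
    return 100.0 * window_total / annual_total


def event_summary(excess: xr.DataArray, population_daily: xr.DataArray,
                  window: tuple[str, str]) -> dict:
    """Daily and total report for an event window (e.g. one heatwave).

    Returns the daily national excess inside the window, per-district totals
    and per-million rates, the window total, and the window's share of the
    excess in the calendar year of the window's start.
    """
    t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    dates = pd.DatetimeIndex(excess.coords["time"].values)
    if t0 < dates.min() or t1 > dates.max():
        raise ValueError("event window outside the prediction range")
    win = excess.sel(time=slice(t0, t1))
    daily_national = win.sum(dim=["district", "sex", "age"]).to_series()
    district_totals = win.sum(dim=["time", "sex", "age"]).to_series()

    pop_win = population_daily.sel(time=slice(t0, t1))
    district_pop = pop_win.sum(dim=["sex", "age"]).mean(dim="time").to_series()
    rate = np.where(district_pop.values > 0,
                    district_totals.values / district_pop.values * 1e6, np.nan)
    undefined = (district_pop.values == 0) & (district_totals.values != 0)
    per_million = pd.Series(rate, index=district_totals.index,
                            name="excess_per_million")

    year = t0.year
    annual = float(excess.sel(time=str(year)).sum())
    window_total = float(win.sum())
    return {
        "daily_national": daily_national,
        "district_totals": district_totals,
        "district_per_million": per_million,
        "rate_undefined_districts": list(district_totals.index[undefined]),
        "window_total": window_total,
        "annual_total": annual,
        "share_pct": event_share(window_total, annual),
    }


def concentration_stats(daily_national_excess: pd.Series,
                        top_k: int = 10) -> dict:
    """Share of the top-k excess days and their 'disconnected' fraction.

    Operates on one calendar year of daily national excess.  A top-k day is
    *disconnected* if no other top-k day falls on an adjacent calendar day;
    a low disconnected fraction indicates excess concentrated in consecutive
    runs of hot days, i.e. heatwaves.
    """
    s = daily_national_excess.sort_index()
    years = pd.DatetimeIndex(s.index).year
    if len(set(years)) != 1:
        raise ValueError("one calendar year of daily excess is required")
    total = float(s.sum())
    if total == 0:
        return {"top_k_share_pct": np.nan, "disconnected_fraction": np.nan,
                "top_k_days": [], "undefined": True}
    k = min(top_k, len(s))
    order = np.argsort(-s.values, kind="stable")[:k]
    top_days = pd.DatetimeIndex(s.index[np.sort(order)])
    share = 100.0 * float(s.values[order].sum()) / total
    day = pd.Timedelta(days=1)
    top_set = set(top_days)
    disconnected = sum(1 for d in top_days
                       if (d - day) not in top_set and (d + day) not in top_set)
    return {"top_k_share_pct": share,
            "disconnected_fraction": disconnected / k,
            "top_k_days": list(top_days), "undefined": False}
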