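"""Shared data conventions: age bands, sexes, calendars, stratified arrays.

The package's single currency for mortality-type quantities is a
"stratified series": an :class:`xarray.DataArray` whose dimensions are a
subset of ``("time", "district", "sex", "age")``.  Daily model-resolution
data always carries all four dimensions (time = calendar day, age = 5-year
bands).  Reporting streams — the coarser tables a statistics office would
release — are long-form :class:`pandas.DataFrame` objects produced by
:func:`aggregate_to_stream`.

Age is handled through *bands*: half-open intervals ``[lo, hi)`` with the
last band open-ended.  Model resolution is 5-year bands (``0-5`` … ``90-95``,
``95+``); the reporting streams use coarser groupings that are exact unions
of the 5-year bands, so aggregation is a projection matrix and conservation
holds to the integer.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

SEXES: tuple[str, str] = ("f", "m")

#: 5-year model-resolution band lower edges (last band open: 95+).
FIVE_YEAR_EDGES: tuple[int, ...] = tuple(range(0, 100, 5))
#: Broad age groups used by the weekly state-level stream.
BROAD_EDGES: tuple[int, ...] = (0, 65, 75, 85)
#: Fine age groups used by the weekly national stream: 0-30, then 5-year bands.
FINE_EDGES: tuple[int, ...] = (0, 30) + tuple(range(35, 100, 5))

STREAM_DAILY_STATE_SEX = "daily_state_sex"
STREAM_WEEKLY_STATE_SEX_BROADAGE = "weekly_state_sex_broadage"
STREAM_WEEKLY_NATIONAL_SEX_FINEAGE = "weekly_national_sex_fineage"
STREAMS = (
    STREAM_DAILY_STATE_SEX,
    STREAM_WEEKLY_STATE_SEX_BROADAGE,
    STREAM_WEEKLY_NATIONAL_SEX_FINEAGE,
)


def band_labels(edges: Sequence[int]) -> list[str]:
    """Human-readable labels for half-open age bands, e.g. ``"65-75"``, ``"95+"``."""
    edges = list(edges)
    labels = [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


FIVE_YEAR_LABELS = band_labels(FIVE_YEAR_EDGES)
BROAD_LABELS = band_labels(BROAD_EDGES)
FINE_LABELS = band_labels(FINE_EDGES)


def band_midpoints(edges: Sequence[int], open_width: float = 5.0) -> np.ndarray:
    """Midpoint age of each band; the open top band uses ``open_width``."""
    edges = np.asarray(edges, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return np.append(mids, edges[-1] + open_width / 2.0)


def band_projection(coarse_edges: Sequence[int],
                    fine_edges: Sequence[int] = FIVE_YEAR_EDGES) -> np.ndarray:
    """0/1 matrix ``(n_coarse, n_fine)`` summing fine bands into coarse bands.

    Raises
    ------
    ValueError
        If the coarse bands do not start at 0 or are not exact unions of the
        fine bands (so that the mapping cannot be a projection).
    """
    coarse = list(coarse_edges)
    fine = list(fine_edges)
    if coarse[0] != 0 or fine[0] != 0:
        raise ValueError("age bands must cover [0, open); first edge must be 0")
    for e in coarse:
        if e not in fine:
            raise ValueError(f"coarse band edge {e} is not a fine band edge; "
                             "coarse bands must be unions of fine bands")
    n_c, n_f = len(coarse), len(fine)
    proj = np.zeros((n_c, n_f))
    coarse_hi = coarse[1:] + [np.inf]
    fine_hi = fine[1:] + [np.inf]
    for j, (flo, fhi) in enumerate(zip(fine, fine_hi)):
        for i, (clo, chi) in enumerate(zip(coarse, coarse_hi)):
            if clo <= flo and fhi <= chi:
                proj[i, j] = 1.0
                break
        else:  # pragma: no cover - guarded by edge check above
            raise ValueError(f"fine band [{flo},{fhi}) not contained in any coarse band")
    return proj


# ---------------------------------------------------------------------------
# calendars
# ---------------------------------------------------------------------------

def daily_index(year_start: int, year_end: int) -> pd.DatetimeIndex:
    """Daily calendar covering the inclusive year range."""
    if year_end < year_start:
        raise ValueError("empty date range: year_end < year_start")
    return pd.date_range(f"{year_start}-01-01", f"{year_end}-12-31", freq="D")


def iso_week_monday(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """The Monday starting each date's ISO week."""
    return dates - pd.to_timedelta(dates.weekday, unit="D")


def full_iso_weeks(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Mondays of the ISO weeks fully contained in the (contiguous) date range.

    Partial weeks at the edges are dropped so weekly tables are exact sums of
    the daily records they cover.
    """
    mondays = iso_week_monday(dates).unique().sort_values()
    keep = (mondays >= dates.min()) & (mondays + pd.Timedelta(days=6) <= dates.max())
    return mondays[keep]


def check_contiguous_daily(dates: pd.DatetimeIndex) -> None:
    if len(dates) == 0:
        raise ValueError("empty date range")
    expected = pd.date_range(dates[0], dates[-1], freq="D")
    if len(dates) != len(expected) or not (dates == expected).all():
        raise ValueError("calendar has gaps; a contiguous daily series is required")


# ---------------------------------------------------------------------------
# stratified arrays and reporting streams
# ---------------------------------------------------------------------------

def stratified_daily(values: np.ndarray, dates: pd.DatetimeIndex,
                     districts: Sequence[str]) -> xr.DataArray:
    """Wrap a ``(time, district, sex, age)`` array with labelled coordinates."""
    return xr.DataArray(
        values,
        dims=("time", "district", "sex", "age"),
        coords={"time": dates, "district": list(districts),
                "sex": list(SEXES), "age": FIVE_YEAR_LABELS},
    )


def _to_long(daily: xr.DataArray) -> pd.DataFrame:
    df = daily.to_dataframe(name="deaths").reset_index()
    return df


def aggregate_to_stream(daily: xr.DataArray, stream: str,
                        district_states: pd.Series | dict) -> pd.DataFrame:
    """Aggregate daily district×sex×5-year-age data to a reporting stream.

    Parameters
    ----------
    daily
        Stratified daily DataArray ``(time, district, sex, age)`` with 5-year
        age bands.
    stream
        One of :data:`STREAMS`.
    district_states
        Mapping district id → state id.

    Returns
    -------
    DataFrame with a ``deaths`` column; weekly streams are keyed by the ISO
    week's Monday (``week`` column) and drop partial edge weeks.
    """
    if stream not in STREAMS:
        raise ValueError(f"unknown stream {stream!r}; expected one of {STREAMS}")
    dates = pd.DatetimeIndex(daily.coords["time"].values)
    check_contiguous_daily(dates)
    states = pd.Series(district_states)

    df = _to_long(daily)
    df["state"] = df["district"].map(states)
    if df["state"].isna().any():
        missing = sorted(df.loc[df["state"].isna(), "district"].unique())
        raise ValueError(f"districts without state membership: {missing}")

    if stream == STREAM_DAILY_STATE_SEX:
        out = (df.groupby(["time", "state", "sex"], as_index=False)["deaths"].sum()
                 .rename(columns={"time": "date"}))
        return out.sort_values(["date", "state", "sex"]).reset_index(drop=True)

    week = iso_week_monday(pd.DatetimeIndex(df["time"]))
    df = df.assign(week=week)
    keep_weeks = full_iso_weeks(dates)
    df = df[df["week"].isin(keep_weeks)]

    if stream == STREAM_WEEKLY_STATE_SEX_BROADAGE:
        mapping = _band_map(BROAD_EDGES)
        df = df.assign(age=df["age"].map(mapping))
        out = df.groupby(["week", "state", "sex", "age"], as_index=False)["deaths"].sum()
        return out.sort_values(["week", "state", "sex", "age"]).reset_index(drop=True)

    mapping = _band_map(FINE_EDGES)
    df = df.assign(age=df["age"].map(mapping))
    out = df.groupby(["week", "sex", "age"], as_index=False)["deaths"].sum()
    return out.sort_values(["week", "sex", "age"]).reset_index(drop=True)


def _band_map(coarse_edges: Sequence[int]) -> dict[str, str]:
    """Map each 5-year band label to its coarse band label."""
    proj = band_projection(coarse_edges)
    coarse_labels = band_labels(coarse_edges)
    return {FIVE_YEAR_LABELS[j]: coarse_labels[int(np.argmax(proj[:, j]))]
            for j in range(proj.shape[1])}
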