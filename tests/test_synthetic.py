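"""Generator tests: determinism, structure recovery, conservation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import heatmort as hm
from heatmort.containers import (FIVE_YEAR_LABELS, SEXES, STREAMS,
                                 aggregate_to_stream, stratified_daily)


def test_region_determinism(small_cfg, small_region):
    again = hm.generate_region(small_cfg)
    pd.testing.assert_frame_equal(again.districts, small_region.districts)
    assert (again.population_snapshots.values
            == small_region.population_snapshots.values).all()


def test_temperature_and_deaths_determinism(small_cfg, small_region,
                                            small_fields, small_truth):
    fields2 = hm.generate_temperature_fields(small_region)
    assert (fields2.district_temps.values
            == small_fields.district_temps.values).all()
    assert (fields2.station_temps.values
            == small_fields.station_temps.values).all()
    truth2 = hm.generate_mortality_counts(small_region, fields2.district_temps)
    assert (truth2.realized_deaths.values
            == small_truth.realized_deaths.values).all()


def test_degenerate_single_district():
    cfg = hm.RegionConfig(n_states=1, n_districts=1, n_stations=2,
                          years=(2019, 2019), seed=1)
    region = hm.generate_region(cfg)
    assert len(region.districts) == 1
    assert region.districts["state"].iloc[0] == "S00"
    national = region.population_snapshots.sum(["district"])
    only = region.population_snapshots.isel(district=0)
    assert np.allclose(national.values, only.values)


def test_invalid_region_configs():
    with pytest.raises(ValueError):
        hm.RegionConfig(n_states=5, n_districts=3)
    with pytest.raises(ValueError):
        hm.RegionConfig(heat_island_amplitude=-1.0)
    with pytest.raises(ValueError):
        hm.RegionConfig(bbox=(8.0, 50.0, 8.0, 52.0))
    with pytest.raises(ValueError):
        hm.RegionConfig(years=(2020, 2015))


def test_old_age_share_recovered():
    cfg = hm.RegionConfig(n_districts=20, n_states=4, old_age_share=0.25,
                          years=(2019, 2019), seed=3)
    region = hm.generate_region(cfg)
    snap = region.population_snapshots.isel(year=-1)
    labels = list(snap.coords["age"].values)
    old = [a for a in labels if int(a.split("-")[0].rstrip("+")) >= 75]
    share = float(snap.sel(age=old).sum() / snap.sum())
    assert abs(share - 0.25) < 0.02


def test_ar1_autocorrelation_recovered():
    base = dict(n_states=2, n_districts=4, n_stations=4, years=(2011, 2020),
                seed=9, ar_phi=0.7, ar_sigma=2.0)
    cfg = hm.RegionConfig(**base)
    cfg0 = hm.RegionConfig(**{**base, "ar_sigma": 0.0})
    region = hm.generate_region(cfg)
    with_ar = hm.generate_temperature_fields(region, cfg).district_temps.values
    no_ar = hm.generate_temperature_fields(region, cfg0).district_temps.values
    anomaly = (with_ar - no_ar)[:, 0]  # shared across districts
    r1 = np.corrcoef(anomaly[:-1], anomaly[1:])[0, 1]
    assert abs(r1 - 0.7) < 0.05


def test_heat_island_independent_when_amplitude_zero():
    base = dict(n_states=2, n_districts=6, n_stations=4, years=(2019, 2019),
                seed=5, heat_island_amplitude=0.0)
    t_a = hm.generate_temperature_fields(
        hm.generate_region(hm.RegionConfig(**base, urban_fraction=0.5)))
    t_b = hm.generate_temperature_fields(
        hm.generate_region(hm.RegionConfig(**base, urban_fraction=0.0)))
    assert np.allclose(t_a.district_temps.values, t_b.district_temps.values)


def test_heat_island_offset_constant():
    base = dict(n_states=2, n_districts=6, n_stations=4, years=(2019, 2019),
                seed=5, urban_fraction=0.5)
    r = hm.generate_region(hm.RegionConfig(**base, heat_island_amplitude=0.0))
    r2 = hm.generate_region(hm.RegionConfig(**base, heat_island_amplitude=4.0))
    cold = hm.generate_temperature_fields(r).district_temps.values
    hot = hm.generate_temperature_fields(r2).district_temps.values
    diff = hot - cold
    # per-district constant offset, zero for rural districts
    assert np.allclose(diff.std(axis=0), 0.0, atol=1e-12)
    urban = r2.districts["urban"].values
    assert (diff[0][urban] > 0).all()
    assert np.allclose(diff[0][~urban], 0.0)


def test_pure_sinusoid_symmetry_around_peak():
    cfg = hm.RegionConfig(n_states=1, n_districts=2, n_stations=2,
                          years=(2018, 2018), seed=2, ar_phi=0.0, ar_sigma=0.0,
                          station_noise_sd=0.0, heat_island_amplitude=0.0)
    region = hm.generate_region(cfg)
    temps = hm.generate_temperature_fields(region).district_temps
    series = temps.isel(district=0).values
    peak = cfg.peak_doy - 1  # 0-based index into a non-leap year
    for k in (5, 30, 60):
        assert series[peak - k] == pytest.approx(series[peak + k], abs=1e-6)


def test_zero_slope_gives_baseline_times_population(small_region, small_fields,
                                                    small_population_daily):
    truth_model = hm.TrueRiskModel(slope=0.0)
    out = hm.generate_mortality_counts(small_region,
                                       small_fields.district_temps, truth_model)
    dates = pd.DatetimeIndex(small_fields.district_temps.coords["time"].values)
    rates = out.baseline.daily_rates(dates)
    dow = truth_model.dow_factors[dates.weekday.values]
    manual = (rates[:, None, :, :] * small_population_daily.values
              * dow[:, None, None, None])
    assert np.allclose(out.expected_deaths.values, manual, rtol=1e-12)
    assert float(np.abs(out.true_excess.values).max()) == 0.0


def test_zero_population_district_has_zero_deaths(small_cfg, small_fields):
    region = hm.generate_region(small_cfg)
    snaps = region.population_snapshots.copy()
    snaps[:, 0] = 0.0
    region.population_snapshots = snaps
    out = hm.generate_mortality_counts(region, small_fields.district_temps)
    assert float(out.expected_deaths.isel(district=0).sum()) == 0.0
    assert int(out.realized_deaths.isel(district=0).sum()) == 0


def test_realized_total_within_four_sd(small_truth):
    total_expected = float(small_truth.expected_deaths.sum())
    total_realized = float(small_truth.realized_deaths.sum())
    sd = np.sqrt(total_expected)
    assert abs(total_realized - total_expected) < 4 * sd


def test_realized_convergence_rate_in_size():
    rel_err = {}
    for tag, mean_pop in (("small", 2e4), ("large", 2e6)):
        cfg = hm.RegionConfig(n_states=2, n_districts=6, n_stations=4,
                              years=(2019, 2019), seed=13,
                              district_pop_mean=mean_pop)
        region = hm.generate_region(cfg)
        fields = hm.generate_temperature_fields(region)
        t = hm.generate_mortality_counts(region, fields.district_temps)
        e, r = float(t.expected_deaths.sum()), float(t.realized_deaths.sum())
        rel_err[tag] = abs(r - e) / e
    # 100x more population -> ~10x smaller relative Poisson error
    assert rel_err["large"] < rel_err["small"]


def test_true_excess_nonnegative_and_zero_below_cap(small_truth):
    assert float(small_truth.true_excess.values.min()) >= 0.0
    temps = small_truth.district_temps.values
    lagged_cool = np.ones_like(temps, dtype=bool)
    lw = small_truth.risk_model.lag_weights
    for k in range(len(lw)):
        idx = np.maximum(np.arange(temps.shape[0]) - k, 0)
        lagged_cool &= temps[idx] <= small_truth.cap_c
    excess_by_cell = small_truth.true_excess.sum(dim=["sex", "age"]).values
    assert np.allclose(excess_by_cell[lagged_cool], 0.0)


# -- reporting streams ------------------------------------------------------

def test_stream_conservation_exact(small_truth, small_states, small_streams):
    daily = small_truth.realized_deaths
    total_all = int(daily.sum())
    s1 = small_streams["daily_state_sex"]
    assert int(s1["deaths"].sum()) == total_all
    # weekly streams cover exactly the full ISO weeks
    weeks = sorted(small_streams["weekly_state_sex_broadage"]["week"].unique())
    dates = pd.DatetimeIndex(daily.coords["time"].values)
    covered = dates[(dates >= weeks[0]) & (dates <= pd.Timestamp(weeks[-1])
                                           + pd.Timedelta(days=6))]
    total_weeks = int(daily.sel(time=covered).sum())
    assert int(small_streams["weekly_state_sex_broadage"]["deaths"].sum()) \
        == total_weeks
    assert int(small_streams["weekly_national_sex_fineage"]["deaths"].sum()) \
        == total_weeks


def test_stream_cell_matches_bruteforce(small_truth, small_states,
                                        small_streams):
    df = small_streams["weekly_state_sex_broadage"]
    row = df.iloc[len(df) // 2]
    daily = small_truth.realized_deaths
    days = pd.date_range(row["week"], periods=7)
    members = [d for d, s in small_states.items() if s == row["state"]]
    ages = {"0-65": range(0, 13), "65-75": range(13, 15),
            "75-85": range(15, 17), "85+": range(17, 20)}[row["age"]]
    manual = int(daily.sel(time=days, district=members,
                           sex=row["sex"]).isel(age=list(ages)).sum())
    assert int(row["deaths"]) == manual


def test_single_stratum_stream_equals_daily_series():
    dates = pd.date_range("2019-01-07", periods=21)  # Monday-aligned
    vals = np.zeros((21, 1, 2, 20))
    vals[:, 0, 0, 10] = np.arange(21)
    daily = stratified_daily(vals, dates, ["D0"])
    s1 = aggregate_to_stream(daily, "daily_state_sex", {"D0": "S0"})
    got = s1[s1["sex"] == "f"].sort_values("date")["deaths"].values
    assert np.allclose(got, np.arange(21))


def test_broad_band_arithmetic():
    dates = pd.date_range("2019-01-07", periods=7)
    vals = np.zeros((7, 1, 2, 20))
    vals[:, 0, 0, 13] = 2.0   # ages 65-70
    vals[:, 0, 0, 14] = 3.0   # ages 70-75
    daily = stratified_daily(vals, dates, ["D0"])
    s2 = aggregate_to_stream(daily, "weekly_state_sex_broadage", {"D0": "S0"})
    by_age = s2[s2["sex"] == "f"].set_index("age")["deaths"]
    assert by_age["65-75"] == 35.0
    assert by_age.drop("65-75").sum() == 0.0


def test_partial_edge_weeks_dropped():
    dates = pd.date_range("2019-01-02", "2019-01-27")  # Wed .. Sun
    vals = np.ones((len(dates), 1, 2, 20))
    daily = stratified_daily(vals, dates, ["D0"])
    s = aggregate_to_stream(daily, "weekly_national_sex_fineage", {"D0": "S0"})
    weeks = sorted(pd.DatetimeIndex(s["week"].unique()))
    assert weeks == [pd.Timestamp("2019-01-07"), pd.Timestamp("2019-01-14"),
                     pd.Timestamp("2019-01-21")]


def test_dow_factors_validation():
    with pytest.raises(ValueError):
        hm.TrueRiskModel(dow_factors=np.array([1.1] * 7))
    with pytest.raises(ValueError):
        hm.TrueRiskModel(lag_weights=np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        hm.TrueRiskModel(exponent=0.5)
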