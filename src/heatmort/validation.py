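"""End-to-end self-validation studies against synthetic ground truth.

These functions run the full pipeline on data from :mod:`heatmort.synthetic`
— where the exposure-response, day-of-week factors and excess deaths are
known exactly — and report how well each stage recovers the truth.  They are
used by the test-suite and the reproduction script, and are available to
users who want to gauge estimator behaviour at other study sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attribution import excess_mortality
from .containers import BROAD_EDGES, band_projection
from .exposure import MortalityEnsemble, TrainingData, interpolate_population_daily
from .interpolation import AttentionInterpolator
from .synthetic import (RegionConfig, TrueRiskModel, build_reporting_tables,
                        generate_mortality_counts, generate_region,
                        generate_temperature_fields)

__all__ = ["exposure_recovery_study", "interpolator_recovery_study"]


def exposure_recovery_study(seed: int = 11, n_instances: int = 5,
                            region_config: RegionConfig | None = None,
                            model_seed: int | None = None) -> dict:
    """Fit a mortality ensemble on synthetic data with known risk truth.

    Generates the default study region (20 districts, 6 calendar years),
    trains an ensemble on the three reporting streams (first four years
    training, last two validation), and compares the estimated heat excess,
    the relative-risk profile and the day-of-week factors against the
    generator's ground truth.

    Returns a dict with, among others, ``excess_ratio`` (estimated / true
    total excess), ``profile_max_rel_err`` (worst relative error of the
    death-weighted f(T)/f(20) profile on 20..30 deg C), and
    ``dow_max_abs_err``.
    """
    cfg = region_config or RegionConfig(seed=seed)
    region = generate_region(cfg)
    fields = generate_temperature_fields(region)
    truth_model = TrueRiskModel()
    truth = generate_mortality_counts(region, fields.district_temps, truth_model)
    states = region.districts.set_index("district")["state"]
    streams = build_reporting_tables(truth, states)
    dates = pd.DatetimeIndex(fields.district_temps.coords["time"].values)
    pop = interpolate_population_daily(region.population_snapshots, dates)
    data = TrainingData(district_temps=fields.district_temps,
                        district_states=states, population_daily=pop,
                        streams=streams)

    y0, y1 = cfg.years
    n_train = max(int(round(0.8 * (y1 - y0 + 1))), 1)
    ens = MortalityEnsemble(
        n_instances=n_instances,
        random_state=seed if model_seed is None else model_seed,
        train_years=(y0, y0 + n_train - 1), validation_years=(y0 + n_train, y1))
    ens.fit(data)

    est = excess_mortality(ens, fields.district_temps, pop)
    true_total = float(truth.true_excess.sum())
    est_total = float(est.sum())

    proj = band_projection(BROAD_EDGES)
    weights = np.einsum("tisa,ga->sg", truth.true_excess.values, proj)
    weights = weights / weights.sum()
    temps_c = np.arange(20.0, 30.5, 1.0)
    lag = np.repeat(temps_c[:, None], ens.instances_[0].lag_days + 1, axis=1)
    f_hat = np.mean([inst.response_factors(lag) for inst in ens.instances_],
                    axis=0)
    profile = np.einsum("nsg,sg->n", f_hat / f_hat[0:1], weights)
    f_true = 1.0 + truth_model.slope * np.maximum(
        temps_c - truth_model.threshold, 0.0) ** truth_model.exponent
    true_profile = f_true / f_true[0]
    profile_err = np.abs(profile / true_profile - 1.0)

    dow_hat = np.mean([inst.dow_factors_ for inst in ens.instances_], axis=0)

    return {
        "ensemble": ens, "data": data, "truth": truth, "fields": fields,
        "population_daily": pop,
        "est_total_excess": est_total, "true_total_excess": true_total,
        "excess_ratio": est_total / true_total,
        "temps_c": temps_c, "profile": profile, "true_profile": true_profile,
        "profile_max_rel_err": float(profile_err.max()),
        "dow_max_abs_err": float(np.abs(dow_hat
                                        - truth_model.dow_factors).max()),
        "n_observations": int(sum(len(s) for s in streams.values())),
    }


def interpolator_recovery_study(seed: int = 0, n_sources: int = 12,
                                n_districts: int = 10,
                                n_days: int = 400) -> dict:
    """Fit the attention interpolator on data from known parameters.

    District series are generated exactly by a known parameter set applied
    to noise-free source series; the fitted model is scored on held-out
    days (the final 20% of the record).
    """
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.uniform(6, 14, n_sources),
                         rng.uniform(47, 54, n_sources)])
    coords = np.column_stack([rng.uniform(7, 13, n_districts),
                              rng.uniform(48, 53, n_districts)])
    truth = AttentionInterpolator(source_coords=Y)
    truth.coords_ = coords
    truth.bias_ = rng.normal(0, 1, n_districts)
    truth.alpha_ = rng.uniform(0.3, 2.0, n_districts)
    truth.weights_ = truth._weights(coords, truth.alpha_)
    truth.n_sources_ = n_sources

    X = 10 + 8 * np.sin(np.arange(n_days) / 30)[:, None] \
        + rng.normal(0, 3, (n_days, n_sources))
    ref = truth.predict(X)

    fit = AttentionInterpolator(source_coords=Y, district_coords_init=coords)
    fit.fit(X, ref)
    n_train = int(round(0.8 * n_days))
    held = float(np.sqrt(np.mean(
        (fit.predict(X[n_train:]) - ref[n_train:]) ** 2)))
    return {"model": fit, "heldout_rmse_c": held,
            "train_rmse_c": fit.train_rmse_, "n_heldout_days": n_days - n_train}
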