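"""Exposure model pieces: population, lags, response, loss, metrics."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from heatmort._optim import softplus_inv
from heatmort.containers import FIVE_YEAR_LABELS, SEXES, STREAMS, aggregate_to_stream
from heatmort.exposure import (ExposureResponseModel, MortalityEnsemble,
                               TrainingData, _Design, build_lag_matrix,
                               evaluate_metrics, expected_deaths,
                               interpolate_population_daily, poisson_nll,
                               poisson_nll_grad, response_factor)


def _snapshots(values, years):
    values = np.asarray(values, dtype=float)
    return xr.DataArray(
        values.reshape(len(years), 1, 1, 1)
        * np.ones((len(years), 1, 2, 20)) / 40.0,
        dims=("year", "district", "sex", "age"),
        coords={"year": years, "district": ["D0"], "sex": list(SEXES),
                "age": FIVE_YEAR_LABELS})


class TestPopulationInterpolation:
    def test_equal_snapshots_constant(self):
        snaps = _snapshots([1000, 1000], [2018, 2019])
        daily = interpolate_population_daily(
            snaps, pd.date_range("2019-01-01", "2019-12-31"))
        assert np.allclose(daily.sum(["district", "sex", "age"]).values, 1000.0)

    def test_linear_midpoint(self):
        snaps = _snapshots([1000, 2000], [2018, 2019])
        mid = pd.Timestamp("2018-12-31") + (pd.Timestamp("2019-12-31")
                                            - pd.Timestamp("2018-12-31")) / 2
        daily = interpolate_population_daily(snaps, pd.DatetimeIndex([mid]))
        total = float(daily.sum())
        assert abs(total - 1500.0) < 1500.0 / 365 + 1e-9

    def test_monotone_across_leap_years(self):
        snaps = _snapshots([1000, 1400, 2000], [2019, 2020, 2021])
        dates = pd.date_range("2019-12-31", "2021-12-31")
        total = interpolate_population_daily(snaps, dates) \
            .sum(["district", "sex", "age"]).values
        assert (np.diff(total) >= -1e-9).all()

    def test_constant_extrapolation(self):
        snaps = _snapshots([1000, 2000], [2018, 2019])
        daily = interpolate_population_daily(
            snaps, pd.DatetimeIndex(["2017-06-01", "2021-06-01"]))
        totals = daily.sum(["district", "sex", "age"]).values
        assert np.allclose(totals, [1000.0, 2000.0])


class TestLagMatrix:
    def test_zero_lag_is_identity(self):
        out = build_lag_matrix(np.array([3.0, 4.0, 5.0]), 0)
        assert np.allclose(out[:, 0], [3, 4, 5])

    def test_spec_example(self):
        out = build_lag_matrix(np.array([10.0, 20.0, 30.0]), 1)
        assert np.allclose(out, [[10, 10], [20, 10], [30, 20]])

    @pytest.mark.parametrize("lag", [1, 3, 6])
    def test_bruteforce_indexing(self, lag):
        rng = np.random.default_rng(lag)
        series = rng.normal(size=40)
        out = build_lag_matrix(series, lag)
        for t in range(40):
            for k in range(lag + 1):
                assert out[t, k] == series[max(t - k, 0)]

    def test_two_dim_series(self):
        series = np.arange(12.0).reshape(6, 2)
        out = build_lag_matrix(series, 2)
        assert out.shape == (6, 2, 3)
        assert out[3, 1, 2] == series[1, 1]

    def test_calendar_gap_rejected(self):
        dates = pd.DatetimeIndex(["2020-01-01", "2020-01-02", "2020-01-04"])
        with pytest.raises(ValueError):
            build_lag_matrix(np.zeros(3), 1, dates=dates)


class TestResponseFactor:
    def test_identity_unit_gives_one(self):
        p = {"W": np.zeros((1, 4)), "b": np.zeros(1),
             "rs": np.asarray([softplus_inv(1.0)]),
             "rc": np.array([-40.0])}  # softplus(-40) ~ 4e-18
        f = response_factor("exponential", p, np.full((5, 4), 13.0))
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_constant_in_temperature(self):
        ck = np.array([0.3, -0.5])
        sk = np.array([0.7, 1.2])
        p = {"W": np.zeros((2, 4)), "b": ck,
             "rs": np.asarray(softplus_inv(sk)),
             "rc": np.asarray([softplus_inv(0.25)])}
        expect = 0.25 + (sk * np.exp(ck)).sum()
        for T in (0.0, 15.0, 35.0):
            f = response_factor("exponential", p, np.full((3, 4), T))
            assert np.allclose(f, expect, rtol=1e-12)

    def test_hand_evaluated_exponent(self):
        # g1(T) = 0.1*(mean(T) - 20); at T=30 everywhere f = e^1
        # (inner weights are in standardized units, (T-20)/10)
        L1 = 8
        p = {"W": np.full((1, L1), 1.0 / L1), "b": np.zeros(1),
             "rs": np.asarray([softplus_inv(1.0)]), "rc": np.array([-40.0])}
        f = response_factor("exponential", p, np.full((1, L1), 30.0))
        assert f[0] == pytest.approx(np.e, rel=1e-9)

    def test_dimension_mismatch(self):
        p = {"W": np.zeros((1, 4)), "b": np.zeros(1),
             "rs": np.zeros(1), "rc": np.zeros(1)}
        with pytest.raises(ValueError):
            response_factor("exponential", p, np.zeros((3, 6)))

    def test_linear_variant_positive(self):
        rng = np.random.default_rng(0)
        from heatmort.exposure import _LinearNet
        p = _LinearNet.init(rng, 7, 8)
        f = response_factor("linear", p, rng.normal(15, 10, (50, 8)))
        assert (f > 0).all()


class TestExpectedDeaths:
    def test_product_formula(self):
        T, I = 3, 2
        baseline = np.full((T, 2, 20), 1e-5)
        pop = np.full((T, I, 2, 20), 1e6 / 40)
        f = np.full((T, I, 2, 20), 1.2)
        out = expected_deaths(baseline, pop, f, np.ones(T))
        assert out.sum(axis=(1, 2, 3))[0] == pytest.approx(2 * 12.0)

    def test_zero_population(self):
        out = expected_deaths(np.full((2, 2, 20), 1e-5),
                              np.zeros((2, 1, 2, 20)),
                              np.ones((2, 1, 2, 20)), np.ones(2))
        assert out.sum() == 0.0

    def test_misaligned_strata_error(self):
        with pytest.raises(ValueError):
            expected_deaths(np.ones((2, 2, 20)), np.ones((3, 1, 2, 20)),
                            np.ones((3, 1, 2, 20)), np.ones(3))


class TestPoissonLoss:
    def test_closed_form_cells(self):
        assert poisson_nll(np.array([1.0]), np.array([1.0])) == pytest.approx(1.0)
        assert poisson_nll(np.array([2.0]), np.array([0.0])) == pytest.approx(2.0)

    def test_minimized_at_lambda_equals_y(self):
        y = np.array([3.0])
        lams = np.linspace(0.5, 8, 200)
        losses = [poisson_nll(np.array([l]), y) for l in lams]
        assert lams[int(np.argmin(losses))] == pytest.approx(3.0, abs=0.05)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.5, 30, 50)
        y = rng.poisson(lam).astype(float)
        g = poisson_nll_grad(lam, y)
        h = 1e-6 * lam
        fd = np.array([
            (poisson_nll(np.array([l + e]), np.array([yy]))
             - poisson_nll(np.array([l - e]), np.array([yy]))) / (2 * e)
            for l, e, yy in zip(lam, h, y)])
        rel = np.abs(fd - g) / np.maximum(np.abs(fd), 1.0)
        assert rel.max() < 1e-6

    def test_negative_observed_rejected(self):
        with pytest.raises(ValueError):
            poisson_nll(np.array([1.0]), np.array([-1.0]))


class TestModelGradients:
    @pytest.mark.parametrize("variant", ["exponential", "linear"])
    def test_analytic_gradients_match_fd(self, variant, small_training_data):
        m = ExposureResponseModel(variant=variant, lag_days=3, hidden_dim=3,
                                  train_years=(2018, 2018),
                                  validation_years=(2019, 2019),
                                  random_state=7)
        design = _Design(small_training_data, m.lag_days)
        params = m._init_params(design)
        mt, mw = design.year_masks([2018])
        nll, grads = m._forward(params, design, True, mt, mw)
        rng = np.random.default_rng(0)
        for key in params:
            arr = params[key]
            idxs = list(np.ndindex(arr.shape))
            for i in rng.choice(len(idxs), size=min(3, len(idxs)),
                                replace=False):
                ix = idxs[i]
                h = 1e-6 * max(1.0, abs(arr[ix]))
                old = arr[ix]
                arr[ix] = old + h
                f1 = m._forward(params, design, False, mt, mw)
                arr[ix] = old - h
                f0 = m._forward(params, design, False, mt, mw)
                arr[ix] = old
                fd = (f1 - f0) / (2 * h)
                an = grads[key][ix]
                assert abs(fd - an) / max(1.0, abs(fd), abs(an)) < 1e-4, key


class TestAggregationConsistency:
    def test_model_stream_rates_match_pandas_aggregation(
            self, small_training_data, small_truth, small_states):
        """The training design's dense stream arrays must agree with the
        public pandas aggregation on the same daily data."""
        design = _Design(small_training_data, 2)
        daily = small_truth.realized_deaths
        s1 = aggregate_to_stream(daily, STREAMS[0], small_states)
        assert float(design.y1.sum()) == pytest.approx(float(s1["deaths"].sum()))
        s2 = aggregate_to_stream(daily, STREAMS[1], small_states)
        assert float(design.y2.sum()) == pytest.approx(float(s2["deaths"].sum()))
        piv = s2.pivot_table(index="week", columns=["state", "sex", "age"],
                             values="deaths")
        assert float(design.y2[0].sum()) == pytest.approx(float(piv.iloc[0].sum()))


class TestDayOfWeekFactors:
    def test_mean_exactly_one(self):
        m = ExposureResponseModel()
        m.params_ = {"rho": np.random.default_rng(0).normal(0, 0.5, 7)}
        assert m.dow_factors_.mean() == pytest.approx(1.0, abs=1e-14)
        assert (m.dow_factors_ > 0).all()


class TestEnsembleMechanics:
    def test_seed_shortage_rejected(self, small_training_data):
        ens = MortalityEnsemble(n_instances=3, seeds=[1, 2])
        with pytest.raises(ValueError):
            ens.fit(small_training_data)

    def test_single_instance_ensemble_equals_instance(self, small_training_data):
        kw = dict(train_years=(2018, 2018), validation_years=(2019, 2019),
                  n_rounds=1, base_iters=5, net_iters=5)
        ens = MortalityEnsemble(n_instances=1, seeds=[11], **kw)
        ens.fit(small_training_data)
        solo = ExposureResponseModel(random_state=11, **kw)
        solo.fit(small_training_data)
        E_ens = ens.predict_expected(small_training_data.district_temps,
                                     small_training_data.population_daily)
        E_solo = solo.predict_expected(small_training_data.district_temps,
                                       small_training_data.population_daily)
        assert np.allclose(E_ens.values, E_solo.values, rtol=1e-12)

    def test_identical_seeds_zero_spread(self, small_training_data):
        kw = dict(train_years=(2018, 2018), validation_years=(2019, 2019),
                  n_rounds=1, base_iters=5, net_iters=5)
        ens = MortalityEnsemble(n_instances=2, seeds=[11, 11], **kw)
        ens.fit(small_training_data)
        E0 = ens.instances_[0].predict_expected(
            small_training_data.district_temps,
            small_training_data.population_daily)
        E1 = ens.instances_[1].predict_expected(
            small_training_data.district_temps,
            small_training_data.population_daily)
        assert np.allclose(E0.values, E1.values)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.arange(1.0, 50.0)
        out = evaluate_metrics(y, y)
        assert out["rmse_all"] == 0.0
        assert out["r2_all"] == pytest.approx(1.0)

    def test_poisson_bound_sqrt_lambda(self):
        lam = np.full(1000, 100.0)
        out = evaluate_metrics(lam, lam)
        assert out["poisson_rmse_bound_all"] == pytest.approx(10.0)

    def test_warm_subset(self):
        lam = np.array([10.0, 10.0, 10.0])
        y = np.array([10.0, 12.0, 8.0])
        temps = np.array([15.0, 25.0, 26.0])
        out = evaluate_metrics(lam, y, temps, warm_threshold=20.0)
        assert out["rmse_warm"] == pytest.approx(2.0)

    def test_empty_warm_subset_is_nan(self):
        out = evaluate_metrics(np.array([5.0]), np.array([5.0]),
                               np.array([10.0]))
        assert np.isnan(out["rmse_warm"])
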