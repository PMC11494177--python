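import numpy as np
import pandas as pd
import pytest

import heatmort as hm
from heatmort.exposure import TrainingData, interpolate_population_daily


@pytest.fixture(scope="session")
def small_cfg():
    return hm.RegionConfig(n_states=3, n_districts=8, n_stations=10,
                           years=(2018, 2019), seed=7)


@pytest.fixture(scope="session")
def small_region(small_cfg):
    return hm.generate_region(small_cfg)


@pytest.fixture(scope="session")
def small_fields(small_region):
    return hm.generate_temperature_fields(small_region)


@pytest.fixture(scope="session")
def small_truth(small_region, small_fields):
    return hm.generate_mortality_counts(small_region, small_fields.district_temps)


@pytest.fixture(scope="session")
def small_states(small_region):
    return small_region.districts.set_index("district")["state"]


@pytest.fixture(scope="session")
def small_streams(small_truth, small_states):
    return hm.build_reporting_tables(small_truth, small_states)


@pytest.fixture(scope="session")
def small_population_daily(small_region, small_fields):
    dates = pd.DatetimeIndex(small_fields.district_temps.coords["time"].values)
    return interpolate_population_daily(small_region.population_snapshots, dates)


@pytest.fixture(scope="session")
def small_training_data(small_fields, small_states, small_population_daily,
                        small_streams):
    return TrainingData(district_temps=small_fields.district_temps,
                        district_states=small_states,
                        population_daily=small_population_daily,
                        streams=small_streams)


def make_monotone_instance(lag_days=3, seed=0, tau_origin="2018-01-01"):
    """A hand-built exposure model with a monotone-increasing response.

    Exponential-variant parameters with non-negative inner weights, so the
    response factor is non-decreasing in every lag coordinate; useful for
    attribution sign and counterfactual tests without a training run.
    """
    from heatmort._optim import softplus_inv
    from heatmort.exposure import _GROUPS, ExposureResponseModel

    rng = np.random.default_rng(seed)
    m = ExposureResponseModel(lag_days=lag_days, hidden_dim=2)
    params = {
        "beta0": np.log(np.full((2, 20), 2e-5)),
        "beta1": np.zeros((2, 20)),
        "rho": rng.normal(0.0, 0.02, 7),
    }
    for k in range(len(_GROUPS)):
        params[f"net{k}_W"] = rng.uniform(0.5, 2.0, (2, lag_days + 1))
        params[f"net{k}_b"] = rng.normal(-2.0, 0.2, 2)
        params[f"net{k}_rs"] = np.asarray(softplus_inv(np.full(2, 0.5)))
        params[f"net{k}_rc"] = np.array([float(softplus_inv(0.5))])
    m.params_ = params
    m.tau_origin_ = pd.Timestamp(tau_origin)
    m.tau_center_days_ = 365.0
    return m
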