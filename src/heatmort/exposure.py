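"""Temperature–mortality exposure model trained against aggregated streams.

The model predicts daily expected deaths per district and stratum as

    E(t, district, sex, age) = baseline(t, sex, age)
                               x population(t, district, sex, age)
                               x f_{sex, broad-age}(T_lag(t, district))
                               x dow(weekday(t))

where ``f`` is a trainable exposure-response function of the recent
temperature history (a lag vector of the current and the ``l`` preceding
daily mean temperatures), ``baseline`` is a spatially uniform, log-linear-in-
time death rate per stratum, and ``dow`` is a mean-one day-of-week reporting
correction.  Expected deaths are aggregated to the resolution of each
mortality reporting stream and scored against the observed counts with a
Poisson likelihood; all parameters are trained jointly by full-batch L-BFGS
on exact hand-derived gradients, keeping the iterate with the best
validation likelihood (an early-stopping analogue).  Network inputs are
standardized as (T - 20)/10 internally so the optimization is well
conditioned; this is a fixed affine change of variables, not a fitted one.

Two response-function families are available:

* ``exponential`` — a non-negative affine mixture of exponentials of affine
  maps of the lag vector, ``f(T) = c + sum_k s_k exp(w_k . T + b_k)`` with
  ``s_k, c >= 0`` enforced structurally through a softplus reparameterization.
* ``linear`` — a one-dimensional convolution (kernel size ``l``) over the lag
  vector followed by a small fully connected rectifier network, with a final
  softplus guaranteeing a positive multiplying factor.

Because a rescaling (baseline x c, f x 1/c) leaves the likelihood unchanged,
absolute levels of baseline and f are not separately identified; every
downstream quantity (expected deaths, heat-attributed excess) is invariant
to this rescaling, which the test-suite asserts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator

from ._optim import sigmoid, softplus, softplus_inv
from .containers import (
    BROAD_EDGES,
    BROAD_LABELS,
    FINE_EDGES,
    FIVE_YEAR_EDGES,
    FIVE_YEAR_LABELS,
    SEXES,
    STREAM_DAILY_STATE_SEX,
    STREAM_WEEKLY_NATIONAL_SEX_FINEAGE,
    STREAM_WEEKLY_STATE_SEX_BROADAGE,
    band_projection,
    check_contiguous_daily,
    full_iso_weeks,
    iso_week_monday,
)

__all__ = [
    "interpolate_population_daily",
    "build_lag_matrix",
    "response_factor",
    "expected_deaths",
    "poisson_nll",
    "poisson_nll_grad",
    "TrainingData",
    "ExposureResponseModel",
    "MortalityEnsemble",
    "evaluate_metrics",
]

_EPS_RATE = 1e-8
_Z_CLIP = 30.0  # overflow guard on exponent arguments


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def interpolate_population_daily(snapshots: xr.DataArray,
                                 dates: pd.DatetimeIndex) -> xr.DataArray:
    """Linearly interpolate annual Dec-31 population snapshots to daily values.

    Outside the snapshot span the nearest snapshot is held constant
    (constant extrapolation).

    Parameters
    ----------
    snapshots
        DataArray with dims ``(year, district, sex, age)``; each year's value
        is the population on December 31 of that year.
    dates
        Daily calendar to evaluate on.
    """
    years = np.asarray(snapshots.coords["year"].values, dtype=int)
    if years.size < 1:
        raise ValueError("at least one population snapshot is required")
    order = np.argsort(years)
    years = years[order]
    vals = snapshots.values[order]  # (K, I, S, A)
    snap_times = pd.to_datetime([f"{y}-12-31" for y in years]).asi8.astype(float)
    t = dates.asi8.astype(float)
    if t.min() < snap_times[0] or t.max() > snap_times[-1]:
        import warnings
        warnings.warn("dates outside the snapshot span; holding the nearest "
                      "snapshot constant", stacklevel=2)
    if years.size == 1:
        daily = np.broadcast_to(vals[0], (len(dates),) + vals.shape[1:]).copy()
    else:
        flat = vals.reshape(len(years), -1)
        out = np.empty((len(t), flat.shape[1]))
        for j in range(flat.shape[1]):
            out[:, j] = np.interp(t, snap_times, flat[:, j])
        daily = out.reshape((len(t),) + vals.shape[1:])
    return xr.DataArray(
        daily, dims=("time",) + snapshots.dims[1:],
        coords={"time": dates, **{d: snapshots.coords[d] for d in snapshots.dims[1:]}},
    )


# ---------------------------------------------------------------------------
# lag matrix
# ---------------------------------------------------------------------------

def build_lag_matrix(values: np.ndarray, lag_days: int,
                     dates: pd.DatetimeIndex | None = None) -> np.ndarray:
    """Lag vectors [T_0, T_1, ..., T_l] per day (same-day first).

    ``values`` is ``(T,)`` or ``(T, n_series)``; the result appends a trailing
    axis of length ``lag_days + 1`` where entry ``k`` is the temperature ``k``
    days before (replicate-first-day padding at the start of the series).
    """
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    if dates is not None:
        check_contiguous_daily(pd.DatetimeIndex(dates))
    v = np.asarray(values, dtype=float)
    T = v.shape[0]
    out = np.empty(v.shape + (lag_days + 1,))
    for k in range(lag_days + 1):
        idx = np.maximum(np.arange(T) - k, 0)
        out[..., k] = v[idx]
    return out


# ---------------------------------------------------------------------------
# response networks (numpy forward/backward)
# ---------------------------------------------------------------------------

# fixed affine standardization of temperature inputs (deg C -> unitless)
_T_SHIFT = 20.0
_T_SCALE = 10.0


class _ExponentialNet:
    """f(T) = softplus(rc) + sum_k softplus(rs_k) * exp(w_k . T' + b_k)

    with T' = (T - 20)/10 the standardized lag vector.  The regularizable
    parameters (exponent weights and biases) are returned by ``reg_names``.
    """

    names = ("W", "b", "rs", "rc")
    reg_names = ("W", "b")

    @staticmethod
    def init(rng: np.random.Generator, lag_days: int,
             hidden_dim: int) -> dict[str, np.ndarray]:
        L1 = lag_days + 1
        W = rng.normal(0.0, 0.3, size=(hidden_dim, L1))
        b = rng.normal(0.0, 0.3, size=hidden_dim)
        rs = np.full(hidden_dim, softplus_inv(0.95 / hidden_dim)) \
            + rng.normal(0.0, 0.05, size=hidden_dim)
        rc = np.array([softplus_inv(0.05)])
        return {"W": W, "b": b, "rs": rs, "rc": rc}

    @staticmethod
    def forward(p: dict[str, np.ndarray], X: np.ndarray,
                standardized: bool = False):
        Xs = X if standardized else (X - _T_SHIFT) / _T_SCALE
        z = Xs @ p["W"].T + p["b"]
        zc = np.minimum(z, _Z_CLIP)
        e = np.exp(zc)
        s = softplus(p["rs"])
        c = softplus(p["rc"])[0]
        f = c + e @ s
        return f, (Xs, z, e, s)

    @staticmethod
    def backward(p, cache, gf: np.ndarray) -> dict[str, np.ndarray]:
        Xs, z, e, s = cache
        gs = e.T @ gf
        gc = gf.sum()
        gz = (gf[:, None] * e) * s[None, :]
        gz[z > _Z_CLIP] = 0.0
        return {
            "W": gz.T @ Xs,
            "b": gz.sum(axis=0),
            "rs": gs * sigmoid(p["rs"]),
            "rc": np.array([gc]) * sigmoid(p["rc"]),
        }


class _LinearNet:
    """1-D convolution (kernel size l) + rectifier MLP + softplus output."""

    names = ("k", "kb", "W1", "b1", "w2", "b2")
    reg_names = ("k", "W1", "w2")

    @staticmethod
    def init(rng: np.random.Generator, lag_days: int,
             hidden_dim: int) -> dict[str, np.ndarray]:
        L = max(lag_days, 1)
        k = rng.normal(0.0, 0.3, size=L)
        kb = np.array([0.5])
        W1 = rng.normal(0.0, 0.3, size=(2, hidden_dim))
        b1 = np.full(hidden_dim, 0.1)
        w2 = rng.normal(0.0, 0.3, size=hidden_dim)
        b2 = np.array([float(softplus_inv(1.0))])
        return {"k": k, "kb": kb, "W1": W1, "b1": b1, "w2": w2, "b2": b2}

    @staticmethod
    def forward(p: dict[str, np.ndarray], X: np.ndarray,
                standardized: bool = False):
        Xs = X if standardized else (X - _T_SHIFT) / _T_SCALE
        L = p["k"].shape[0]
        u0 = Xs[:, :L] @ p["k"] + p["kb"][0]
        u1 = Xs[:, Xs.shape[1] - L:] @ p["k"] + p["kb"][0]
        U = np.stack([u0, u1], axis=1)
        Ur = np.maximum(U, 0.0)
        Hpre = Ur @ p["W1"] + p["b1"]
        H = np.maximum(Hpre, 0.0)
        o = H @ p["w2"] + p["b2"][0]
        f = softplus(o)
        return f, (Xs, U, Ur, Hpre, H, o)

    @staticmethod
    def backward(p, cache, gf: np.ndarray) -> dict[str, np.ndarray]:
        Xs, U, Ur, Hpre, H, o = cache
        L = p["k"].shape[0]
        go = gf * sigmoid(o)
        gw2 = H.T @ go
        gb2 = np.array([go.sum()])
        gH = go[:, None] * p["w2"][None, :]
        gH[Hpre <= 0] = 0.0
        gW1 = Ur.T @ gH
        gb1 = gH.sum(axis=0)
        gU = gH @ p["W1"].T
        gU[U <= 0] = 0.0
        gk = Xs[:, :L].T @ gU[:, 0] + Xs[:, Xs.shape[1] - L:].T @ gU[:, 1]
        gkb = np.array([gU.sum()])
        return {"k": gk, "kb": gkb, "W1": gW1, "b1": gb1, "w2": gw2, "b2": gb2}


_NETS = {"exponential": _ExponentialNet, "linear": _LinearNet}


def response_factor(variant: str, params: dict[str, np.ndarray],
                    lag_vectors: np.ndarray) -> np.ndarray:
    """Evaluate the exposure-response multiplying factor on lag vectors.

    ``lag_vectors`` has shape ``(..., l+1)``; returns the matching shape of
    non-negative factors.
    """
    net = _NETS[variant]
    X = np.asarray(lag_vectors, dtype=float)
    if variant == "exponential" and X.shape[-1] != params["W"].shape[1]:
        raise ValueError(
            f"lag vector length {X.shape[-1]} does not match "
            f"parameters (expected {params['W'].shape[1]})")
    flat = X.reshape(-1, X.shape[-1])
    f, _ = net.forward(params, flat)
    return f.reshape(X.shape[:-1])


# ---------------------------------------------------------------------------
# expected deaths and Poisson loss
# ---------------------------------------------------------------------------

def expected_deaths(baseline_rates: np.ndarray, population: np.ndarray,
                    factors: np.ndarray, dow: np.ndarray) -> np.ndarray:
    """E = baseline x population x f x dow with broadcasting.

    ``baseline_rates`` (T, S, A) per person-day; ``population`` (T, I, S, A);
    ``factors`` (T, I, S, A); ``dow`` (T,) day-of-week multipliers.
    """
    b = np.asarray(baseline_rates)[:, None, :, :]
    pop = np.asarray(population)
    f = np.asarray(factors)
    if pop.shape != f.shape or b.shape[0] != pop.shape[0] or b.shape[2:] != pop.shape[2:]:
        raise ValueError("misaligned strata: baseline/population/factor shapes differ")
    out = b * pop * f * np.asarray(dow)[:, None, None, None]
    if (out < 0).any():
        raise ValueError("negative expected deaths; inputs must be non-negative")
    return out


def poisson_nll(expected: np.ndarray, observed: np.ndarray,
                eps: float = _EPS_RATE) -> float:
    """Poisson negative log likelihood sum(lambda - y log lambda), y-constants dropped.

    ``expected`` is floored at ``eps`` before the log so early-training zeros
    do not produce infinities; a genuinely non-positive rate with a positive
    observation is a modelling error surfaced by the floor's enormous loss.
    """
    lam = np.maximum(np.asarray(expected, dtype=float), eps)
    y = np.asarray(observed, dtype=float)
    if (y < 0).any():
        raise ValueError("observed counts must be non-negative")
    return float(np.sum(lam - y * np.log(lam)))


def poisson_nll_grad(expected: np.ndarray, observed: np.ndarray,
                     eps: float = _EPS_RATE) -> np.ndarray:
    """d(nll)/d(lambda) = 1 - y/lambda elementwise (with the epsilon floor)."""
    lam = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    return 1.0 - y / np.maximum(lam, eps)


# ---------------------------------------------------------------------------
# training data and design
# ---------------------------------------------------------------------------

@dataclass
class TrainingData:
    """Bundle of everything the exposure model trains on.

    Attributes
    ----------
    district_temps : DataArray (time, district), daily mean deg C
    district_states : Series mapping district id -> state id
    population_daily : DataArray (time, district, sex, age)
    streams : dict of reporting DataFrames keyed by stream name
    """

    district_temps: xr.DataArray
    district_states: pd.Series
    population_daily: xr.DataArray
    streams: dict[str, pd.DataFrame] = field(default_factory=dict)


class _Design:
    """Precomputed index structures and observed arrays for one dataset."""

    def __init__(self, data: TrainingData, lag_days: int):
        temps = data.district_temps
        self.dates = pd.DatetimeIndex(temps.coords["time"].values)
        check_contiguous_daily(self.dates)
        self.districts = [str(d) for d in temps.coords["district"].values]
        self.states = sorted(set(pd.Series(data.district_states).astype(str)))
        st_map = {s: i for i, s in enumerate(self.states)}
        self.state_of_i = np.array(
            [st_map[str(pd.Series(data.district_states)[d])] for d in self.districts])
        T, I = len(self.dates), len(self.districts)
        self.T, self.I = T, I
        self.S, self.A = len(SEXES), len(FIVE_YEAR_LABELS)
        self.G, self.Fi = len(BROAD_LABELS), len(FINE_EDGES)

        day_num = (self.dates - self.dates[0]).days.values.astype(float)
        self.tau = (day_num - day_num.mean()) / 365.25
        self.tau_origin = self.dates[0]
        self.tau_center_days = float(day_num.mean())
        self.dow_of_t = self.dates.weekday.values
        self.year_of_t = self.dates.year.values

        self.weeks = full_iso_weeks(self.dates)
        self.Wk = len(self.weeks)
        wk_map = {w: i for i, w in enumerate(self.weeks)}
        mondays = iso_week_monday(self.dates)
        self.week_of_t = np.array([wk_map.get(m, -1) for m in mondays])
        self.year_of_wk = self.weeks.year.values

        self.A_broad = band_projection(BROAD_EDGES)
        self.A_fine = band_projection(FINE_EDGES)
        self.broad_of_a = np.argmax(self.A_broad, axis=0)
        self.fine_of_a = np.argmax(self.A_fine, axis=0)

        pop = data.population_daily.sel(time=self.dates)
        pop = pop.transpose("time", "district", "sex", "age")
        self.P = np.asarray(pop.values, dtype=float)
        if self.P.shape != (T, I, self.S, self.A):
            raise ValueError("population_daily misaligned with temperatures")

        self.temps = np.asarray(temps.values, dtype=float)  # (T, I)
        self.Tlag = build_lag_matrix(self.temps, lag_days)  # (T, I, L+1)

        M_state = np.zeros((len(self.states), I))
        M_state[self.state_of_i, np.arange(I)] = 1.0
        self.M_state = M_state
        M_week = np.zeros((self.Wk, T))
        sel = self.week_of_t >= 0
        M_week[self.week_of_t[sel], np.nonzero(sel)[0]] = 1.0
        self.M_week = M_week

        self.y1, self.has1 = self._dense_stream1(data.streams)
        self.y2, self.has2 = self._dense_stream2(data.streams)
        self.y3, self.has3 = self._dense_stream3(data.streams)

    # -- observed stream tables to dense arrays ---------------------------
    def _dense_stream1(self, streams):
        if STREAM_DAILY_STATE_SEX not in streams:
            return np.zeros((self.T, len(self.states), self.S)), False
        df = streams[STREAM_DAILY_STATE_SEX]
        y = np.zeros((self.T, len(self.states), self.S))
        t_idx = {d: i for i, d in enumerate(self.dates)}
        s_idx = {s: i for i, s in enumerate(self.states)}
        x_idx = {s: i for i, s in enumerate(SEXES)}
        for row in df.itertuples(index=False):
            ti = t_idx.get(pd.Timestamp(row.date))
            if ti is not None:
                y[ti, s_idx[str(row.state)], x_idx[row.sex]] = row.deaths
        return y, True

    def _dense_stream2(self, streams):
        shape = (self.Wk, len(self.states), self.S, self.G)
        if STREAM_WEEKLY_STATE_SEX_BROADAGE not in streams:
            return np.zeros(shape), False
        df = streams[STREAM_WEEKLY_STATE_SEX_BROADAGE]
        y = np.zeros(shape)
        w_idx = {w: i for i, w in enumerate(self.weeks)}
        s_idx = {s: i for i, s in enumerate(self.states)}
        x_idx = {s: i for i, s in enumerate(SEXES)}
        a_idx = {a: i for i, a in enumerate(BROAD_LABELS)}
        for row in df.itertuples(index=False):
            wi = w_idx.get(pd.Timestamp(row.week))
            if wi is not None:
                y[wi, s_idx[str(row.state)], x_idx[row.sex], a_idx[row.age]] = row.deaths
        return y, True

    def _dense_stream3(self, streams):
        shape = (self.Wk, self.S, self.Fi)
        if STREAM_WEEKLY_NATIONAL_SEX_FINEAGE not in streams:
            return np.zeros(shape), False
        df = streams[STREAM_WEEKLY_NATIONAL_SEX_FINEAGE]
        from .containers import FINE_LABELS
        y = np.zeros(shape)
        w_idx = {w: i for i, w in enumerate(self.weeks)}
        x_idx = {s: i for i, s in enumerate(SEXES)}
        a_idx = {a: i for i, a in enumerate(FINE_LABELS)}
        for row in df.itertuples(index=False):
            wi = w_idx.get(pd.Timestamp(row.week))
            if wi is not None:
                y[wi, x_idx[row.sex], a_idx[row.age]] = row.deaths
        return y, True

    def year_masks(self, years: Sequence[int]):
        yrs = set(int(y) for y in years)
        m_t = np.isin(self.year_of_t, list(yrs))
        m_w = np.isin(self.year_of_wk, list(yrs))
        return m_t, m_w


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

_GROUPS = [(s, g) for s in range(len(SEXES)) for g in range(len(BROAD_LABELS))]


class ExposureResponseModel(BaseEstimator):
    """One instance of the temperature-mortality model (Poisson-trained).

    Parameters
    ----------
    variant : {"exponential", "linear"}
        Response-function family.
    lag_days : int
        Number of preceding days in the temperature lag vector (window
        length ``lag_days + 1``).
    hidden_dim : int
        Number of exponential terms / hidden units per response function.
    train_years, validation_years : tuple of int (inclusive ranges)
        Temporal split; the default mirrors an 80:20 split of a ten-year
        record (first eight years train, last two validate).
    dow_correction : bool
        Whether the mean-one day-of-week factors are trainable (else fixed 1).
    l2_reg : float
        Ridge penalty on the response networks' weight parameters (in NLL
        units); a small value tames unidentified extrapolation directions.
    n_rounds, base_iters, net_iters : int
        Optimization proceeds by block-alternating L-BFGS: ``n_rounds``
        passes of (baseline+day-of-week block, response-network block) with
        the given per-block iteration caps, followed by a short baseline
        polish.  The joint problem couples parameters of vastly different
        curvature (baseline rates touch every death, steep exponent weights
        only the hottest days); alternation conditions each subproblem and
        reliably reaches the likelihood optimum where joint first-order or
        quasi-Newton steps stall.
    random_state : int
        Seed for parameter initialization.
    """

    def __init__(self, variant: str = "exponential", lag_days: int = 7,
                 hidden_dim: int = 8, train_years: tuple[int, int] = (2011, 2018),
                 validation_years: tuple[int, int] = (2019, 2020),
                 dow_correction: bool = True, l2_reg: float = 0.02,
                 n_rounds: int = 2, base_iters: int = 100, net_iters: int = 250,
                 random_state: int = 0):
        self.variant = variant
        self.lag_days = lag_days
        self.hidden_dim = hidden_dim
        self.train_years = train_years
        self.validation_years = validation_years
        self.dow_correction = dow_correction
        self.l2_reg = l2_reg
        self.n_rounds = n_rounds
        self.base_iters = base_iters
        self.net_iters = net_iters
        self.random_state = random_state

    # -- parameter handling ------------------------------------------------
    def _init_params(self, design: _Design) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        net = _NETS[self.variant]
        params: dict[str, np.ndarray] = {}
        beta0 = self._crude_log_rates(design)
        params["beta0"] = beta0 + rng.normal(0.0, 0.01, size=beta0.shape)
        params["beta1"] = np.zeros_like(beta0)
        params["rho"] = rng.normal(0.0, 0.01, size=7) if self.dow_correction \
            else np.zeros(7)
        for k in range(len(_GROUPS)):
            for name, v in net.init(rng, self.lag_days, self.hidden_dim).items():
                params[f"net{k}_{name}"] = v
        return params

    def _crude_log_rates(self, design: _Design) -> np.ndarray:
        """Deterministic baseline init from observed stream totals."""
        person_days = design.P.sum(axis=(0, 1))  # (S, A)
        person_days = np.maximum(person_days, 1.0)
        if design.has3:
            deaths_f = design.y3.sum(axis=0)  # (S, Fi)
            pd_f = np.maximum(
                np.einsum("sa,fa->sf", person_days, design.A_fine), 1.0)
            frac_weeks = max(design.M_week.sum() / design.T, 1e-6)
            rate_f = deaths_f / (pd_f * frac_weeks)
            rate = rate_f[:, design.fine_of_a]
        else:
            total = design.y1.sum() if design.has1 else design.y2.sum()
            total = max(total, 1.0)
            rate = np.full((design.S, design.A),
                           total / person_days.sum())
        return np.log(np.maximum(rate, 1e-12))

    # -- forward / backward ------------------------------------------------
    def _forward(self, params, design, want_grad: bool,
                 mask_t=None, mask_w=None):
        d = design
        B = np.exp(params["beta0"][None] + params["beta1"][None] * d.tau[:, None, None])
        C = B[:, None] * d.P  # (T, I, S, A)
        erho = np.exp(params["rho"])
        dowf = erho / erho.mean()
        dvec = dowf[d.dow_of_t]
        if not hasattr(d, "_Xs_flat"):
            d._Xs_flat = (d.Tlag.reshape(d.T * d.I, -1) - _T_SHIFT) / _T_SCALE
        net = _NETS[self.variant]
        F = np.empty((d.T, d.I, d.S, d.G))
        caches = []
        for k, (s, g) in enumerate(_GROUPS):
            p_k = {n: params[f"net{k}_{n}"] for n in net.names}
            f, cache = net.forward(p_k, d._Xs_flat, standardized=True)
            F[:, :, s, g] = f.reshape(d.T, d.I)
            caches.append((p_k, cache))
        Fa = F[:, :, :, d.broad_of_a]
        E = C * Fa * dvec[:, None, None, None]

        E_sumA = E.sum(axis=3)
        lam1 = np.einsum("tis,ji->tjs", E_sumA, d.M_state)
        E_g = np.einsum("tisa,ga->tisg", E, d.A_broad)
        E_g_state = np.einsum("tisg,ji->tjsg", E_g, d.M_state)
        lam2 = np.tensordot(d.M_week, E_g_state, axes=(1, 0))
        E_nat = E.sum(axis=1)
        E_f = np.einsum("tsa,fa->tsf", E_nat, d.A_fine)
        lam3 = np.tensordot(d.M_week, E_f, axes=(1, 0))

        def _nll(mt, mw):
            total = 0.0
            if d.has1:
                total += poisson_nll(lam1[mt], d.y1[mt])
            if d.has2:
                total += poisson_nll(lam2[mw], d.y2[mw])
            if d.has3:
                total += poisson_nll(lam3[mw], d.y3[mw])
            return total

        if not want_grad:
            return _nll(mask_t, mask_w)

        mt, mw = mask_t, mask_w
        c1 = np.zeros_like(lam1)
        if d.has1:
            c1[mt] = poisson_nll_grad(lam1[mt], d.y1[mt])
        c2 = np.zeros_like(lam2)
        if d.has2:
            c2[mw] = poisson_nll_grad(lam2[mw], d.y2[mw])
        c3 = np.zeros_like(lam3)
        if d.has3:
            c3[mw] = poisson_nll_grad(lam3[mw], d.y3[mw])

        widx = np.where(d.week_of_t >= 0, d.week_of_t, d.Wk)
        c2p = np.concatenate([c2, np.zeros((1,) + c2.shape[1:])], axis=0)
        c3p = np.concatenate([c3, np.zeros((1,) + c3.shape[1:])], axis=0)
        # expand each stream's coefficient back to (T, I, S, A)
        c3t = c3p[widx][:, :, d.fine_of_a]  # (T, S, A)
        G_a = (c1[:, d.state_of_i, :][:, :, :, None]
               + c2p[widx][:, d.state_of_i][:, :, :, d.broad_of_a]
               + c3t[:, None])
        GE = G_a * E
        grads: dict[str, np.ndarray] = {}
        grads["beta0"] = GE.sum(axis=(0, 1))
        grads["beta1"] = np.einsum("tisa,t->sa", GE, d.tau)
        s_t = GE.sum(axis=(1, 2, 3)) / dvec
        gdow = np.bincount(d.dow_of_t, weights=s_t, minlength=7)
        if self.dow_correction:
            inner = float(np.sum(gdow * dowf))
            grads["rho"] = gdow * dowf - dowf * inner / 7.0
        else:
            grads["rho"] = np.zeros(7)
        GC = G_a * C * dvec[:, None, None, None]
        gF = np.einsum("tisa,ga->tisg", GC, d.A_broad)
        for k, (s, g) in enumerate(_GROUPS):
            p_k, cache = caches[k]
            gk = net.backward(p_k, cache, gF[:, :, s, g].reshape(-1))
            for n, v in gk.items():
                grads[f"net{k}_{n}"] = v
        return _nll(mt, mw), grads

    # -- fitting -----------------------------------------------------------
    def fit(self, data: TrainingData, design: _Design | None = None):
        design = design or _Design(data, self.lag_days)
        if not (design.has1 or design.has2 or design.has3):
            raise ValueError("no reporting streams provided")
        tr_t, tr_w = design.year_masks(range(self.train_years[0],
                                             self.train_years[1] + 1))
        va_t, va_w = design.year_masks(range(self.validation_years[0],
                                             self.validation_years[1] + 1))
        if not tr_t.any():
            raise ValueError("training years do not overlap the data calendar")
        has_val = bool(va_t.any() or va_w.any())

        from scipy.optimize import minimize

        params = self._init_params(design)
        keys = sorted(params)
        shapes = {k: params[k].shape for k in keys}
        sizes = {k: params[k].size for k in keys}
        base_keys = [k for k in ("beta0", "beta1", "rho")
                     if k != "rho" or self.dow_correction]
        net_keys = [k for k in keys if k.startswith("net")]
        reg_keys = {f"net{k}_{n}" for k in range(len(_GROUPS))
                    for n in _NETS[self.variant].reg_names}

        def make_objective(subset):
            def objective(v):
                i = 0
                for k in subset:
                    params[k] = v[i:i + sizes[k]].reshape(shapes[k])
                    i += sizes[k]
                nll, grads = self._forward(params, design, True, tr_t, tr_w)
                if self.l2_reg > 0:
                    for k in reg_keys:
                        if k in subset:
                            nll += self.l2_reg * float(np.sum(params[k] ** 2))
                            grads[k] = grads[k] + 2.0 * self.l2_reg * params[k]
                return nll, np.concatenate([grads[k].ravel() for k in subset])
            return objective

        def vec_of(subset):
            return np.concatenate([params[k].ravel() for k in subset])

        def run_block(subset, maxiter):
            return minimize(make_objective(subset), vec_of(subset), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxcor": 30})

        n_iter = 0
        history = []
        best = {"val": np.inf, "params": None}
        for _ in range(self.n_rounds):
            res_b = run_block(base_keys, self.base_iters)
            res_n = run_block(net_keys, self.net_iters)
            n_iter += int(res_b.nit) + int(res_n.nit)
            if has_val:
                val = self._forward(params, design, False, va_t, va_w)
                history.append(val)
                if val < best["val"]:
                    best["val"] = val
                    best["params"] = {k: v.copy() for k, v in params.items()}
        res_b = run_block(base_keys, self.base_iters)  # final baseline polish
        n_iter += int(res_b.nit)
        if has_val:
            val = self._forward(params, design, False, va_t, va_w)
            history.append(val)
            if val < best["val"]:
                best["val"] = val
                best["params"] = {k: v.copy() for k, v in params.items()}
            self.params_ = best["params"]
        else:
            self.params_ = {k: v.copy() for k, v in params.items()}
        self.n_iter_ = n_iter
        self.history_ = history
        self.train_nll_ = self._forward(self.params_, design, False, tr_t, tr_w)
        self.validation_nll_ = (self._forward(self.params_, design, False,
                                              va_t, va_w) if has_val else np.nan)
        self.tau_origin_ = design.tau_origin
        self.tau_center_days_ = design.tau_center_days
        return self

    # -- prediction --------------------------------------------------------
    def _tau_of(self, dates: pd.DatetimeIndex,
                frozen_at: pd.Timestamp | None = None) -> np.ndarray:
        day_num = (dates - self.tau_origin_).days.values.astype(float)
        tau = (day_num - self.tau_center_days_) / 365.25
        if frozen_at is not None:
            cap = (pd.Timestamp(frozen_at) - self.tau_origin_).days
            tau = np.minimum(tau, (cap - self.tau_center_days_) / 365.25)
        return tau

    def baseline_rates(self, dates: pd.DatetimeIndex,
                       frozen_at=None) -> np.ndarray:
        """Per-person-day death rates (T, S, A)."""
        tau = self._tau_of(pd.DatetimeIndex(dates), frozen_at)
        return np.exp(self.params_["beta0"][None]
                      + self.params_["beta1"][None] * tau[:, None, None])

    @property
    def dow_factors_(self) -> np.ndarray:
        erho = np.exp(self.params_["rho"])
        return erho / erho.mean()

    def response_factors(self, lag_vectors: np.ndarray) -> np.ndarray:
        """Factors per group: input (..., l+1) -> output (..., S, G)."""
        X = np.asarray(lag_vectors, dtype=float)
        out = np.empty(X.shape[:-1] + (len(SEXES), len(BROAD_LABELS)))
        for k, (s, g) in enumerate(_GROUPS):
            p_k = {n: self.params_[f"net{k}_{n}"] for n in _NETS[self.variant].names}
            out[..., s, g] = response_factor(self.variant, p_k, X)
        return out

    def predict_expected(self, district_temps: xr.DataArray,
                         population_daily: xr.DataArray,
                         cap_c: float | None = None,
                         baseline_frozen_at=None,
                         dow: bool = True) -> xr.DataArray:
        """Daily expected deaths (time, district, sex, age).

        If ``cap_c`` is given the whole temperature series is capped at that
        value *before* lag-vector construction (the counterfactual used for
        heat attribution).
        """
        dates = pd.DatetimeIndex(district_temps.coords["time"].values)
        temps = np.asarray(district_temps.values, dtype=float)
        if cap_c is not None:
            temps = np.minimum(temps, cap_c)
        Tlag = build_lag_matrix(temps, self.lag_days)
        Fg = self.response_factors(Tlag)  # (T, I, S, G)
        broad_of_a = np.argmax(band_projection(BROAD_EDGES), axis=0)
        Fa = Fg[:, :, :, broad_of_a]
        B = self.baseline_rates(dates, baseline_frozen_at)
        pop = population_daily.sel(time=dates).transpose(
            "time", "district", "sex", "age").values
        dvec = self.dow_factors_[dates.weekday.values] if dow else np.ones(len(dates))
        E = expected_deaths(B, pop, Fa, dvec)
        from .containers import stratified_daily
        return stratified_daily(E, dates,
                                [str(x) for x in district_temps.coords["district"].values])

    def rescaled(self, c: float) -> "ExposureResponseModel":
        """Return a copy with baseline x c and response function x 1/c.

        The Poisson likelihood and all excess estimates are invariant under
        this transformation (identifiability gauge).
        """
        other = copy.deepcopy(self)
        other.params_["beta0"] = other.params_["beta0"] + np.log(c)
        if self.variant == "exponential":
            for k in range(len(_GROUPS)):
                other.params_[f"net{k}_rs"] = softplus_inv(
                    softplus(other.params_[f"net{k}_rs"]) / c)
                other.params_[f"net{k}_rc"] = softplus_inv(
                    softplus(other.params_[f"net{k}_rc"]) / c)
        else:
            raise NotImplementedError(
                "exact rescaling is only structural for the exponential variant")
        return other


class MortalityEnsemble(BaseEstimator):
    """Ensemble of independently initialized exposure models, averaged.

    The final predictor is the mean of the instance-level daily expected
    deaths, reducing the initialization variance of single instances.
    """

    def __init__(self, n_instances: int = 20, seeds: Sequence[int] | None = None,
                 random_state: int = 0, **model_kwargs):
        self.n_instances = n_instances
        self.seeds = seeds
        self.random_state = random_state
        self.model_kwargs = model_kwargs

    def get_params(self, deep=True):  # model_kwargs is a plain passthrough
        return {"n_instances": self.n_instances, "seeds": self.seeds,
                "random_state": self.random_state, "model_kwargs": self.model_kwargs}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, data: TrainingData):
        if self.n_instances < 1:
            raise ValueError("ensemble size must be >= 1")
        if self.seeds is not None:
            if len(self.seeds) < self.n_instances:
                raise ValueError(
                    f"{len(self.seeds)} seeds provided for "
                    f"{self.n_instances} instances")
            seeds = [int(s) for s in self.seeds[: self.n_instances]]
        else:
            ss = np.random.SeedSequence(self.random_state)
            seeds = [int(s) for s in ss.generate_state(self.n_instances) >> 1]
        lag_days = self.model_kwargs.get("lag_days", 7)
        design = _Design(data, lag_days)
        self.instances_ = []
        self.fit_report_ = []
        for seed in seeds:
            inst = ExposureResponseModel(random_state=seed, **self.model_kwargs)
            inst.fit(data, design=design)
            self.instances_.append(inst)
            self.fit_report_.append({
                "seed": seed, "train_nll": inst.train_nll_,
                "validation_nll": inst.validation_nll_,
                "n_iter": inst.n_iter_,
            })
        self.seeds_ = seeds
        return self

    def predict_expected(self, district_temps, population_daily,
                         **kw) -> xr.DataArray:
        """Ensemble-mean daily expected deaths (time, district, sex, age)."""
        acc = None
        for inst in self.instances_:
            E = inst.predict_expected(district_temps, population_daily, **kw)
            acc = E if acc is None else acc + E
        return acc / len(self.instances_)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: MortalityEnsemble, directory) -> None:
    """Write each instance as an .npz checkpoint plus a JSON metadata file."""
    import json
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"n_instances": len(ensemble.instances_), "seeds": ensemble.seeds_,
            "model_kwargs": ensemble.model_kwargs,
            "fit_report": ensemble.fit_report_}
    for i, inst in enumerate(ensemble.instances_):
        np.savez(directory / f"instance_{i:03d}.npz", **inst.params_)
    inst0 = ensemble.instances_[0]
    meta["tau_origin"] = str(inst0.tau_origin_)
    meta["tau_center_days"] = inst0.tau_center_days_
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2, default=str))


def load_ensemble(directory) -> MortalityEnsemble:
    import json
    from pathlib import Path
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    ens = MortalityEnsemble(n_instances=meta["n_instances"],
                            seeds=meta["seeds"], **meta["model_kwargs"])
    ens.instances_ = []
    ens.seeds_ = meta["seeds"]
    ens.fit_report_ = meta["fit_report"]
    for i in range(meta["n_instances"]):
        inst = ExposureResponseModel(random_state=meta["seeds"][i],
                                     **meta["model_kwargs"])
        with np.load(directory / f"instance_{i:03d}.npz") as z:
            inst.params_ = {k: z[k] for k in z.files}
        inst.tau_origin_ = pd.Timestamp(meta["tau_origin"])
        inst.tau_center_days_ = float(meta["tau_center_days"])
        ens.instances_.append(inst)
    return ens


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_metrics(predicted: np.ndarray, observed: np.ndarray,
                     national_mean_temp: np.ndarray | None = None,
                     warm_threshold: float = 20.0) -> dict[str, float]:
    """RMSE / R-squared on all cells and on warm days, plus Poisson bounds.

    ``predicted`` is the model's expected count (lambda) per cell, ``observed``
    the registered count.  Warm-day metrics use the cells whose
    population-weighted national mean temperature exceeds ``warm_threshold``.
    The theoretical floor on the RMSE of *any* predictor of a Poisson count
    with the true rates lambda is sqrt(mean lambda); the matching ceiling on
    R-squared is ``1 - mean(lambda) / var(y)``.
    """
    lam = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if lam.shape != y.shape:
        raise ValueError("predicted and observed must align")

    def _metrics(l, o):
        if l.size == 0:
            return dict(rmse=np.nan, r2=np.nan, poisson_rmse_bound=np.nan,
                        r2_upper_bound=np.nan)
        rmse = float(np.sqrt(np.mean((l - o) ** 2)))
        var = float(np.var(o))
        r2 = float(1.0 - np.mean((l - o) ** 2) / var) if var > 0 else np.nan
        bound = float(np.sqrt(np.mean(l)))
        r2_ub = float(1.0 - np.mean(l) / var) if var > 0 else np.nan
        return dict(rmse=rmse, r2=r2, poisson_rmse_bound=bound,
                    r2_upper_bound=r2_ub)

    out = {f"{k}_all": v for k, v in _metrics(lam, y).items()}
    if national_mean_temp is not None:
        warm = np.asarray(national_mean_temp, dtype=float).ravel() > warm_threshold
        sub = _metrics(lam[warm], y[warm])
        out.update({f"{k}_warm": v for k, v in sub.items()})
    return out
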