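"""Attention-weighted spatial interpolation of point temperatures to districts.

Each district ``i`` carries a trainable position ``X_i = (lon_i, lat_i)``, a
bias ``b_i`` (deg C) and a positive scale ``alpha_i``; the district's daily
mean temperature is a softmax-weighted average of the source points (weather
stations or climate-model grid points),

    T_i(t) = b_i + sum_j w_ij T_j(t),
    w_ij = exp(-alpha_i d(X_i, Y_j)) / sum_k exp(-alpha_i d(X_i, Y_k)),

with ``d`` the great-circle distance in km.  The weights are constant in
time, so the map is affine in the source temperatures and a uniform shift of
all sources shifts every district by the same amount.  The same fitted model
is reused unchanged for climate downscaling (no bias correction).

The fitting problem separates across districts (four parameters each), so
each district is fitted independently with L-BFGS-B on the training-period
mean squared error; positivity of ``alpha`` is enforced via softplus of an
unconstrained parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from ._optim import softplus, softplus_inv

__all__ = ["great_circle_km", "attention_weights", "AttentionInterpolator",
           "fill_gaps_mean_adjusted"]

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    """Haversine great-circle distance in km.

    ``lonlat_a`` is ``(..., 2)`` and ``lonlat_b`` ``(m, 2)``; broadcasting
    returns ``(..., m)`` distances.
    """
    a = np.radians(np.asarray(lonlat_a, dtype=float))
    b = np.radians(np.asarray(lonlat_b, dtype=float))
    lon1, lat1 = a[..., 0:1], a[..., 1:2]
    lon2, lat2 = b[..., 0], b[..., 1]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def attention_weights(district_coord: np.ndarray, source_coords: np.ndarray,
                      alpha: float) -> np.ndarray:
    """Softmax attention of one district over the source points (sums to 1)."""
    source_coords = np.atleast_2d(np.asarray(source_coords, dtype=float))
    if source_coords.shape[0] == 0:
        raise ValueError("at least one source point is required")
    d = great_circle_km(np.asarray(district_coord, dtype=float), source_coords)
    z = -float(alpha) * d
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class AttentionInterpolator(RegressorMixin, BaseEstimator):
    """Trainable station-to-district temperature interpolator.

    Parameters
    ----------
    source_coords : array (n_sources, 2)
        Fixed (lon, lat) of the source points; immutable during fitting.
    district_coords_init : array (n_districts, 2)
        District reference points used to initialize the trainable positions.
    alpha_init : float
        Initial scale (1/km) of the distance decay.
    train_fraction : float
        Leading fraction of days used for fitting; the remainder reports a
        validation RMSE (temporal 80:20 split by default).
    max_iter : int
        L-BFGS-B iteration cap per district.

    Attributes
    ----------
    coords_ : (n_districts, 2) fitted district positions
    bias_ : (n_districts,) fitted biases, deg C
    alpha_ : (n_districts,) fitted positive scales
    weights_ : (n_districts, n_sources) attention weights
    train_rmse_, validation_rmse_ : fit quality in deg C
    """

    def __init__(self, source_coords=None, district_coords_init=None,
                 alpha_init: float = 1.0, train_fraction: float = 0.8,
                 max_iter: int = 300, random_state: int = 0):
        self.source_coords = source_coords
        self.district_coords_init = district_coords_init
        self.alpha_init = alpha_init
        self.train_fraction = train_fraction
        self.max_iter = max_iter
        self.random_state = random_state

    # -- core --------------------------------------------------------------
    def _weights(self, coords: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(self.source_coords, dtype=float))
        d = great_circle_km(coords[:, None, :], Y)[:, 0, :]
        z = -alpha[:, None] * d
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, X: np.ndarray, y: np.ndarray):
        """Fit district positions, biases and scales.

        ``X`` is (n_days, n_sources) source temperatures (no missing values)
        and ``y`` (n_days, n_districts) reference district temperatures over
        the same days.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X (days x sources) and y (days x districts) "
                             "must share the day axis")
        if X.shape[0] == 0:
            raise ValueError("no overlapping dates between source and reference")
        if np.isnan(X).any():
            raise ValueError("missing source values; fill gaps before fitting "
                             "(see fill_gaps_mean_adjusted)")
        Y = np.atleast_2d(np.asarray(self.source_coords, dtype=float))
        if Y.shape[0] != X.shape[1]:
            raise ValueError("source_coords and X disagree on source count")
        init = np.asarray(self.district_coords_init, dtype=float)
        n_districts = init.shape[0]
        if y.shape[1] != n_districts:
            raise ValueError("district_coords_init and y disagree on districts")

        n_train = max(int(round(self.train_fraction * X.shape[0])), 1)
        Xtr, ytr = X[:n_train], y[:n_train]

        coords = np.empty((n_districts, 2))
        bias = np.empty(n_districts)
        raw_alpha0 = float(softplus_inv(self.alpha_init))
        alpha = np.empty(n_districts)
        for i in range(n_districts):
            ref = ytr[:, i]

            def objective(p):
                w = attention_weights(p[:2], Y, softplus(p[3]))
                pred = p[2] + Xtr @ w
                return float(np.mean((pred - ref) ** 2))

            # multi-start over the scale: a local (alpha_init) and a
            # near-uniform (small alpha) basin; each L-BFGS run is polished
            # by a derivative-free pass, since quasi-Newton steps can stall
            # on finite-difference gradient noise near the optimum
            best = None
            for raw_a in (raw_alpha0, float(softplus_inv(1e-3))):
                p0 = np.array([init[i, 0], init[i, 1], 0.0, raw_a])
                res = minimize(objective, p0, method="L-BFGS-B",
                               options={"maxiter": self.max_iter,
                                        "ftol": 1e-15, "gtol": 1e-12})
                res = minimize(objective, res.x, method="Nelder-Mead",
                               options={"maxiter": 600, "xatol": 1e-10,
                                        "fatol": 1e-14})
                if best is None or res.fun < best.fun:
                    best = res
            coords[i] = best.x[:2]
            bias[i] = best.x[2]
            alpha[i] = softplus(best.x[3])

        self.coords_ = coords
        self.bias_ = bias
        self.alpha_ = alpha
        self.weights_ = self._weights(coords, alpha)
        self.n_sources_ = X.shape[1]
        pred_tr = self.predict(Xtr)
        self.train_rmse_ = float(np.sqrt(np.mean((pred_tr - ytr) ** 2)))
        if n_train < X.shape[0]:
            pred_va = self.predict(X[n_train:])
            self.validation_rmse_ = float(
                np.sqrt(np.mean((pred_va - y[n_train:]) ** 2)))
        else:
            self.validation_rmse_ = np.nan
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """District temperatures (n_days, n_districts) from source temps."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_sources_:
            raise ValueError(
                f"expected {self.n_sources_} source series, got shape {X.shape}")
        if np.isnan(X).any():
            raise ValueError("missing source values; fill gaps before predicting")
        return self.bias_[None, :] + X @ self.weights_.T

    def attention(self, district_index: int) -> np.ndarray:
        """Fitted attention weights of one district over the source points."""
        return self.weights_[district_index]

    def downscale_member(self, member_temps: np.ndarray,
                         member_coords: np.ndarray | None = None) -> np.ndarray:
        """Apply the fitted map to one climate-ensemble member (no bias
        correction).

        If ``member_coords`` is given it must match the grid the model was
        fitted on.
        """
        if member_coords is not None:
            Y = np.atleast_2d(np.asarray(self.source_coords, dtype=float))
            mc = np.atleast_2d(np.asarray(member_coords, dtype=float))
            if mc.shape != Y.shape or not np.allclose(mc, Y):
                raise ValueError("member grid does not match the grid the "
                                 "interpolator was fitted on")
        return self.predict(member_temps)


def fill_gaps_mean_adjusted(primary: pd.DataFrame,
                            secondary: pd.DataFrame) -> pd.DataFrame:
    """Fill missing primary values from a secondary source after removing the
    overlapping-period mean difference.

    Both frames are (time x series) aligned on columns; for each series the
    mean difference primary - secondary over jointly observed days is added
    to the secondary values before substitution.
    """
    primary = primary.copy()
    for col in primary.columns:
        p = primary[col]
        s = secondary[col]
        missing = p.isna()
        if not missing.any():
            continue
        overlap = (~p.isna()) & (~s.isna())
        if not overlap.any():
            raise ValueError(f"no overlap between primary and secondary for {col!r}")
        offset = float((p[overlap] - s[overlap]).mean())
        primary.loc[missing, col] = s[missing] + offset
    return primary
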