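"""Per-cluster seasonal SARIMA models on artificially concatenated PP series.

Each cluster's postprandial periods are concatenated as
``[5 presamples | 48 window samples]`` blocks, which imposes an artificial
seasonality of S = 53 samples (the periodic meal consumption becomes the
season).  A SARIMA(p,d,q)(P,D,Q)_S model is then identified per cluster by
exhaustive BIC grid search.  Estimation runs through the statsmodels
state-space machinery, so missing entries are handled by the Kalman filter
as genuinely unobserved — never imputed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.statespace.sarimax import SARIMAX

logger = logging.getLogger(__name__)

SEASONALITY = 53  # 48 window samples + 5 presamples


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SeasonalModelSpec:
    """A fitted (or failed) SARIMA model for one cluster.

    ``params`` is the full parameter vector in estimation order (trend, AR,
    MA, seasonal AR, seasonal MA, innovation variance) so the model can be
    re-applied to new histories without re-estimation; the named coefficient
    fields are convenience views of the same vector.
    """

    orders: tuple[int, int, int]
    seasonal_orders: tuple[int, int, int]
    seasonality: int
    ar_coeffs: tuple[float, ...] = ()
    ma_coeffs: tuple[float, ...] = ()
    seasonal_ar: tuple[float, ...] = ()
    seasonal_ma: tuple[float, ...] = ()
    intercept: float = 0.0
    noise_variance: float = float("nan")
    loglik: float = float("nan")
    bic: float = float("inf")
    n_obs: int = 0
    converged: bool = False
    trend: str = "n"
    params: tuple[float, ...] = ()
    param_names: tuple[str, ...] = ()
    std_errors: tuple[float, ...] = ()

    @property
    def n_free_params(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        return {
            "orders": list(self.orders),
            "seasonal_orders": list(self.seasonal_orders),
            "seasonality": self.seasonality,
            "ar_coeffs": list(self.ar_coeffs),
            "ma_coeffs": list(self.ma_coeffs),
            "seasonal_ar": list(self.seasonal_ar),
            "seasonal_ma": list(self.seasonal_ma),
            "intercept": self.intercept,
            "noise_variance": self.noise_variance,
            "loglik": self.loglik,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "trend": self.trend,
            "params": list(self.params),
            "param_names": list(self.param_names),
            "std_errors": list(self.std_errors),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SeasonalModelSpec":
        return cls(
            orders=tuple(payload["orders"]),
            seasonal_orders=tuple(payload["seasonal_orders"]),
            seasonality=payload["seasonality"],
            ar_coeffs=tuple(payload["ar_coeffs"]),
            ma_coeffs=tuple(payload["ma_coeffs"]),
            seasonal_ar=tuple(payload["seasonal_ar"]),
            seasonal_ma=tuple(payload["seasonal_ma"]),
            intercept=payload["intercept"],
            noise_variance=payload["noise_variance"],
            loglik=payload["loglik"],
            bic=payload["bic"],
            n_obs=payload["n_obs"],
            converged=payload["converged"],
            trend=payload["trend"],
            params=tuple(payload["params"]),
            param_names=tuple(payload["param_names"]),
            std_errors=tuple(payload.get("std_errors", ())),
        )


@dataclass(frozen=True)
class SarimaGrid:
    """Identification grid for the seasonal models.

    Defaults: p in 1..4, q in 0..4, d in {0,1}, P in 1..3, Q in 0..3,
    D in {0,1}.
    """

    p_range: tuple[int, ...] = (1, 2, 3, 4)
    q_range: tuple[int, ...] = (0, 1, 2, 3, 4)
    d_range: tuple[int, ...] = (0, 1)
    P_range: tuple[int, ...] = (1, 2, 3)
    Q_range: tuple[int, ...] = (0, 1, 2, 3)
    D_range: tuple[int, ...] = (0, 1)

    def cells(self):
        """Lexicographic (p, d, q, P, D, Q) iteration over the grid."""
        return itertools.product(
            sorted(self.p_range),
            sorted(self.d_range),
            sorted(self.q_range),
            sorted(self.P_range),
            sorted(self.D_range),
            sorted(self.Q_range),
        )


def build_seasonal_series(pps, cluster_set, cluster_index: int) -> np.ndarray:
    """Concatenate a cluster's PPs into the artificial seasonal series.

    PPs hard-assigned (argmax membership, ties to the lowest index) to
    ``cluster_index`` are emitted in the given (chronological) order as
    ``[presamples | window]`` blocks of 53 samples each, preserving missing
    markers.  ``pps`` must be the same profiles, in the same order, that
    produced ``cluster_set.memberships``.
    """
    if len(pps) != cluster_set.memberships.shape[0]:
        raise ModelError("pps and cluster memberships have different lengths")
    assigned = [
        pp
        for pp, hard in zip(pps, cluster_set.hard_assignments())
        if hard == cluster_index
    ]
    if not assigned:
        raise ModelError(f"cluster {cluster_index} has no hard-assigned PPs")
    blocks = [np.concatenate([pp.presamples, pp.window]) for pp in assigned]
    return np.concatenate(blocks)


def _make_model(series: np.ndarray, orders, seasonal_orders, S: int, trend: str):
    p, d, q = orders
    P, D, Q = seasonal_orders
    return SARIMAX(
        np.asarray(series, dtype=float),
        order=(p, d, q),
        seasonal_order=(P, D, Q, S) if (P, D, Q) != (0, 0, 0) else (0, 0, 0, 0),
        trend=trend,
        enforce_stationarity=True,
        enforce_invertibility=True,
    )


def _trend_for(orders, seasonal_orders) -> str:
    # a free intercept is only identified without differencing
    return "c" if orders[1] == 0 and seasonal_orders[1] == 0 else "n"


def _extract_coeffs(names, values, prefix):
    return tuple(float(v) for n, v in zip(names, values) if n.startswith(prefix))


def fit_sarima(
    series: np.ndarray,
    orders: tuple[int, int, int],
    seasonal_orders: tuple[int, int, int],
    S: int = SEASONALITY,
    trend: str | None = None,
    maxiter: int = 100,
) -> SeasonalModelSpec:
    """Maximum-likelihood SARIMA fit via the state-space representation.

    Missing entries are treated as unobserved by the Kalman filter.  A fit
    that fails to converge (or errors numerically) is returned with
    ``converged=False`` and infinite BIC so grid search can skip it instead
    of crashing.  Deterministic given the series and optimizer settings.
    """
    trend = trend if trend is not None else _trend_for(orders, seasonal_orders)
    base = SeasonalModelSpec(
        orders=tuple(orders),
        seasonal_orders=tuple(seasonal_orders),
        seasonality=S,
        trend=trend,
    )
    try:
        model = _make_model(series, orders, seasonal_orders, S, trend)
        if not np.any(np.isnan(np.asarray(series, dtype=float))):
            # Chandrasekhar recursions cut filtering cost sharply for the
            # large state dimensions seasonal models imply; only valid on
            # fully observed series
            model.ssm.filter_chandrasekhar = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=maxiter, method="lbfgs")
        converged = bool(res.mle_retvals.get("converged", True))
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.info("SARIMA %s x %s failed: %s", orders, seasonal_orders, exc)
        return base
    if not converged or not np.isfinite(res.llf):
        logger.info("SARIMA %s x %s did not converge", orders, seasonal_orders)
        return base
    names = list(res.model.param_names)
    values = np.asarray(res.params, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse, dtype=float)
    intercept = next(
        (float(v) for n, v in zip(names, values) if n in ("intercept", "const")), 0.0
    )
    seasonal_ar = _extract_coeffs(names, values, "ar.S.")
    seasonal_ma = _extract_coeffs(names, values, "ma.S.")
    return SeasonalModelSpec(
        orders=tuple(orders),
        seasonal_orders=tuple(seasonal_orders),
        seasonality=S,
        ar_coeffs=tuple(
            float(v)
            for n, v in zip(names, values)
            if n.startswith("ar.") and not n.startswith("ar.S.")
        ),
        ma_coeffs=tuple(
            float(v)
            for n, v in zip(names, values)
            if n.startswith("ma.") and not n.startswith("ma.S.")
        ),
        seasonal_ar=seasonal_ar,
        seasonal_ma=seasonal_ma,
        intercept=intercept,
        noise_variance=float(values[names.index("sigma2")]),
        loglik=float(res.llf),
        bic=float(res.bic),
        n_obs=int(res.nobs),
        converged=True,
        trend=trend,
        params=tuple(values),
        param_names=tuple(names),
        std_errors=tuple(bse),
    )


def select_sarima(
    series: np.ndarray, grid: SarimaGrid | None = None, S: int = SEASONALITY
) -> SeasonalModelSpec:
    """Exhaustive BIC grid search over SARIMA orders.

    Fits every cell of the grid and returns the converged fit with minimal
    BIC; ties break toward the smaller free-parameter count, then the
    lexicographically first cell.
    """
    grid = grid or SarimaGrid()
    best: tuple[tuple, SeasonalModelSpec] | None = None
    for cell in grid.cells():
        p, d, q, P, D, Q = cell
        spec = fit_sarima(series, (p, d, q), (P, D, Q), S=S)
        if not spec.converged:
            continue
        key = (spec.bic, spec.n_free_params, cell)
        if best is None or key < best[0]:
            best = (key, spec)
    if best is None:
        raise ModelError("no SARIMA grid cell converged on this series")
    return best[1]


def sarima_forecast(
    model: SeasonalModelSpec, history: np.ndarray, h: int
) -> np.ndarray:
    """h-step-ahead forecasts conditioning the fitted model on ``history``.

    The Kalman filter runs over the history with missing entries skipped
    (treated as unobserved); no re-estimation happens.  An empty or
    all-missing history yields the model's unconditional forecast.
    """
    if h < 1:
        raise ModelError("forecast horizon must be >= 1")
    if not model.converged:
        raise ModelError("cannot forecast with a non-converged model")
    history = np.asarray(history, dtype=float)
    if history.size == 0 or np.all(np.isnan(history)):
        logger.warning("forecasting from an empty history: unconditional forecast")
        history = np.full(max(history.size, 1), np.nan)
    mod = _make_model(
        history, model.orders, model.seasonal_orders, model.seasonality, model.trend
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.filter(np.asarray(model.params))
        return np.asarray(res.forecast(h), dtype=float)


def apply_model(model: SeasonalModelSpec, series: np.ndarray, exog=None):
    """Kalman-filter a fitted model over a new series without re-estimating.

    Returns the statsmodels results object (for batched forecasting via
    :func:`multi_step_forecasts`).
    """
    mod = _make_model(
        np.asarray(series, dtype=float),
        model.orders,
        model.seasonal_orders,
        model.seasonality,
        model.trend,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mod.filter(np.asarray(model.params))


def multi_step_forecasts(res, h: int) -> np.ndarray:
    """All h-step-ahead forecasts from every origin of a filtered model.

    Returns an array ``F`` of shape (nobs, h) with
    ``F[t, j-1] = E[y_{t+j} | y_0..y_t]`` computed by propagating the
    predicted state through the transition equation — one Kalman pass total
    instead of one per origin.  Entries whose step lands beyond the sample
    are NaN when the model has time-varying observation intercepts (exogenous
    regressors), since the future intercept is unknown there.
    """
    fr = res.filter_results
    nobs = fr.nobs
    Z = fr.design[0, :, 0]  # time-invariant for (S)ARIMA(X)
    T = fr.transition[:, :, 0]
    c = fr.state_intercept
    c_tv = c.shape[1] > 1
    d = fr.obs_intercept
    d_tv = d.shape[1] > 1
    A = fr.predicted_state[:, 1 : nobs + 1].copy()  # a(t+1|t), t = 0..nobs-1
    out = np.full((nobs, h), np.nan)
    t_idx = np.arange(nobs)
    for j in range(1, h + 1):
        if d_tv:
            valid = t_idx + j <= nobs - 1
            if valid.any():
                out[valid, j - 1] = d[0, t_idx[valid] + j] + Z @ A[:, valid]
        else:
            out[:, j - 1] = d[0, 0] + Z @ A
        if j < h:
            step_c = c[:, :1] if not c_tv else np.pad(
                c, ((0, 0), (0, j + 1)), mode="edge"
            )[:, t_idx + j]
            A = step_c + T @ A
    return out
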