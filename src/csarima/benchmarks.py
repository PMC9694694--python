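"""Individualized ARIMA (CGM-only) and ARIMAX (CGM + insulin + CHO) comparators.

The benchmarks fit one global-order, per-subject-parameter model on each
subject's whole training trace and forecast through postprandial periods by
conditioning on the full test history up to each time point — unlike
C-SARIMA, they are not reset at mealtime.  Exogenous inputs are encoded as
raw impulses (the logged amount at the event's grid slot) with basal insulin
spread as IU per slot; lag polynomials of order X are applied to both inputs.
Forecasts inside a horizon use the logged future exogenous values — meal and
bolus amounts are announced at mealtime, an information advantage the ARIMAX
is allowed by construction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .forecaster import evaluable_origins, pp_target
from .io_segmentation import EventLog, GlucoseSeries, PostprandialPeriod
from .seasonal_models import multi_step_forecasts

logger = logging.getLogger(__name__)


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class BenchmarkGrid:
    """Order grids for the benchmark identification.

    Defaults: AR 1..20, MA 0..20, I {0,1}, X (exogenous lag order,
    ARIMAX only) 1..20.
    """

    ar_range: tuple[int, ...] = tuple(range(1, 21))
    ma_range: tuple[int, ...] = tuple(range(0, 21))
    i_range: tuple[int, ...] = (0, 1)
    x_range: tuple[int, ...] = tuple(range(1, 21))

    def cells(self, with_exog: bool):
        x_iter = sorted(self.x_range) if with_exog else (0,)
        return itertools.product(
            sorted(self.ar_range), sorted(self.i_range), sorted(self.ma_range), x_iter
        )


@dataclass(frozen=True)
class BenchmarkModelSpec:
    """A fitted individualized ARIMA/ARIMAX comparator."""

    kind: str  # "ARIMA" or "ARIMAX"
    orders: tuple[int, int, int]  # (AR, I, MA)
    exog_lag_order: int  # X; 0 for ARIMA
    params: tuple[float, ...]
    param_names: tuple[str, ...]
    noise_variance: float
    loglik: float
    bic: float
    trend: str
    converged: bool

    def __post_init__(self) -> None:
        if self.kind == "ARIMA" and self.exog_lag_order != 0:
            raise BenchmarkError("ARIMA has no exogenous terms")


def build_exog_signals(
    events: EventLog, grid: GlucoseSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slot CHO (grams) and insulin (IU) sequences aligned to a glucose grid.

    Meals and boluses are impulses: the full logged amount at the event's
    grid slot, zero elsewhere (meals with unknown amount contribute zero).
    Basal records are rate changes: the rate holds from each record to the
    next and is converted to IU per 5-min slot (rate / 12 for hourly rates).
    """
    n = len(grid)
    cho = np.zeros(n)
    insulin = np.zeros(n)
    for meal in events.meals:
        slot = grid.slot_of(meal.time)
        if 0 <= slot < n and meal.cho_grams is not None:
            cho[slot] += meal.cho_grams
    for bolus in events.boluses:
        slot = grid.slot_of(bolus.time)
        if 0 <= slot < n:
            insulin[slot] += bolus.amount
    slots_per_hour = 3600 / grid.sampling_interval.total_seconds()
    basal = sorted(events.basal, key=lambda e: e.time)
    for i, record in enumerate(basal):
        start = max(0, grid.slot_of(record.time))
        end = n if i + 1 == len(basal) else min(n, max(0, grid.slot_of(basal[i + 1].time)))
        if start < end:
            insulin[start:end] += record.amount / slots_per_hour
    return cho, insulin


def lagged_exog_matrix(signals: tuple[np.ndarray, np.ndarray], x_order: int) -> np.ndarray:
    """Distributed-lag design matrix: lags 0..X-1 of each input, leading zeros."""
    if x_order < 1:
        raise BenchmarkError("exogenous lag order X must be >= 1")
    cols = []
    for sig in signals:
        sig = np.asarray(sig, dtype=float)
        for lag in range(x_order):
            col = np.zeros_like(sig)
            if lag == 0:
                col[:] = sig
            else:
                col[lag:] = sig[:-lag]
            cols.append(col)
    return np.column_stack(cols)


def _fit_cell(endog, exog, ar, i, ma, maxiter=100):
    trend = "c" if i == 0 else "n"
    try:
        model = SARIMAX(
            endog,
            exog=exog,
            order=(ar, i, ma),
            trend=trend,
            enforce_stationarity=True,
            enforce_invertibility=True,
        )
        # Chandrasekhar recursions need time-invariant, fully observed systems
        if exog is None and not np.any(np.isnan(np.asarray(endog, dtype=float))):
            model.ssm.filter_chandrasekhar = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=maxiter, method="lbfgs")
        if not bool(res.mle_retvals.get("converged", True)) or not np.isfinite(res.llf):
            return None
        return res
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.info("benchmark (%d,%d,%d) failed: %s", ar, i, ma, exc)
        return None


def _spec_from_results(res, kind, orders, x_order, trend) -> BenchmarkModelSpec:
    names = list(res.model.param_names)
    values = np.asarray(res.params, dtype=float)
    return BenchmarkModelSpec(
        kind=kind,
        orders=orders,
        exog_lag_order=x_order,
        params=tuple(values),
        param_names=tuple(names),
        noise_variance=float(values[names.index("sigma2")]),
        loglik=float(res.llf),
        bic=float(res.bic),
        trend=trend,
        converged=True,
    )


def fit_benchmark(
    train: GlucoseSeries,
    exog: tuple[np.ndarray, np.ndarray] | None = None,
    grid: BenchmarkGrid | None = None,
    orders: tuple[int, int, int] | None = None,
    x_order: int | None = None,
) -> BenchmarkModelSpec:
    """Fit an individualized ARIMA (``exog=None``) or ARIMAX benchmark.

    With ``orders`` (and ``x_order`` for ARIMAX) given, only the subject's
    parameters are estimated at those fixed orders — the second phase of the
    cohort protocol.  Otherwise every grid cell is fit on this subject and
    the minimal-BIC converged cell wins.
    """
    grid = grid or BenchmarkGrid()
    kind = "ARIMA" if exog is None else "ARIMAX"
    endog = np.asarray(train.values, dtype=float)
    if orders is not None:
        x = x_order or 0
        if kind == "ARIMAX" and x < 1:
            raise BenchmarkError("ARIMAX needs x_order >= 1")
        design = lagged_exog_matrix(exog, x) if exog is not None else None
        res = _fit_cell(endog, design, orders[0], orders[1], orders[2])
        if res is None:
            raise BenchmarkError(f"benchmark fit at fixed orders {orders} failed")
        return _spec_from_results(res, kind, tuple(orders), x, "c" if orders[1] == 0 else "n")
    best: tuple[tuple, BenchmarkModelSpec] | None = None
    for ar, i, ma, x in grid.cells(with_exog=exog is not None):
        design = lagged_exog_matrix(exog, x) if exog is not None else None
        res = _fit_cell(endog, design, ar, i, ma)
        if res is None:
            continue
        spec = _spec_from_results(res, kind, (ar, i, ma), x, "c" if i == 0 else "n")
        key = (spec.bic, len(spec.params), (ar, i, ma, x))
        if best is None or key < best[0]:
            best = (key, spec)
    if best is None:
        raise BenchmarkError("no benchmark grid cell converged")
    return best[1]


def select_benchmark_orders(
    trains: list[GlucoseSeries],
    exogs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    grid: BenchmarkGrid | None = None,
) -> tuple[tuple[int, int, int], int]:
    """Cohort phase 1: pick the orders minimizing the summed BIC across subjects.

    Cells where any subject fails to converge are rejected.  Returns
    ``((AR, I, MA), X)`` with X = 0 for the CGM-only model.
    """
    grid = grid or BenchmarkGrid()
    with_exog = exogs is not None
    best: tuple[tuple, tuple] | None = None
    for ar, i, ma, x in grid.cells(with_exog):
        total = 0.0
        n_params = 0
        ok = True
        for s, train in enumerate(trains):
            design = lagged_exog_matrix(exogs[s], x) if with_exog else None
            res = _fit_cell(np.asarray(train.values, dtype=float), design, ar, i, ma)
            if res is None:
                ok = False
                break
            total += float(res.bic)
            n_params = len(res.params)
        if not ok:
            continue
        key = (total, n_params, (ar, i, ma, x))
        if best is None or key < best[0]:
            best = (key, ((ar, i, ma), x))
    if best is None:
        raise BenchmarkError("no benchmark grid cell converged on every subject")
    return best[1]


def apply_benchmark(
    model: BenchmarkModelSpec,
    series: GlucoseSeries,
    exog: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Kalman-filter a fitted benchmark over a (test) series without re-estimating."""
    design = (
        lagged_exog_matrix(exog, model.exog_lag_order) if exog is not None else None
    )
    mod = SARIMAX(
        np.asarray(series.values, dtype=float),
        exog=design,
        order=model.orders,
        trend=model.trend,
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mod.filter(np.asarray(model.params))


def predict_pp_benchmark(
    model: BenchmarkModelSpec,
    test_series: GlucoseSeries,
    pp: PostprandialPeriod,
    ph_minutes=(30, 45, 60, 75),
    exog: tuple[np.ndarray, np.ndarray] | None = None,
    burn_in: int = 3,
    _filtered=None,
) -> dict[int, list[tuple[int, float, float]]]:
    """Benchmark forecasts through one PP, paired exactly like the C-SARIMA.

    The model conditions on the full test-series history up to each origin
    inside the PP (benchmarks are not meal-reset); pairing of predictions
    with targets reuses the shared :func:`forecaster.evaluable_origins` /
    :func:`forecaster.pp_target` logic.  Pass ``_filtered`` (from
    :func:`apply_benchmark`) to reuse one Kalman pass across many PPs.
    """
    sampling = int(test_series.sampling_interval.total_seconds() // 60)
    ph_minutes = tuple(int(ph) for ph in ph_minutes)
    steps = []
    for ph in ph_minutes:
        if ph <= 0 or ph % sampling != 0:
            raise BenchmarkError(f"horizon {ph} not a multiple of {sampling} min")
        steps.append(ph // sampling)
    if not steps:
        return {}
    res = _filtered if _filtered is not None else apply_benchmark(model, test_series, exog)
    forecasts = multi_step_forecasts(res, max(steps))
    g0 = test_series.slot_of(pp.source_span[0])
    out: dict[int, list[tuple[int, float, float]]] = {ph: [] for ph in ph_minutes}
    for t in evaluable_origins(pp, burn_in):
        origin = g0 + t - 1
        if not 0 <= origin < forecasts.shape[0]:
            continue
        for ph, step_n in zip(ph_minutes, steps):
            y_hat = float(forecasts[origin, step_n - 1])
            out[ph].append((t, y_hat, pp_target(pp, t, step_n)))
    return out
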