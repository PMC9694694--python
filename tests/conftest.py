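import numpy as np
import pandas as pd
import pytest

from csarima.io_segmentation import EventLog, GlucoseSeries, MealEvent
from csarima.seasonal_models import SeasonalModelSpec

T0 = pd.Timestamp("2021-03-01T08:00:00")


def make_series(values, start=T0, mask=None):
    """GlucoseSeries from a value list; NaN entries are marked missing."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    return GlucoseSeries(start_time=start, values=values, missing_mask=np.asarray(mask, bool))


def make_meals(*timestamps):
    return EventLog(meals=tuple(MealEvent(pd.Timestamp(t), 50.0, "meal") for t in timestamps))


def ar1_spec(phi: float, intercept: float = 0.0, sigma2: float = 1.0) -> SeasonalModelSpec:
    """Hand-built AR(1) model spec (no estimation) for closed-form forecast checks."""
    return SeasonalModelSpec(
        orders=(1, 0, 0),
        seasonal_orders=(0, 0, 0),
        seasonality=53,
        ar_coeffs=(phi,),
        intercept=intercept,
        noise_variance=sigma2,
        converged=True,
        trend="c",
        params=(intercept, phi, sigma2),
        param_names=("intercept", "ar.L1", "sigma2"),
    )


def random_walk_spec(sigma2: float = 1.0) -> SeasonalModelSpec:
    return SeasonalModelSpec(
        orders=(0, 1, 0),
        seasonal_orders=(0, 0, 0),
        seasonality=53,
        noise_variance=sigma2,
        converged=True,
        trend="n",
        params=(sigma2,),
        param_names=("sigma2",),
    )


def simulate_sarima_110(n, phi, seasonal_phi, S, sd=1.0, seed=0, mean=0.0):
    """Simulate y_t = mean + x_t with (1 - phi B)(1 - Phi B^S) x_t = eps_t."""
    rng = np.random.default_rng(seed)
    burn = 5 * S
    x = np.zeros(n + burn)
    eps = rng.normal(0, sd, n + burn)
    for t in range(n + burn):
        x[t] = eps[t]
        if t >= 1:
            x[t] += phi * x[t - 1]
        if t >= S:
            x[t] += seasonal_phi * x[t - S]
        if t >= S + 1:
            x[t] -= phi * seasonal_phi * x[t - S - 1]
    return mean + x[burn:]


@pytest.fixture(scope="session")
def flat_series():
    """Fully observed constant-ish series spanning one morning."""
    return make_series(np.full(60, 120.0))
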