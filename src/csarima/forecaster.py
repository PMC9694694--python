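"""Real-time C-SARIMA forecasting: burn-in, membership weighting, weighted output.

Forecasting is triggered at mealtime.  After a burn-in of 3 observed post-meal
samples, each new CGM sample updates (i) the membership weights of the
partially observed window against the fitted cluster prototypes and (ii) each
cluster's local SARIMA forecast; the emitted prediction at every horizon is
the membership-weighted sum of the local forecasts.  Each local model
conditions on its cluster's concatenated training series followed by
``presamples | prefix`` — the current period enters as the next season of
the cluster's artificial seasonal series, so the seasonal lags are informed.
Test periods are never chained to each other: every meal opens a fresh
session.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .clustering import ClusterSet, score_membership
from .io_segmentation import PP_PRESAMPLES, PP_WINDOW_SAMPLES, PostprandialPeriod
from .seasonal_models import (
    SeasonalModelSpec,
    apply_model,
    multi_step_forecasts,
    sarima_forecast,
)

logger = logging.getLogger(__name__)

BURN_IN_SAMPLES = 3
DEFAULT_PH_MINUTES = (30, 45, 60, 75)


class ForecastError(ValueError):
    pass


@dataclass(frozen=True)
class ModelBundle:
    """A fitted C-SARIMA forecaster: cluster prototypes plus one SARIMA per cluster.

    ``contexts`` holds each cluster's concatenated training series.  At
    prediction time a new postprandial period is appended to its cluster's
    context as the next season, so the seasonal lags of the local model see
    the cluster's past periods; without a context the model conditions on the
    presamples and prefix alone and its seasonal terms stay at their
    stationary prior.
    """

    cluster_set: ClusterSet
    models: tuple[SeasonalModelSpec, ...]
    sampling_minutes: int = 5
    burn_in: int = BURN_IN_SAMPLES
    contexts: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.models) != self.cluster_set.n_clusters:
            raise ForecastError("need exactly one model per cluster")
        if self.contexts is not None and len(self.contexts) != len(self.models):
            raise ForecastError("need exactly one training context per cluster")

    def context_for(self, cluster: int) -> np.ndarray:
        if self.contexts is None:
            return np.empty(0)
        return np.asarray(self.contexts[cluster], dtype=float)

    def save(self, path) -> None:
        payload = {
            "sampling_minutes": self.sampling_minutes,
            "burn_in": self.burn_in,
            "contexts": None
            if self.contexts is None
            else [np.asarray(c, dtype=float).tolist() for c in self.contexts],
            "cluster_set": {
                "n_clusters": self.cluster_set.n_clusters,
                "fuzzifier": self.cluster_set.fuzzifier,
                "prototypes": self.cluster_set.prototypes.tolist(),
                "validity": self.cluster_set.validity,
                "seed": self.cluster_set.seed,
            },
            "models": [m.to_dict() for m in self.models],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            payload = json.load(fh)
        cs = payload["cluster_set"]
        prototypes = np.asarray(cs["prototypes"], dtype=float)
        cluster_set = ClusterSet(
            n_clusters=cs["n_clusters"],
            fuzzifier=cs["fuzzifier"],
            prototypes=prototypes,
            memberships=np.zeros((0, cs["n_clusters"])),
            objective_history=(),
            validity=cs["validity"],
            seed=cs["seed"],
        )
        models = tuple(SeasonalModelSpec.from_dict(m) for m in payload["models"])
        raw_contexts = payload.get("contexts")
        return cls(
            cluster_set=cluster_set,
            models=models,
            sampling_minutes=payload["sampling_minutes"],
            burn_in=payload["burn_in"],
            contexts=None
            if raw_contexts is None
            else tuple(np.asarray(c, dtype=float) for c in raw_contexts),
        )


@dataclass(frozen=True)
class ForecastState:
    """Rolling state of the real-time loop inside one postprandial period."""

    bundle: ModelBundle
    presamples: np.ndarray  # 5 values, NaN where missing
    ph_steps: tuple[int, ...]
    ph_minutes: tuple[int, ...]
    prefix: tuple[float, ...] = ()  # post-meal window samples seen so far
    samples_since_meal: int = 0  # observed (non-missing) post-meal samples
    weights: np.ndarray | None = None
    local_predictions: np.ndarray | None = None  # (nC, max ph_step)
    output: dict[int, float] | None = None  # ph_minutes -> weighted prediction

    @property
    def slot(self) -> int:
        """Number of post-meal grid slots consumed (1-based index of the last one)."""
        return len(self.prefix)

    @property
    def closed(self) -> bool:
        return len(self.prefix) >= PP_WINDOW_SAMPLES


def _validate_ph(ph_minutes, sampling_minutes: int) -> tuple[int, ...]:
    steps = []
    for ph in ph_minutes:
        if ph <= 0 or ph % sampling_minutes != 0:
            raise ForecastError(
                f"prediction horizon {ph} min is not a positive multiple of the "
                f"{sampling_minutes}-min sampling interval"
            )
        steps.append(ph // sampling_minutes)
    return tuple(steps)


def start_pp(
    presamples: np.ndarray,
    cluster_models: ModelBundle,
    ph_minutes=DEFAULT_PH_MINUTES,
) -> ForecastState:
    """Open a postprandial forecasting session at mealtime.

    The 5 pre-meal samples seed every local model's history; no output is
    produced until the burn-in completes.
    """
    presamples = np.asarray(presamples, dtype=float)
    if presamples.shape != (PP_PRESAMPLES,):
        raise ForecastError(f"expected {PP_PRESAMPLES} presamples")
    ph_minutes = tuple(int(ph) for ph in ph_minutes)
    steps = _validate_ph(ph_minutes, cluster_models.sampling_minutes)
    return ForecastState(
        bundle=cluster_models,
        presamples=presamples,
        ph_steps=steps,
        ph_minutes=ph_minutes,
    )


def _weighted_output(
    weights: np.ndarray, local: np.ndarray, ph_minutes, ph_steps
) -> dict[int, float]:
    return {
        ph: float(weights @ local[:, step - 1])
        for ph, step in zip(ph_minutes, ph_steps)
    }


def step(state: ForecastState, new_sample: float) -> ForecastState:
    """Consume one new CGM sample (NaN = missing) and update the forecast.

    Membership weights are recomputed from the observed prefix on every
    observed sample and frozen across missing ones; local forecasts always
    condition on the full ``presamples | prefix`` history with missing slots
    left unobserved.  No output before the 3rd observed post-meal sample.
    """
    if state.closed:
        raise ForecastError("postprandial window exhausted (48 slots consumed)")
    value = float(new_sample) if new_sample is not None else float("nan")
    prefix = state.prefix + (value,)
    observed = state.samples_since_meal + (0 if np.isnan(value) else 1)
    if observed < state.bundle.burn_in:
        return replace(
            state,
            prefix=prefix,
            samples_since_meal=observed,
            weights=state.weights,
            local_predictions=None,
            output=None,
        )
    if np.isnan(value) and state.weights is not None:
        weights = state.weights  # frozen across a missing sample
    else:
        padded = np.full(PP_WINDOW_SAMPLES, np.nan)
        padded[: len(prefix)] = prefix
        weights = score_membership(padded, state.bundle.cluster_set)
    history = np.concatenate([state.presamples, prefix])
    if not state.ph_steps:
        return replace(
            state,
            prefix=prefix,
            samples_since_meal=observed,
            weights=weights,
            local_predictions=None,
            output={},
        )
    h = max(state.ph_steps)
    local = np.vstack(
        [
            sarima_forecast(
                m, np.concatenate([state.bundle.context_for(i), history]), h
            )
            for i, m in enumerate(state.bundle.models)
        ]
    )
    output = _weighted_output(weights, local, state.ph_minutes, state.ph_steps)
    return replace(
        state,
        prefix=prefix,
        samples_since_meal=observed,
        weights=weights,
        local_predictions=local,
        output=output,
    )


def evaluable_origins(pp: PostprandialPeriod, burn_in: int = BURN_IN_SAMPLES) -> list[int]:
    """1-based window slots at which a forecast is emitted for this PP.

    The burn-in counts *observed* post-meal samples, so missing slots extend
    the wait; once reached, every subsequent slot (observed or missing)
    carries an output.  Shared by the C-SARIMA forecaster and the ARIMA/
    ARIMAX benchmarks so all methods are paired identically.
    """
    origins = []
    observed = 0
    for t in range(1, pp.observed_length + 1):
        if not np.isnan(pp.window[t - 1]):
            observed += 1
        if observed >= burn_in:
            origins.append(t)
    return origins


def pp_target(pp: PostprandialPeriod, t: int, step_n: int) -> float:
    """Observed target for a forecast issued at slot ``t`` over ``step_n`` steps.

    NaN when the target slot is missing, padded, or beyond the 48-slot window
    — such predictions are excluded from evaluation pairs.
    """
    target_slot = t + step_n
    if target_slot <= pp.observed_length and not np.isnan(pp.window[target_slot - 1]):
        return float(pp.window[target_slot - 1])
    return float("nan")


def predict_pp(
    pp: PostprandialPeriod,
    bundle: ModelBundle,
    ph_minutes=DEFAULT_PH_MINUTES,
) -> dict[int, list[tuple[int, float, float]]]:
    """Replay the real-time loop over a PP and pair predictions with targets.

    Returns, per horizon, a list of ``(t, y_hat, target)`` tuples where ``t``
    is the 1-based post-meal slot at which the forecast was issued and
    ``target`` is the observed window value at slot ``t + ph_step`` — NaN when
    that slot is missing, padded, or beyond the window, in which case the
    tuple is excluded from evaluation pairs by :func:`evaluation.rmse_pp`
    callers (use :func:`prediction_pairs`).

    Local forecasts are computed with a single Kalman pass per cluster over
    ``context | presamples | window`` — the filter is causal, so the
    forecasts from origin ``t`` match the incremental :func:`step` loop
    exactly.
    """
    ph_minutes = tuple(int(ph) for ph in ph_minutes)
    ph_steps = _validate_ph(ph_minutes, bundle.sampling_minutes)
    if not ph_steps:
        return {}
    h = max(ph_steps)
    n_obs_region = pp.observed_length
    session = np.concatenate([pp.presamples, pp.window[:n_obs_region]])
    # one filter pass per cluster over (training context | presamples | window);
    # forecasts from every origin at once.  Origin index of window slot t
    # (1-based) is len(context) + presamples + t - 1.
    all_forecasts = []
    offsets = []
    for i, model in enumerate(bundle.models):
        context = bundle.context_for(i)
        res = apply_model(model, np.concatenate([context, session]))
        all_forecasts.append(multi_step_forecasts(res, h))
        offsets.append(len(context) + PP_PRESAMPLES)
    out: dict[int, list[tuple[int, float, float]]] = {ph: [] for ph in ph_minutes}
    weights: np.ndarray | None = None
    for t in evaluable_origins(pp, bundle.burn_in):
        value = pp.window[t - 1]
        if np.isnan(value) and weights is not None:
            pass  # weights frozen across the missing sample
        else:
            padded = np.full(PP_WINDOW_SAMPLES, np.nan)
            padded[:t] = pp.window[:t]
            weights = score_membership(padded, bundle.cluster_set)
        for ph, step_n in zip(ph_minutes, ph_steps):
            local = np.array(
                [
                    f[offset + t - 1, step_n - 1]
                    for f, offset in zip(all_forecasts, offsets)
                ]
            )
            y_hat = float(weights @ local)
            out[ph].append((t, y_hat, pp_target(pp, t, step_n)))
    return out


def prediction_pairs(
    trajectories: dict[int, list[tuple[int, float, float]]]
) -> dict[int, list[tuple[float, float]]]:
    """Extract the (target, prediction) evaluation pairs per horizon."""
    return {
        ph: [
            (target, y_hat)
            for _, y_hat, target in rows
            if not (np.isnan(target) or np.isnan(y_hat))
        ]
        for ph, rows in trajectories.items()
    }
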