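"""Seeded generator of realistic multi-week CGM traces and labeled PP sets.

The generator emulates the structure of free-living CGM studies: weeks of
5-minute samples with a circadian baseline, meal-triggered glucose excursions
drawn from a small set of archetype response shapes, AR(1) sensor noise, and
missing-data gaps from a seeded point process.  It is the test bed for every
pipeline stage — real clinical traces (which it stands in for) additionally
carry exercise effects, sensor drift and compression artifacts that the
generator does not attempt.

Meal responses use a gamma-density-shaped curve: smooth, unimodal, with
independent control of rise time and decay — adequate to span the range of
postprandial excursions without claiming physiological fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_segmentation import (
    PP_WINDOW_SAMPLES,
    EventLog,
    GlucoseSeries,
    InsulinEvent,
    MealEvent,
)

SLOTS_PER_DAY = 288  # 5-min grid

#: archetype (peak rise mg/dL, time-to-peak min, decay time min) triples:
#: a fast-spiking meal, a moderate mixed meal, and a slow flat response.
DEFAULT_ARCHETYPES = (
    (140.0, 45.0, 70.0),
    (80.0, 60.0, 110.0),
    (45.0, 90.0, 160.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic subject.

    Defaults mirror an 8-week open-loop monitoring study: 5-min sampling,
    three daily meals with half-hour timing jitter, ~12% missing data in
    multi-sample gaps, and moderate sensor noise.
    """

    days: int = 56
    archetype_params: tuple[tuple[float, float, float], ...] = DEFAULT_ARCHETYPES
    baseline_mean: float = 120.0  # mg/dL
    circadian_amplitude: float = 15.0  # mg/dL, dawn-phenomenon scale
    noise_sd: float = 5.0  # mg/dL stationary sensor noise sd
    noise_ar1: float = 0.6  # lag-1 autocorrelation of sensor noise
    missing_rate: float = 0.12  # target missing fraction
    gap_length_mean: float = 4.0  # mean gap length, samples (geometric)
    meal_times_hours: tuple[float, ...] = (7.5, 12.5, 19.0)
    meal_jitter_sd_min: float = 30.0
    start_time: str = "2021-01-04T00:00:00"
    seed: int = 0

    @property
    def n_archetypes(self) -> int:
        return len(self.archetype_params)

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("need at least one archetype")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not -1 < self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in (-1, 1)")


def meal_response_curve(
    minutes: np.ndarray, peak: float, time_to_peak: float, decay: float
) -> np.ndarray:
    """Gamma-density-shaped postprandial excursion, normalized to ``peak`` at its mode."""
    theta = decay / 3.0
    k = 1.0 + time_to_peak / theta
    tau = np.maximum(np.asarray(minutes, dtype=float), 0.0) / theta
    mode = time_to_peak / theta
    with np.errstate(divide="ignore", invalid="ignore"):
        log_f = (k - 1) * np.log(tau) - tau
        log_mode = (k - 1) * np.log(mode) - mode
        curve = np.exp(log_f - log_mode)
    curve[np.asarray(minutes) < 0] = 0.0
    curve[~np.isfinite(curve)] = 0.0
    return peak * curve


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1 - rho**2)
    e = np.empty(n)
    e[0] = rng.normal(0, sd)
    shocks = rng.normal(0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + shocks[t - 1]
    return e


def generate_subject(
    config: SimConfig,
) -> tuple[GlucoseSeries, EventLog, list[int]]:
    """Simulate one monitored subject: trace, event log, and per-meal archetype labels.

    Glucose = circadian baseline + superposed archetype meal responses +
    AR(1) sensor noise, clipped to the 40–400 mg/dL device range.  Missing
    gaps are placed by a seeded point process with geometric lengths; meal
    anchor slots are protected so every logged meal has a grid slot.  CHO is
    logged proportional to the archetype's peak rise; each meal gets a bolus
    and a constant basal rate runs throughout.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.days * SLOTS_PER_DAY
    start = pd.Timestamp(config.start_time)
    t_min = np.arange(n) * 5.0  # minutes since start
    hour_of_day = (t_min / 60.0) % 24.0
    # circadian term: trough near 03:00, dawn rise toward 09:00
    circadian = config.circadian_amplitude * np.sin(
        2 * np.pi * (hour_of_day - 9.0) / 24.0
    )
    glucose = config.baseline_mean + circadian

    meal_slots: list[int] = []
    labels: list[int] = []
    meals: list[MealEvent] = []
    boluses: list[InsulinEvent] = []
    for day in range(config.days):
        for meal_hour in config.meal_times_hours:
            jitter = rng.normal(0, config.meal_jitter_sd_min)
            minute = day * 1440 + meal_hour * 60 + jitter
            slot = int(round(minute / 5.0))
            if not 0 <= slot < n:
                continue
            arch = int(rng.integers(config.n_archetypes))
            peak, ttp, decay = config.archetype_params[arch]
            horizon = min(n - slot, SLOTS_PER_DAY)  # responses die off within a day
            rel_min = np.arange(horizon) * 5.0
            glucose[slot : slot + horizon] += meal_response_curve(
                rel_min, peak, ttp, decay
            )
            when = start + pd.Timedelta(minutes=5 * slot)
            cho = float(round(0.6 * peak))
            meal_slots.append(slot)
            labels.append(arch)
            meals.append(MealEvent(when, cho, "meal"))
            boluses.append(InsulinEvent(when, round(cho / 10.0, 1)))

    glucose += _ar1_noise(rng, n, config.noise_sd, config.noise_ar1)
    np.clip(glucose, 40.0, 400.0, out=glucose)

    mask = np.zeros(n, dtype=bool)
    if config.missing_rate > 0:
        p_start = config.missing_rate / config.gap_length_mean
        p_geom = 1.0 / config.gap_length_mean
        protected = np.zeros(n, dtype=bool)
        protected[meal_slots] = True
        t = 0
        while t < n:
            if rng.random() < p_start:
                length = int(rng.geometric(p_geom))
                for k in range(t, min(n, t + length)):
                    if not protected[k]:
                        mask[k] = True
                t += length
            else:
                t += 1
    values = glucose.copy()
    values[mask] = np.nan

    series = GlucoseSeries(
        start_time=start, values=values, missing_mask=mask
    )
    basal = (InsulinEvent(start, 1.0),)  # flat 1 IU/h throughout
    events = EventLog(tuple(meals), tuple(boluses), basal)
    return series, events, labels


def generate_pp_set(
    K: int,
    n_per_cluster: int,
    noise_sd: float,
    seed: int = 0,
    truncate_frac: float = 0.0,
    baseline: float = 120.0,
    archetype_params: tuple[tuple[float, float, float], ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 48-sample PP windows for cluster-recovery experiments.

    Each profile is an archetype curve sampled on the 48-slot grid plus
    i.i.d. Gaussian noise; a ``truncate_frac`` fraction of profiles is
    NaN-padded from a random cut point in [12, 48) to mimic early-next-meal
    padding.  Returns ``(X, labels)`` with ``X`` of shape (K*n_per_cluster, 48).
    """
    if K < 2:
        raise ValueError("need at least two archetypes")
    params = archetype_params or _spread_archetypes(K)
    if len(params) < K:
        raise ValueError(f"need {K} archetype parameter triples")
    rng = np.random.default_rng(seed)
    rel_min = (np.arange(PP_WINDOW_SAMPLES) + 1) * 5.0
    curves = np.stack(
        [baseline + meal_response_curve(rel_min, *params[k]) for k in range(K)]
    )
    labels = np.repeat(np.arange(K), n_per_cluster)
    rng.shuffle(labels)
    X = curves[labels] + rng.normal(0, noise_sd, size=(labels.size, PP_WINDOW_SAMPLES))
    if truncate_frac > 0:
        n_trunc = int(round(truncate_frac * labels.size))
        idx = rng.choice(labels.size, size=n_trunc, replace=False)
        for j in idx:
            cut = int(rng.integers(12, PP_WINDOW_SAMPLES))
            X[j, cut:] = np.nan
    return X, labels


def _spread_archetypes(K: int) -> tuple[tuple[float, float, float], ...]:
    """K well-spread archetype triples covering fast/high to slow/flat responses."""
    peaks = np.linspace(140.0, 40.0, K)
    ttps = np.linspace(40.0, 100.0, K)
    decays = np.linspace(70.0, 170.0, K)
    return tuple((float(p), float(t), float(d)) for p, t, d in zip(peaks, ttps, decays))
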