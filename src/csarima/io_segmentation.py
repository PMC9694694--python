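"""CGM input/output, gap imputation, train/test splitting and postprandial segmentation.

Glucose traces live on a uniform 5-minute grid anchored at clock multiples of
the sampling interval.  Missing samples are explicit: ``values`` carries NaN
wherever ``missing_mask`` is True, and all downstream stages treat those slots
as unobserved rather than imputed (except the short-gap interpolation applied
to training data only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default CGM sampling interval
SAMPLING_INTERVAL = pd.Timedelta(minutes=5)
#: postprandial window length, samples (4 h at 5 min)
PP_WINDOW_SAMPLES = 48
#: pre-meal samples used for model initialization
PP_PRESAMPLES = 5
#: a PP with more missing samples than this in its observed region is discarded
MAX_MISSING_PP = 18


class ValidationError(ValueError):
    """Input violates a structural precondition."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending row."""


@dataclass(frozen=True)
class GlucoseSeries:
    """A uniformly sampled glucose trace with an explicit missing mask.

    Sample ``k`` sits at ``start_time + k * sampling_interval``; glucose is
    in mg/dL and NaN wherever the mask marks a slot missing.
    """

    start_time: pd.Timestamp
    values: np.ndarray
    missing_mask: np.ndarray
    sampling_interval: pd.Timedelta = SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if values.shape != mask.shape or values.ndim != 1:
            raise ValidationError(
                "values and missing_mask must be 1-D and of equal length"
            )
        observed = values[~mask]
        if not np.all(np.isfinite(observed)) or np.any(observed <= 0):
            raise ValidationError("non-missing glucose must be finite and > 0")
        if np.any(~np.isnan(values[mask])):
            values = values.copy()
            values[mask] = np.nan
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=self.sampling_interval
        )

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + (len(self) - 1) * self.sampling_interval

    def slot_of(self, timestamp: pd.Timestamp) -> int:
        """Grid slot index of ``timestamp`` (nearest slot, ties to the earlier one)."""
        return snap_to_grid(timestamp, self.sampling_interval) - snap_to_grid(
            self.start_time, self.sampling_interval
        )


@dataclass(frozen=True)
class MealEvent:
    time: pd.Timestamp
    cho_grams: float | None = None
    label: str = ""


@dataclass(frozen=True)
class InsulinEvent:
    time: pd.Timestamp
    amount: float  # IU for boluses, IU/h for basal rate records


@dataclass(frozen=True)
class EventLog:
    """Self-reported meals plus insulin boluses and basal-rate records."""

    meals: tuple[MealEvent, ...] = ()
    boluses: tuple[InsulinEvent, ...] = ()
    basal: tuple[InsulinEvent, ...] = ()

    def __post_init__(self) -> None:
        for name in ("meals", "boluses", "basal"):
            events = getattr(self, name)
            times = [e.time for e in events]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValidationError(f"{name} timestamps must be sorted ascending")
        for meal in self.meals:
            if meal.cho_grams is not None and meal.cho_grams < 0:
                raise ValidationError("meal CHO amounts must be non-negative")
        for ev in self.boluses + self.basal:
            if ev.amount < 0:
                raise ValidationError("insulin amounts must be non-negative")

    def between(self, start: pd.Timestamp, end: pd.Timestamp) -> "EventLog":
        """Events with start <= time < end."""

        def keep(events):
            return tuple(e for e in events if start <= e.time < end)

        return EventLog(keep(self.meals), keep(self.boluses), keep(self.basal))


@dataclass(frozen=True)
class PostprandialPeriod:
    """A 48-sample post-meal window, NaN-padded, plus the 5 pre-meal samples.

    ``observed_length`` counts the grid slots genuinely belonging to this PP
    (up to the next meal); positions at and beyond it are structural padding,
    always marked missing.  Missing entries *inside* the observed region are
    sensor dropouts.
    """

    meal_index: int
    window: np.ndarray
    presamples: np.ndarray
    observed_length: int
    source_span: tuple[pd.Timestamp, pd.Timestamp]
    meal: MealEvent | None = None

    def __post_init__(self) -> None:
        window = np.asarray(self.window, dtype=float)
        pres = np.asarray(self.presamples, dtype=float)
        if window.shape != (PP_WINDOW_SAMPLES,):
            raise ValidationError(f"window must have length {PP_WINDOW_SAMPLES}")
        if pres.shape != (PP_PRESAMPLES,):
            raise ValidationError(f"presamples must have length {PP_PRESAMPLES}")
        if not 1 <= self.observed_length <= PP_WINDOW_SAMPLES:
            raise ValidationError("observed_length must lie in [1, 48]")
        if np.any(~np.isnan(window[self.observed_length :])):
            raise ValidationError("padding positions must be missing")
        object.__setattr__(self, "window", window)
        object.__setattr__(self, "presamples", pres)

    @property
    def n_missing_observed(self) -> int:
        """Sensor-dropout count inside the observed (unpadded) region."""
        return int(np.isnan(self.window[: self.observed_length]).sum())


@dataclass(frozen=True)
class GlycemicSummary:
    """Standard glycemic statistics over the non-missing samples of a trace."""

    cv: float  # coefficient of variation, percent: 100 * sd / mean
    tir: float  # percent of time in 70-180 mg/dL
    tar: float  # percent of time above 180 mg/dL
    tbr: float  # percent of time below 70 mg/dL
    missing_pct: float


def snap_to_grid(
    timestamp: pd.Timestamp, interval: pd.Timedelta = SAMPLING_INTERVAL
) -> int:
    """Absolute grid slot of ``timestamp``: nearest slot, ties toward the earlier one."""
    step = int(interval.total_seconds())
    sec = int(pd.Timestamp(timestamp).value // 1_000_000_000)
    q, r = divmod(sec, step)
    return q + (1 if r > step / 2 else 0)


def _slot_time(slot: int, interval: pd.Timedelta = SAMPLING_INTERVAL) -> pd.Timestamp:
    return pd.Timestamp(slot * int(interval.total_seconds()), unit="s")


def read_cgm_csv(
    path,
    events_path=None,
    sampling_interval: pd.Timedelta = SAMPLING_INTERVAL,
) -> tuple[GlucoseSeries, EventLog]:
    """Read a CGM trace (and optionally an event log) from CSV.

    The CGM file has header ``timestamp,glucose_mg_dl`` with ISO-8601
    timestamps; an empty glucose field marks a missing sample.  Timestamps are
    snapped to the nearest 5-minute grid slot (ties toward the earlier slot),
    duplicate slots keep the last record, and uncovered slots are missing.
    """
    try:
        frame = pd.read_csv(path, dtype={"timestamp": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not read CGM CSV {path}: {exc}") from exc
    if not {"timestamp", "glucose_mg_dl"} <= set(frame.columns):
        raise ParseError(f"{path}: expected columns timestamp,glucose_mg_dl")
    try:
        stamps = pd.to_datetime(frame["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp ({exc})") from exc
    if stamps.isna().any():
        row = int(stamps.isna().idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: unparseable timestamp at line {row}")
    if not stamps.is_monotonic_increasing:
        raise ValidationError(f"{path}: timestamps are not monotone non-decreasing")
    glucose = pd.to_numeric(frame["glucose_mg_dl"], errors="coerce").to_numpy(float)

    slots = np.array([snap_to_grid(t, sampling_interval) for t in stamps])
    first, last = int(slots.min()), int(slots.max())
    n = last - first + 1
    values = np.full(n, np.nan)
    for slot, g in zip(slots, glucose):  # duplicates: keep the last record
        values[slot - first] = g
    mask = np.isnan(values)
    series = GlucoseSeries(
        start_time=_slot_time(first, sampling_interval),
        values=values,
        missing_mask=mask,
        sampling_interval=sampling_interval,
    )
    events = read_events_csv(events_path) if events_path is not None else EventLog()
    return series, events


def read_events_csv(path) -> EventLog:
    """Read an event log CSV with header ``timestamp,kind,amount,label``."""
    frame = pd.read_csv(path, dtype={"timestamp": str, "label": str})
    expected = {"timestamp", "kind", "amount"}
    if not expected <= set(frame.columns):
        raise ParseError(f"{path}: expected columns timestamp,kind,amount[,label]")
    meals: list[MealEvent] = []
    boluses: list[InsulinEvent] = []
    basal: list[InsulinEvent] = []
    for i, row in frame.iterrows():
        try:
            when = pd.Timestamp(row["timestamp"])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: bad timestamp at line {i + 2}") from exc
        amount = pd.to_numeric(row["amount"], errors="coerce")
        kind = str(row["kind"]).strip().lower()
        label = str(row.get("label", "") or "")
        if label == "nan":
            label = ""
        if kind == "meal":
            cho = None if pd.isna(amount) else float(amount)
            meals.append(MealEvent(when, cho, label))
        elif kind == "bolus":
            if pd.isna(amount):
                raise ParseError(f"{path}: bolus without amount at line {i + 2}")
            boluses.append(InsulinEvent(when, float(amount)))
        elif kind == "basal":
            if pd.isna(amount):
                raise ParseError(f"{path}: basal without rate at line {i + 2}")
            basal.append(InsulinEvent(when, float(amount)))
        else:
            raise ParseError(f"{path}: unknown event kind {kind!r} at line {i + 2}")
    return EventLog(
        tuple(sorted(meals, key=lambda e: e.time)),
        tuple(sorted(boluses, key=lambda e: e.time)),
        tuple(sorted(basal, key=lambda e: e.time)),
    )


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    glucose = ["" if m else f"{v:g}" for v, m in zip(series.values, series.missing_mask)]
    pd.DataFrame(
        {"timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%S"), "glucose_mg_dl": glucose}
    ).to_csv(path, index=False)


def write_events_csv(events: EventLog, path) -> None:
    rows = []
    for m in events.meals:
        rows.append((m.time, "meal", "" if m.cho_grams is None else m.cho_grams, m.label))
    for b in events.boluses:
        rows.append((b.time, "bolus", b.amount, ""))
    for b in events.basal:
        rows.append((b.time, "basal", b.amount, ""))
    rows.sort(key=lambda r: r[0])
    pd.DataFrame(
        [(t.strftime("%Y-%m-%dT%H:%M:%S"), k, a, l) for t, k, a, l in rows],
        columns=["timestamp", "kind", "amount", "label"],
    ).to_csv(path, index=False)


def fill_short_gaps(
    series: GlucoseSeries, max_gap: pd.Timedelta = pd.Timedelta(minutes=30)
) -> GlucoseSeries:
    """Linearly interpolate missing runs strictly shorter than ``max_gap``.

    Only interior runs (bounded by observed values on both sides) are filled;
    runs of exactly ``max_gap`` or longer, and runs touching either edge of
    the series, are left untouched.  Intended for training data only — test
    traces are never imputed.
    """
    max_run = int(max_gap / series.sampling_interval)  # strict: fill runs < max_run
    values = series.values.copy()
    mask = series.missing_mask.copy()
    n = len(values)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if interior and run < max_run:
            left, right = values[i - 1], values[j]
            steps = np.arange(1, run + 1)
            values[i:j] = left + (right - left) * steps / (run + 1)
            mask[i:j] = False
        i = j
    return replace(series, values=values, missing_mask=mask)


def segment_postprandial(
    series: GlucoseSeries,
    events: EventLog,
    max_missing: int = MAX_MISSING_PP,
    include_hypo_treatments: bool = True,
) -> list[PostprandialPeriod]:
    """Cut the trace into postprandial periods, one candidate per meal.

    Each window starts at the meal's grid slot and runs 48 samples or until
    the next meal's slot, whichever comes first; shorter windows are NaN-padded
    to 48.  The 5 slots preceding the meal become the presamples.  Candidates
    with more than ``max_missing`` sensor-dropout samples in their observed
    region are discarded.  Padding introduced by an early next meal is
    structural and does not count toward the limit.
    """
    meals = [
        m
        for m in events.meals
        if include_hypo_treatments or "hypo" not in m.label.lower()
    ]
    n = len(series)
    meal_slots = [series.slot_of(m.time) for m in meals]
    periods: list[PostprandialPeriod] = []
    for idx, (meal, slot) in enumerate(zip(meals, meal_slots)):
        if not 0 <= slot < n:
            logger.warning("meal %d at %s outside series span; skipped", idx, meal.time)
            continue
        next_slot = next(
            (s for s in meal_slots[idx + 1 :] if s > slot), slot + PP_WINDOW_SAMPLES
        )
        observed_length = min(PP_WINDOW_SAMPLES, next_slot - slot)
        window = np.full(PP_WINDOW_SAMPLES, np.nan)
        avail = min(observed_length, n - slot)
        window[:avail] = series.values[slot : slot + avail]
        presamples = np.full(PP_PRESAMPLES, np.nan)
        lo = max(0, slot - PP_PRESAMPLES)
        presamples[PP_PRESAMPLES - (slot - lo) :] = series.values[lo:slot]
        n_missing = int(np.isnan(window[:observed_length]).sum())
        if n_missing > max_missing:
            logger.info(
                "PP %d discarded: %d missing samples (> %d)", idx, n_missing, max_missing
            )
            continue
        start = series.start_time + slot * series.sampling_interval
        end = series.start_time + (slot + observed_length - 1) * series.sampling_interval
        periods.append(
            PostprandialPeriod(
                meal_index=idx,
                window=window,
                presamples=presamples,
                observed_length=observed_length,
                source_span=(start, end),
                meal=meal,
            )
        )
    return periods


def split_train_test(
    series: GlucoseSeries, events: EventLog, test_days: int = 10
) -> tuple[tuple[GlucoseSeries, EventLog], tuple[GlucoseSeries, EventLog]]:
    """Split by calendar day: the last ``test_days`` days form the test set."""
    if test_days < 0:
        raise ValidationError("test_days must be non-negative")
    if test_days == 0:
        empty = GlucoseSeries(
            start_time=series.end_time + series.sampling_interval,
            values=np.empty(0),
            missing_mask=np.empty(0, dtype=bool),
            sampling_interval=series.sampling_interval,
        )
        return (series, events), (empty, EventLog())
    dates = series.times.normalize().unique()
    if len(dates) <= test_days:
        raise ValidationError(
            f"series spans {len(dates)} calendar days; need more than {test_days}"
        )
    cutoff = dates[-test_days]
    cut_slot = int(np.searchsorted(series.times, cutoff))

    def sub(lo: int, hi: int) -> GlucoseSeries:
        return GlucoseSeries(
            start_time=series.start_time + lo * series.sampling_interval,
            values=series.values[lo:hi],
            missing_mask=series.missing_mask[lo:hi],
            sampling_interval=series.sampling_interval,
        )

    train = (sub(0, cut_slot), events.between(series.start_time - pd.Timedelta(days=999), cutoff))
    test = (sub(cut_slot, len(series)), events.between(cutoff, series.end_time + series.sampling_interval))
    return train, test


def glycemic_summary(series: GlucoseSeries) -> GlycemicSummary:
    """Coefficient of variation and time-in-range statistics of a trace.

    CV = 100·σ/μ over the non-missing samples; TBR/TIR/TAR are the percent of
    non-missing samples below 70, within [70, 180], and above 180 mg/dL.
    """
    observed = series.values[~series.missing_mask]
    if observed.size == 0:
        raise ValidationError("cannot summarize an all-missing series")
    mean = float(observed.mean())
    sd = float(observed.std(ddof=0))
    n = observed.size
    tbr = 100.0 * np.sum(observed < 70) / n
    tir = 100.0 * np.sum((observed >= 70) & (observed <= 180)) / n
    tar = 100.0 * np.sum(observed > 180) / n
    missing_pct = 100.0 * series.missing_mask.mean() if len(series) else 0.0
    return GlycemicSummary(
        cv=100.0 * sd / mean, tir=tir, tar=tar, tbr=tbr, missing_pct=float(missing_pct)
    )
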