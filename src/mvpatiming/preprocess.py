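"""Epoch-level accelerometer preprocessing.

Turns raw activity-count series into valid-day, hourly-resolution summaries of
moderate-to-vigorous physical activity (MVPA) by applying, in order:

1. nonwear detection on per-minute counts (long zero runs with a short
   low-count interrupt tolerance),
2. sleep scoring on per-minute counts (linear actigraphy score over rolling
   windows, restricted to a configurable overnight span),
3. per-epoch intensity classification against count cutpoints at their native
   epoch length (MVPA = moderate or vigorous),
4. per-day summarisation (wear minutes, MVPA minutes, 24-hour MVPA vector),
5. cohort inclusion rules (minimum daily wear, reactivity trimming of the
   first monitoring days, minimum number of valid days per participant).

All algorithm constants live in :class:`AlgorithmParams`; nothing is
hard-coded, and every exclusion decision is returned in a log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "Cutpoints",
    "SleepParams",
    "AlgorithmParams",
    "DaySummary",
    "minute_counts",
    "detect_nonwear",
    "score_sleep",
    "classify_intensity",
    "summarize_day",
    "apply_inclusion_rules",
    "process_series",
]

INTENSITY_LEVELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class EpochSeries:
    """Timestamped activity counts for one participant-day.

    ``counts`` holds one nonnegative integer per epoch; ``channel`` declares
    whether they are single-axis ("axis1") or vector-magnitude ("vm") counts.
    """

    participant_id: str
    start: pd.Timestamp
    epoch_s: int
    counts: np.ndarray
    channel: str = "vm"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a nonempty 1-d array")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if 60 % self.epoch_s != 0:
            raise ValueError(
                f"epoch_s={self.epoch_s} does not divide 60 s; cannot aggregate to minutes"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "start", pd.Timestamp(self.start))

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def date(self) -> _date:
        return self.start.date()

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_s, unit="s"
        )


@dataclass(frozen=True)
class Cutpoints:
    """Intensity count thresholds at their native epoch length.

    Defaults are wrist vector-magnitude cutpoints for youth on 5 s epochs:
    counts ≥ ``light`` are light, ≥ ``moderate`` moderate, ≥ ``vigorous``
    vigorous; boundary counts go to the higher class.
    """

    light: float = 306.0
    moderate: float = 818.0
    vigorous: float = 1969.0
    native_epoch_s: int = 5
    channel: str = "vm"

    def __post_init__(self) -> None:
        if not (0 <= self.light < self.moderate < self.vigorous):
            raise ValueError("cutpoints must be nonnegative and strictly ordered")

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([self.light, self.moderate, self.vigorous])


@dataclass(frozen=True)
class SleepParams:
    """Weights and threshold of the five-term actigraphy sleep score.

    Per minute, SI = intercept − w_mean·AVG − w_nats·NATS − w_sd·SD − w_log·LG
    where AVG is the mean count over an 11-minute window centred on the scored
    minute, NATS the number of minutes in that window with counts in
    [nats_low, nats_high), SD the standard deviation over the scored minute
    and the 5 preceding minutes, and LG = ln(count+1) of the scored minute.
    A minute is sleep iff SI ≥ threshold.
    """

    intercept: float = 7.601
    w_mean: float = 0.065
    w_nats: float = 1.08
    w_sd: float = 0.056
    w_log: float = 0.703
    threshold: float = 0.0
    nats_low: float = 50.0
    nats_high: float = 100.0
    centered_window_min: int = 11
    trailing_window_min: int = 6
    # Overnight span (start hour, end hour, wrap past midnight) outside of
    # which minutes are never scored sleep; avoids labelling sedentary
    # afternoons as sleep.
    night_start_hour: int = 20
    night_end_hour: int = 10


@dataclass(frozen=True)
class AlgorithmParams:
    """All preprocessing constants: nonwear, sleep, cutpoints, inclusion."""

    nonwear_window_min: int = 60
    nonwear_spike_max: int = 2
    nonwear_spike_ceiling: float = 100.0
    sleep: SleepParams = field(default_factory=SleepParams)
    cutpoints: Cutpoints = field(default_factory=Cutpoints)
    min_wear_min: int = 480
    reactivity_trim_days: int = 3
    min_valid_days: int = 4

    def __post_init__(self) -> None:
        if self.nonwear_window_min <= 0 or self.min_wear_min <= 0:
            raise ValueError("window lengths must be positive")
        if self.nonwear_spike_max < 0 or self.nonwear_spike_ceiling < 0:
            raise ValueError("spike tolerance must be nonnegative")


@dataclass
class DaySummary:
    """Per participant-day wear and MVPA summary at hourly resolution."""

    participant_id: str
    date: _date
    wear_minutes: float
    mvpa_minutes: float
    hourly_mvpa: np.ndarray  # 24 values, minutes of MVPA per clock hour
    hourly_wear: np.ndarray  # 24 values, worn-awake minutes per clock hour
    is_valid: bool
    is_school_day: bool
    trimmed_for_reactivity: bool = False
    # Set by apply_inclusion_rules on surviving days so that re-application
    # does not trim again (makes the inclusion rules idempotent).
    reactivity_screened: bool = False

    def __post_init__(self) -> None:
        self.hourly_mvpa = np.asarray(self.hourly_mvpa, dtype=float)
        self.hourly_wear = np.asarray(self.hourly_wear, dtype=float)
        if self.hourly_mvpa.shape != (24,) or self.hourly_wear.shape != (24,):
            raise ValueError("hourly vectors must have 24 entries")
        if not np.isclose(self.hourly_mvpa.sum(), self.mvpa_minutes, atol=1e-6):
            raise ValueError("hourly_mvpa must sum to mvpa_minutes")
        if not (-1e-9 <= self.mvpa_minutes <= self.wear_minutes + 1e-9 <= 1440 + 1e-9):
            raise ValueError("need 0 <= mvpa_minutes <= wear_minutes <= 1440")
        if np.any(self.hourly_mvpa > 60 + 1e-9) or np.any(self.hourly_mvpa < -1e-9):
            raise ValueError("hourly MVPA cells must lie in [0, 60] minutes")


# ---------------------------------------------------------------------------
# minute aggregation


def minute_counts(series: EpochSeries) -> np.ndarray:
    """Aggregate an epoch series to per-minute counts by summation.

    Trailing epochs that do not fill a whole minute are dropped.
    """
    per_min = 60 // series.epoch_s
    n_min = series.n_epochs // per_min
    return series.counts[: n_min * per_min].reshape(n_min, per_min).sum(axis=1)


# ---------------------------------------------------------------------------
# nonwear


def detect_nonwear(minutes: np.ndarray, params: AlgorithmParams) -> np.ndarray:
    """Flag nonwear minutes in a per-minute count vector.

    A minute is nonwear iff it lies inside some window of at least
    ``nonwear_window_min`` minutes in which every count is zero except for at
    most ``nonwear_spike_max`` interrupt minutes, each with count strictly
    below ``nonwear_spike_ceiling``.

    Any window of length >= W containing a qualifying configuration contains a
    qualifying window of length exactly W, so scanning length-W windows with
    prefix sums is exact.
    """
    minutes = np.asarray(minutes)
    if np.any(minutes < 0):
        raise ValueError("negative counts are invalid")
    n = minutes.size
    w = params.nonwear_window_min
    mask = np.zeros(n, dtype=bool)
    if n < w:
        return mask

    nonzero = (minutes > 0).astype(np.int64)
    too_big = (minutes >= params.nonwear_spike_ceiling).astype(np.int64)
    cs_nz = np.concatenate([[0], np.cumsum(nonzero)])
    cs_big = np.concatenate([[0], np.cumsum(too_big)])

    starts = np.arange(0, n - w + 1)
    n_interrupt = cs_nz[starts + w] - cs_nz[starts]
    n_big = cs_big[starts + w] - cs_big[starts]
    ok = (n_interrupt <= params.nonwear_spike_max) & (n_big == 0)

    # union of qualifying windows via a difference array
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, starts[ok], 1)
    np.add.at(diff, starts[ok] + w, -1)
    mask = np.cumsum(diff[:-1]) > 0
    return mask


# ---------------------------------------------------------------------------
# sleep


def _rolling_sum(padded: np.ndarray, width: int) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(padded, dtype=float)])
    return cs[width:] - cs[:-width]


def score_sleep(
    minutes: np.ndarray,
    params: AlgorithmParams,
    minute_of_day: np.ndarray | None = None,
) -> np.ndarray:
    """Per-minute sleep/wake labels from the five-term linear activity score.

    Edges are padded with zero counts (documented policy).  If
    ``minute_of_day`` (0..1439 per minute) is given, minutes outside the
    configured overnight span are forced to wake regardless of score.
    Returns a boolean mask, True = sleep.
    """
    sp = params.sleep
    minutes = np.asarray(minutes, dtype=float)
    if np.any(minutes < 0):
        raise ValueError("negative counts are invalid")
    n = minutes.size
    if n < sp.centered_window_min:
        raise ValueError(
            f"series of {n} minutes is shorter than the {sp.centered_window_min}-minute scoring window"
        )

    half = sp.centered_window_min // 2
    pad_c = np.concatenate([np.zeros(half), minutes, np.zeros(half)])
    avg = _rolling_sum(pad_c, sp.centered_window_min) / sp.centered_window_min
    in_band = ((pad_c >= sp.nats_low) & (pad_c < sp.nats_high)).astype(float)
    nats = _rolling_sum(in_band, sp.centered_window_min)

    # trailing window: scored minute plus the preceding (trailing_window_min-1)
    tw = sp.trailing_window_min
    pad_t = np.concatenate([np.zeros(tw - 1), minutes])
    s1 = _rolling_sum(pad_t, tw)
    s2 = _rolling_sum(pad_t**2, tw)
    var = np.maximum(s2 / tw - (s1 / tw) ** 2, 0.0)
    sd = np.sqrt(var)

    lg = np.log(minutes + 1.0)
    si = (
        sp.intercept
        - sp.w_mean * avg
        - sp.w_nats * nats
        - sp.w_sd * sd
        - sp.w_log * lg
    )
    sleep = si >= sp.threshold

    if minute_of_day is not None:
        minute_of_day = np.asarray(minute_of_day)
        hour = minute_of_day // 60
        if sp.night_start_hour > sp.night_end_hour:  # wraps midnight
            in_night = (hour >= sp.night_start_hour) | (hour < sp.night_end_hour)
        else:
            in_night = (hour >= sp.night_start_hour) & (hour < sp.night_end_hour)
        sleep &= in_night
    return sleep


# ---------------------------------------------------------------------------
# intensity


def classify_intensity(
    epoch_counts: np.ndarray, cutpoints: Cutpoints, epoch_s: int
) -> np.ndarray:
    """Label each epoch sedentary/light/moderate/vigorous by ordered cutpoints.

    Counts must be at the cutpoints' native epoch length; shorter epochs are
    re-aggregated by summation.  Boundary counts go to the higher class
    (``>=`` convention).  Returns an integer array (0=sedentary..3=vigorous);
    map through :data:`INTENSITY_LEVELS` for names.
    """
    counts = np.asarray(epoch_counts)
    if np.any(counts < 0):
        raise ValueError("negative counts are invalid")
    native = cutpoints.native_epoch_s
    if epoch_s != native:
        if native % epoch_s != 0:
            raise ValueError(
                f"data epochs of {epoch_s} s cannot be aggregated to the "
                f"cutpoints' native {native} s epochs"
            )
        per = native // epoch_s
        n = counts.size // per
        counts = counts[: n * per].reshape(n, per).sum(axis=1)
    return np.searchsorted(cutpoints.thresholds, counts, side="right")


# ---------------------------------------------------------------------------
# day summary


def summarize_day(
    series: EpochSeries,
    wear_mask: np.ndarray,
    sleep_mask: np.ndarray,
    labels: np.ndarray,
    calendar: Mapping[_date, bool] | pd.DataFrame,
    params: AlgorithmParams | None = None,
) -> DaySummary:
    """Collapse one participant-day to wear and hourly MVPA totals.

    ``wear_mask`` (True = nonwear) and ``sleep_mask`` are per minute; labels
    are per epoch at the cutpoints' native epoch length.  A minute counts as
    worn iff it is neither nonwear nor sleep; MVPA accrues only in worn-awake
    epochs labelled moderate or vigorous, attributed to the clock hour
    containing the epoch's start.
    """
    params = params or AlgorithmParams()
    if isinstance(calendar, pd.DataFrame):
        cal = {
            pd.Timestamp(d).date(): bool(s)
            for d, s in zip(calendar["date"], calendar["is_school_day"])
        }
    else:
        cal = dict(calendar)
    day = series.date
    if day not in cal:
        raise ValueError(f"calendar does not cover {day}")

    native = params.cutpoints.native_epoch_s
    per_min = 60 // native
    n_min = min(wear_mask.size, sleep_mask.size, labels.size // per_min)
    wear_mask = np.asarray(wear_mask, bool)[:n_min]
    sleep_mask = np.asarray(sleep_mask, bool)[:n_min]
    labels = np.asarray(labels)[: n_min * per_min]

    worn_awake_min = ~wear_mask & ~sleep_mask
    worn_awake_epoch = np.repeat(worn_awake_min, per_min)
    is_mvpa = (labels >= 2) & worn_awake_epoch

    start_min = series.start.hour * 60 + series.start.minute
    minute_of_day = (start_min + np.arange(n_min)) % 1440
    hour_of_min = minute_of_day // 60
    hour_of_epoch = np.repeat(hour_of_min, per_min)

    hourly_mvpa = np.bincount(
        hour_of_epoch, weights=is_mvpa.astype(float), minlength=24
    )[:24] * (native / 60.0)
    hourly_wear = np.bincount(
        hour_of_min, weights=worn_awake_min.astype(float), minlength=24
    )[:24]

    wear_minutes = float(worn_awake_min.sum())
    mvpa_minutes = float(hourly_mvpa.sum())
    return DaySummary(
        participant_id=series.participant_id,
        date=day,
        wear_minutes=wear_minutes,
        mvpa_minutes=mvpa_minutes,
        hourly_mvpa=hourly_mvpa,
        hourly_wear=hourly_wear,
        is_valid=wear_minutes >= params.min_wear_min,
        is_school_day=cal[day],
    )


def process_series(
    series: EpochSeries,
    calendar: Mapping[_date, bool] | pd.DataFrame,
    params: AlgorithmParams | None = None,
) -> DaySummary:
    """Run nonwear, sleep and intensity rules on one series, then summarise."""
    params = params or AlgorithmParams()
    mins = minute_counts(series)
    wear = detect_nonwear(mins, params)
    start_min = series.start.hour * 60 + series.start.minute
    minute_of_day = (start_min + np.arange(mins.size)) % 1440
    sleep = score_sleep(mins, params, minute_of_day=minute_of_day)
    labels = classify_intensity(series.counts, params.cutpoints, series.epoch_s)
    return summarize_day(series, wear, sleep, labels, calendar, params)


# ---------------------------------------------------------------------------
# inclusion rules


def apply_inclusion_rules(
    summaries: Iterable[DaySummary],
    params: AlgorithmParams | None = None,
) -> tuple[list[DaySummary], list[dict]]:
    """Apply daily-wear, reactivity-trim and minimum-valid-day rules.

    Per participant (date order): the first ``reactivity_trim_days`` calendar
    days containing any wear are dropped (unless the participant's summaries
    are already marked screened), days with ``wear_minutes < min_wear_min``
    are dropped, and participants with fewer than ``min_valid_days`` remaining
    days are dropped entirely.  Returns the kept summaries and a log with one
    entry per exclusion, naming the rule.
    """
    params = params or AlgorithmParams()
    log: list[dict] = []
    kept: list[DaySummary] = []

    by_pid: dict[str, list[DaySummary]] = {}
    for s in summaries:
        by_pid.setdefault(s.participant_id, []).append(s)

    for pid, days in by_pid.items():
        days = sorted(days, key=lambda s: s.date)
        screened = all(d.reactivity_screened for d in days)
        if not screened:
            wear_dates = [d.date for d in days if d.wear_minutes > 0]
            trim_dates = set(sorted(set(wear_dates))[: params.reactivity_trim_days])
        else:
            trim_dates = set()

        survivors: list[DaySummary] = []
        for d in days:
            if d.date in trim_dates:
                log.append(
                    {
                        "participant_id": pid,
                        "date": d.date,
                        "rule": "reactivity_trim",
                        "detail": f"first {params.reactivity_trim_days} wear days removed",
                    }
                )
                continue
            if d.wear_minutes < params.min_wear_min:
                log.append(
                    {
                        "participant_id": pid,
                        "date": d.date,
                        "rule": "min_wear",
                        "detail": f"{d.wear_minutes:.0f} min worn < {params.min_wear_min}",
                    }
                )
                continue
            survivors.append(replace(d, is_valid=True, reactivity_screened=True))

        if len(survivors) < params.min_valid_days:
            log.append(
                {
                    "participant_id": pid,
                    "date": None,
                    "rule": "min_valid_days",
                    "detail": f"{len(survivors)} valid days < {params.min_valid_days}",
                }
            )
            continue
        kept.extend(survivors)
    return kept, log
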