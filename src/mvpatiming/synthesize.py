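"""Synthetic adolescent accelerometer cohorts.

Two generators:

* :func:`simulate_cohort` emits raw epoch-count streams (one
  :class:`~mvpatiming.preprocess.EpochSeries` per participant-day) with
  circadian structure, overnight sleep blocks, nonwear blocks and
  person-level heterogeneity in daily MVPA, to exercise the preprocessing
  stages end to end;
* :func:`simulate_person_period` draws discrete-time event data directly from
  a known hazard model, to exercise estimation with a known truth.

Defaults emulate the observational design the package targets: 113
adolescents wearing a wrist device for 20 days, population mean daily MVPA of
about 31 minutes with a between-person SD of the same size, and an evening
activity peak.  Moderator timing effects are circular shifts of the hourly
activity-allocation profile, so hypothesized group differences (males more
morning-active; sports participants and school days later-shifted) are
recoverable by the full pipeline.

All randomness flows from a single seed; per-participant substreams are
spawned deterministically so subsetting participants is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Callable

import numpy as np
import pandas as pd

from .preprocess import EpochSeries

__all__ = [
    "SimConfig",
    "TrueHazardModel",
    "SimulatedCohort",
    "DEFAULT_PROFILE",
    "simulate_cohort",
    "simulate_person_period",
]

# Hourly MVPA-allocation weights (arbitrary units, hours 0..23): near-zero
# overnight, modest morning/midday mass, pronounced evening peak at 18:00.
DEFAULT_PROFILE = np.array(
    [
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0,       # 0-5
        0.3, 0.7, 1.3, 1.6, 1.9, 2.1,       # 6-11
        2.3, 2.5, 2.8, 3.6, 5.0, 7.0,       # 12-17
        8.0, 6.5, 3.5, 1.5, 0.6, 0.2,       # 18-23
    ]
)

# Allocation weights for "morning-active" days (e.g. weekend sport,
# commuting on foot): late-morning peak, deliberately negligible before
# 9:00 so that the 8 AM reference interval stays quiet for everyone.
MORNING_PROFILE = np.array(
    [
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0,       # 0-5
        0.1, 0.3, 1.0, 3.5, 5.0, 4.5,       # 6-11
        3.5, 2.5, 2.0, 1.8, 2.0, 2.5,       # 12-17
        3.0, 2.5, 1.5, 0.8, 0.4, 0.2,       # 18-23
    ]
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_participants: int = 113
    n_days: int = 20
    epoch_s: int = 5
    circadian_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROFILE.copy()
    )
    mvpa_mean_minutes: float = 30.91
    mvpa_between_sd: float = 30.94
    # Within-person day-to-day variability of daily MVPA: Gamma shape 1
    # (exponential) keeps the mean at m_i while making the fraction of days
    # on which a person meets their own mean e^-1 ~ 0.37, the rate seen in
    # observational adolescent cohorts.
    day_gamma_shape: float = 1.0
    moderator_prevalences: dict = field(
        default_factory=lambda: {
            "male": 0.372,
            "sports": 0.398,
            "bmi": (0.717, 0.115, 0.168),  # normal / overweight / obese
            "school_day": 0.454,
        }
    )
    # Circular shift of the allocation profile, in whole hours; negative =
    # activity peak earlier in the day.
    timing_shift: dict = field(
        default_factory=lambda: {
            "male": -3,
            "sports": 1,
            "school_day": 1,
            "overweight": 0,
            "obese": 0,
        }
    )
    # Mixture of day types: most days follow the evening-peaked profile, but
    # a fraction are "morning-active" days (late-morning-peaked profile),
    # which is what puts real probability mass on early event hours.
    # Moderators scale the morning-day propensity multiplicatively (males
    # more morning-active; sports participants and school days less so).
    morning_day_prob: float = 0.12
    morning_profile: np.ndarray = field(
        default_factory=lambda: MORNING_PROFILE.copy()
    )
    morning_boost: dict = field(
        default_factory=lambda: {"male": 1.0, "sports": 0.5, "school_day": 0.5}
    )
    nonwear_rate: float = 0.7  # expected nonwear blocks per day
    start_date: _date = _date(2017, 4, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_days, self.epoch_s) <= 0:
            raise ValueError("counts must be positive")
        if 60 % self.epoch_s != 0:
            raise ValueError(
                f"epoch_s={self.epoch_s} must divide 60 for minute aggregation"
            )
        prof = np.asarray(self.circadian_profile, dtype=float)
        if prof.shape != (24,) or np.any(prof < 0):
            raise ValueError("circadian_profile must be 24 nonnegative values")
        object.__setattr__(self, "circadian_profile", prof)
        mprof = np.asarray(self.morning_profile, dtype=float)
        if mprof.shape != (24,) or np.any(mprof < 0):
            raise ValueError("morning_profile must be 24 nonnegative values")
        object.__setattr__(self, "morning_profile", mprof)
        p = self.moderator_prevalences
        probs = [p["male"], p["sports"], p["school_day"], *p["bmi"]]
        if any(not 0 <= q <= 1 for q in probs):
            raise ValueError("prevalences must lie in [0, 1]")
        if abs(sum(p["bmi"]) - 1.0) > 1e-9:
            raise ValueError("BMI category proportions must sum to 1")
        if self.nonwear_rate < 0:
            raise ValueError("nonwear_rate must be nonnegative")
        if not 0 <= self.morning_day_prob <= 1:
            raise ValueError("morning_day_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    covariates: pd.DataFrame  # participant_id, sex, bmi_category, sports
    series: list  # EpochSeries, one per participant-day
    calendar: pd.DataFrame  # date, is_school_day
    truth: dict  # generative law, parameters, per-person targets


BMI_LEVELS = ("normal", "overweight", "obese")

# Count-law constants (counts per 5 s vector-magnitude epoch).  MVPA minutes
# draw epochs from a shifted negative binomial guaranteed above the moderate
# cutpoint; other awake minutes draw truncated-gamma counts capped below it;
# sleep minutes are zeros with occasional small movement spikes.
_MVPA_EPOCH_OFFSET = 818.0
_MVPA_EPOCH_MEAN_EXTRA = 600.0
_MVPA_EPOCH_K = 5.0
_LIGHT_EPOCH_CAP = 817
_LIGHT_GAMMA_SHAPE = 1.2
_SLEEP_SPIKE_PROB = 0.4
_SLEEP_SPIKE_MAX = 45


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _negbin(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    # gamma-mixed Poisson with shape k (variance = mean + mean^2/k)
    lam = rng.gamma(shape=k, scale=mean / k, size=size)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate covariates, a school calendar and raw epoch-count streams.

    Each participant-day is one :class:`EpochSeries` covering 24 h from
    midnight.  Nonwear blocks are runs of exact zeros; overnight sleep blocks
    are low-count runs; daily MVPA minutes are allocated across hours in
    proportion to the (moderator-shifted) circadian profile, so the realised
    person-level mean daily MVPA tracks ``mvpa_mean_minutes``.
    """
    cfg = config
    root = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10**6,)))

    # shared school calendar
    dates = [cfg.start_date + pd.Timedelta(days=d).to_pytimedelta() for d in range(cfg.n_days)]
    school = root.random(cfg.n_days) < cfg.moderator_prevalences["school_day"]
    calendar = pd.DataFrame({"date": dates, "is_school_day": school})

    # person-level covariates and MVPA targets
    p = cfg.moderator_prevalences
    n = cfg.n_participants
    male = root.random(n) < p["male"]
    sports = root.random(n) < p["sports"]
    bmi = root.choice(len(BMI_LEVELS), size=n, p=np.asarray(p["bmi"], dtype=float))
    if cfg.mvpa_between_sd > 0 and cfg.mvpa_mean_minutes > 0:
        shape = (cfg.mvpa_mean_minutes / cfg.mvpa_between_sd) ** 2
        m_i = root.gamma(shape=shape, scale=cfg.mvpa_mean_minutes / shape, size=n)
        m_i = np.maximum(m_i, 1.0)
    else:
        m_i = np.full(n, float(cfg.mvpa_mean_minutes))

    pids = [f"P{i:03d}" for i in range(n)]
    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": np.where(male, "male", "female"),
            "bmi_category": [BMI_LEVELS[b] for b in bmi],
            "sports": sports.astype(int),
        }
    )

    prof_max = cfg.circadian_profile.max()
    per_min = 60 // cfg.epoch_s
    series: list[EpochSeries] = []

    for i, pid in enumerate(pids):
        rng = _participant_rng(cfg.seed, i)
        shift = (
            cfg.timing_shift.get("male", 0) * int(male[i])
            + cfg.timing_shift.get("sports", 0) * int(sports[i])
            + cfg.timing_shift.get(BMI_LEVELS[bmi[i]], 0) * (bmi[i] > 0)
        )
        p_morning = cfg.morning_day_prob
        p_morning *= cfg.morning_boost.get("male", 1.0) ** int(male[i])
        p_morning *= cfg.morning_boost.get("sports", 1.0) ** int(sports[i])
        for d in range(cfg.n_days):
            day_shift = shift + cfg.timing_shift.get("school_day", 0) * int(school[d])
            p_day = min(
                p_morning * cfg.morning_boost.get("school_day", 1.0) ** int(school[d]),
                0.95,
            )
            is_morning_day = rng.random() < p_day
            if prof_max <= 0:
                base = cfg.circadian_profile  # degenerate: stays all-zero
            elif is_morning_day:
                base = cfg.morning_profile
            else:
                base = cfg.circadian_profile
            prof = np.roll(base, day_shift)
            counts = _simulate_day_minutes(rng, cfg, prof, prof_max, m_i[i], per_min)
            series.append(
                EpochSeries(
                    participant_id=pid,
                    start=pd.Timestamp(dates[d]),
                    epoch_s=cfg.epoch_s,
                    counts=counts,
                    channel="vm",
                )
            )

    truth = {
        "count_law": (
            "MVPA epochs: 818 + NegBin(mean=600, k=5); awake non-MVPA epochs: "
            "round(Gamma(shape=1.2, mean prop. to profile)) capped at 817; "
            "sleep minutes: one spike epoch U{5..45} w.p. 0.4 else zeros; "
            "nonwear blocks: exact zeros"
        ),
        "person_mean_mvpa": dict(zip(pids, m_i)),
        "timing_shift": dict(cfg.timing_shift),
        "morning_day_prob": cfg.morning_day_prob,
        "morning_profile": cfg.morning_profile.tolist(),
        "morning_boost": dict(cfg.morning_boost),
        "profile": cfg.circadian_profile.tolist(),
        "day_gamma_shape": cfg.day_gamma_shape,
        "nonwear_rate": cfg.nonwear_rate,
        "seed": cfg.seed,
    }
    return SimulatedCohort(covariates, series, calendar, truth)


def _simulate_day_minutes(
    rng: np.random.Generator,
    cfg: SimConfig,
    prof: np.ndarray,
    prof_max: float,
    m_i: float,
    per_min: int,
) -> np.ndarray:
    """One day (1440 minutes) of epoch counts for one participant."""
    n_min = 1440
    minute_hour = np.arange(n_min) // 60

    # degenerate all-zero profile: no activity at all
    if prof_max <= 0:
        return np.zeros(n_min * per_min, dtype=np.int64)

    # sleep span: [0, wake) and [onset, 1440)
    wake = int(np.clip(rng.normal(7 * 60, 30), 4 * 60, 10 * 60))
    onset = int(np.clip(rng.normal(23.25 * 60, 30), 21 * 60, n_min - 1))
    asleep = np.zeros(n_min, dtype=bool)
    asleep[:wake] = True
    asleep[onset:] = True

    # nonwear blocks: exact zeros, placed in the awake span
    nonwear = np.zeros(n_min, dtype=bool)
    for _ in range(rng.poisson(cfg.nonwear_rate)):
        dur = int(rng.integers(60, 181))
        start = int(rng.integers(wake, max(onset - dur, wake + 1)))
        nonwear[start : start + dur] = True

    # allocate MVPA minutes among awake, worn minutes by profile weight
    avail = ~asleep & ~nonwear
    weights = prof[minute_hour] * avail
    target = rng.gamma(cfg.day_gamma_shape, m_i / cfg.day_gamma_shape)
    n_mvpa = min(int(round(target)), int((weights > 0).sum()))
    mvpa = np.zeros(n_min, dtype=bool)
    wsum = weights.sum()
    if n_mvpa > 0 and wsum > 0:
        idx = rng.choice(n_min, size=n_mvpa, replace=False, p=weights / wsum)
        mvpa[idx] = True

    counts = np.zeros((n_min, per_min), dtype=np.int64)

    sleep_idx = np.flatnonzero(asleep & ~nonwear)
    if sleep_idx.size:
        spiky = rng.random(sleep_idx.size) < _SLEEP_SPIKE_PROB
        which_epoch = rng.integers(0, per_min, size=sleep_idx.size)
        vals = rng.integers(5, _SLEEP_SPIKE_MAX + 1, size=sleep_idx.size)
        rows = sleep_idx[spiky]
        counts[rows, which_epoch[spiky]] = vals[spiky]

    light_idx = np.flatnonzero(avail & ~mvpa)
    if light_idx.size:
        mean_epoch = (
            (40.0 + 360.0 * prof[minute_hour[light_idx]] / prof_max) / per_min
        )
        draws = rng.gamma(
            _LIGHT_GAMMA_SHAPE, mean_epoch[:, None] / _LIGHT_GAMMA_SHAPE,
            size=(light_idx.size, per_min),
        )
        counts[light_idx] = np.minimum(np.round(draws), _LIGHT_EPOCH_CAP).astype(
            np.int64
        )

    mvpa_idx = np.flatnonzero(mvpa)
    if mvpa_idx.size:
        extra = _negbin(
            rng, _MVPA_EPOCH_MEAN_EXTRA, _MVPA_EPOCH_K, mvpa_idx.size * per_min
        ).reshape(mvpa_idx.size, per_min)
        counts[mvpa_idx] = (_MVPA_EPOCH_OFFSET + extra).astype(np.int64)

    return counts.reshape(-1)


# ---------------------------------------------------------------------------
# person-period simulation from a known hazard model


@dataclass(frozen=True)
class TrueHazardModel:
    """Generative discrete-time hazard on the log-odds scale, original hours.

    eta(t, x) = sum_k beta_time[k] * t**k
              + sum_c x_c * beta_cov[c]
              + sum_c x_c * sum_{k>=1} beta_interact[c][k-1] * t**k
    with a person random intercept u_i ~ N(0, sigma_u^2).
    """

    degree: int
    beta_time: tuple  # length degree+1: intercept, t, t^2, ...
    sigma_u: float = 0.0
    beta_cov: dict = field(default_factory=dict)
    beta_interact: dict = field(default_factory=dict)  # cov -> tuple length degree
    risk_window: tuple = (9, 23)

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if len(self.beta_time) != self.degree + 1:
            raise ValueError("beta_time length must equal degree + 1")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        lo, hi = self.risk_window
        if not (0 <= lo <= hi <= 23):
            raise ValueError("risk_window must lie within hours 0..23")
        if lo > hi:
            raise ValueError("risk window is empty")

    def eta(self, t: np.ndarray, covrow: dict | None = None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = sum(b * t**k for k, b in enumerate(self.beta_time))
        if covrow:
            for c, val in covrow.items():
                out = out + val * self.beta_cov.get(c, 0.0)
                for k, b in enumerate(self.beta_interact.get(c, ()), start=1):
                    out = out + val * b * t**k
        return out


def simulate_person_period(
    model: TrueHazardModel,
    n_participants: int,
    n_days: int,
    covariate_sampler: Callable[[np.random.Generator, int], pd.DataFrame] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a person-period event table from a known hazard model.

    For each person, one random intercept u_i; for each day, hours in the risk
    window are walked in order, the event fires with probability
    ``expit(eta(t) + u_i)`` and terminates the day, otherwise the day is
    censored at the window end.  Returns the long-format table and a truth
    record (the model and the drawn random intercepts).
    """
    lo, hi = model.risk_window
    rng = np.random.default_rng(seed)
    hours = np.arange(lo, hi + 1)
    if covariate_sampler is not None:
        cov = covariate_sampler(rng, n_participants)
        covnames = list(cov.columns)
    else:
        cov = pd.DataFrame(index=range(n_participants))
        covnames = []

    u = rng.normal(0.0, model.sigma_u, size=n_participants)
    rows: dict[str, list] = {
        "participant_id": [], "day_id": [], "t": [], "event": [],
        **{c: [] for c in covnames},
    }
    for i in range(n_participants):
        covrow = {c: float(cov.iloc[i][c]) for c in covnames}
        eta = model.eta(hours, covrow) + u[i]
        h = 1.0 / (1.0 + np.exp(-eta))
        pid = f"S{i:04d}"
        for d in range(n_days):
            draws = rng.random(hours.size)
            fired = draws < h
            stop = int(np.argmax(fired)) if fired.any() else hours.size - 1
            upto = stop + 1 if fired.any() else hours.size
            for j in range(upto):
                rows["participant_id"].append(pid)
                rows["day_id"].append(f"{pid}-d{d:02d}")
                rows["t"].append(int(hours[j]))
                rows["event"].append(int(fired.any() and j == stop))
                for c in covnames:
                    rows[c].append(covrow[c])
    table = pd.DataFrame(rows)
    truth = {
        "model": model,
        "u": dict(zip([f"S{i:04d}" for i in range(n_participants)], u)),
        "seed": seed,
    }
    return table, truth
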