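"""Event definition and discrete-time risk-set construction.

The event for a participant-day is the first clock hour by which the
participant has accumulated their *own* average daily MVPA (the arithmetic
mean of daily MVPA minutes over their valid, post-trim days).  Time is
discrete: interval ``t`` is the clock span (t-1:00, t:00], labelled
"before t" in all outputs.  Each valid day contributes one row per hour at
risk, from the window start up to and including the event hour, or through
the window end if the day is censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DaySummary

__all__ = [
    "PersonMean",
    "DEFAULT_RISK_WINDOW",
    "person_mean_mvpa",
    "code_event_hour",
    "build_person_period",
    "DUMMY_COLUMNS",
    "MODERATOR_DUMMIES",
]

# Hour intervals ending 9 AM through 11 PM; the interval ending 8 AM is the
# reference boundary (no event observed earlier in the emulated design).
DEFAULT_RISK_WINDOW = (9, 23)

# one-hot covariate columns carried on every person-period row
DUMMY_COLUMNS = ("male", "bmi_overweight", "bmi_obese", "sports", "school_day")

# moderator name -> its dummy columns in the person-period table
MODERATOR_DUMMIES = {
    "sex": ("male",),
    "bmi_category": ("bmi_overweight", "bmi_obese"),
    "sports": ("sports",),
    "school_day": ("school_day",),
}


@dataclass(frozen=True)
class PersonMean:
    participant_id: str
    mean_mvpa: float
    n_days: int

    def __post_init__(self) -> None:
        if self.mean_mvpa < 0:
            raise ValueError("mean MVPA cannot be negative")


def person_mean_mvpa(summaries: Sequence[DaySummary]) -> PersonMean:
    """Arithmetic mean of daily MVPA minutes over the included days."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot compute a person mean from zero days")
    pids = {s.participant_id for s in summaries}
    if len(pids) != 1:
        raise ValueError("summaries mix participants: " + ", ".join(sorted(pids)))
    vals = [s.mvpa_minutes for s in summaries]
    return PersonMean(
        participant_id=summaries[0].participant_id,
        mean_mvpa=float(np.mean(vals)),
        n_days=len(vals),
    )


def code_event_hour(hourly_mvpa: np.ndarray, mean: PersonMean) -> int | None:
    """First interval t (1..24) whose cumulative MVPA reaches the person mean.

    Cumulative MVPA through interval t is ``sum(hourly_mvpa[:t])``; attainment
    uses the >= convention (exactly reaching the mean counts).  Returns None
    when the day total never reaches the mean (censored).
    """
    hourly = np.asarray(hourly_mvpa, dtype=float)
    if hourly.shape != (24,):
        raise ValueError("hourly_mvpa must have 24 entries")
    if np.any(hourly < 0):
        raise ValueError("negative hourly MVPA is invalid")
    cum = np.cumsum(hourly)
    reached = cum >= mean.mean_mvpa - 1e-12
    if not reached.any():
        return None
    return int(np.argmax(reached)) + 1  # interval label = index + 1


def build_person_period(
    summaries: Iterable[DaySummary],
    means: Mapping[str, PersonMean] | Sequence[PersonMean],
    covariates: pd.DataFrame,
    risk_window: tuple[int, int] = DEFAULT_RISK_WINDOW,
    exclude_degenerate: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the long-format discrete-time risk set.

    ``covariates`` needs columns participant_id, sex, bmi_category, sports.
    Returns (table, log).  Table columns: participant_id, day_id, t, event and
    the one-hot covariates of :data:`DUMMY_COLUMNS`.  Days whose event occurs
    before the window start are coded as an event in the first window
    interval; days with no wear inside the window contribute no rows;
    participants with a zero person mean are excluded by default (their event
    would trivially fire at the first wear hour of every day).
    """
    lo, hi = risk_window
    if not (1 <= lo <= hi <= 24):
        raise ValueError("risk window must satisfy 1 <= start <= end <= 24")
    if isinstance(means, Mapping):
        mean_by_pid = dict(means)
    else:
        mean_by_pid = {m.participant_id: m for m in means}

    cov = covariates.set_index("participant_id")
    for col in ("sex", "bmi_category", "sports"):
        if col not in cov.columns:
            raise ValueError(f"covariate table lacks column {col!r}")

    log: list[dict] = []
    rows: dict[str, list] = {
        "participant_id": [], "day_id": [], "t": [], "event": [],
        **{c: [] for c in DUMMY_COLUMNS},
    }
    hours = np.arange(lo, hi + 1)

    for s in summaries:
        pid = s.participant_id
        if pid not in mean_by_pid:
            raise ValueError(f"no person mean for participant {pid}")
        if pid not in cov.index:
            raise ValueError(f"covariates missing for participant {pid}")
        m = mean_by_pid[pid]
        if exclude_degenerate and m.mean_mvpa <= 0:
            log.append({"participant_id": pid, "rule": "degenerate_zero_mean"})
            continue
        if s.hourly_wear[lo - 1 : hi].sum() <= 0:
            log.append(
                {"participant_id": pid, "date": s.date, "rule": "no_wear_in_window"}
            )
            continue

        t_event = code_event_hour(s.hourly_mvpa, m)
        if t_event is not None and t_event < lo:
            log.append(
                {"participant_id": pid, "date": s.date, "rule": "event_before_window",
                 "detail": f"event at t={t_event} coded at window start {lo}"}
            )
            t_event = lo
        if t_event is not None and t_event > hi:
            t_event = None  # censored within the window

        last = t_event if t_event is not None else hi
        crow = cov.loc[pid]
        dummies = {
            "male": int(crow["sex"] == "male"),
            "bmi_overweight": int(crow["bmi_category"] == "overweight"),
            "bmi_obese": int(crow["bmi_category"] == "obese"),
            "sports": int(crow["sports"]),
            "school_day": int(s.is_school_day),
        }
        day_id = f"{pid}-{s.date.isoformat()}"
        for t in range(lo, last + 1):
            rows["participant_id"].append(pid)
            rows["day_id"].append(day_id)
            rows["t"].append(t)
            rows["event"].append(int(t_event is not None and t == t_event))
            for c in DUMMY_COLUMNS:
                rows[c].append(dummies[c])

    return pd.DataFrame(rows), log
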