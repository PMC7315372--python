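"""Intervention decision points from effect tables.

The overall decision window is derived from the base model's effect table,
either as the contiguous run of near-peak hazard rows or as the window of
steepest survival decline.  Per-moderator windows are emitted only when two
criteria hold: (1) the groups' odds-ratio confidence intervals are disjoint
at one or more hours, and (2) the direction of the difference at those hours
matches the registered hypothesis (exploratory moderators satisfy criterion 2
automatically once criterion 1 holds).

Windows operate on row labels ("before t"), never raw clock spans, and ties
in window position break toward the later (evening) run — the substantive
recommendation privileges the late-day window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HYPOTHESES",
    "DecisionWindow",
    "ModeratorFinding",
    "DecisionReport",
    "peak_hazard_window",
    "steepest_survival_decline",
    "moderator_decision_points",
]

# Registered directional expectations: which group is hypothesized to have
# higher odds of having met their average MVPA.  Sex and BMI carry no
# registered direction (exploratory).
DEFAULT_HYPOTHESES = {
    "sex": "exploratory",
    "bmi_category": "exploratory",
    "sports": "sports",          # sports participants higher
    "school_day": "school_day",  # school days higher
}


@dataclass(frozen=True)
class DecisionWindow:
    """A contiguous run of hour rows, by interval label."""

    start_t: int
    end_t: int
    start_label: str
    end_label: str
    basis: str

    def contains(self, t: int) -> bool:
        return self.start_t <= t <= self.end_t


@dataclass
class ModeratorFinding:
    moderator: str
    criterion1_met: bool
    criterion2_met: bool
    favored_group: str | None
    significant_hours: list[int]
    window: DecisionWindow | None
    rationale: str


@dataclass
class DecisionReport:
    overall_window: DecisionWindow
    basis: str
    moderator_findings: dict[str, ModeratorFinding] = field(default_factory=dict)
    hypotheses: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.moderator_findings.values():
            if f.window is not None and not (f.criterion1_met and f.criterion2_met):
                raise ValueError(
                    f"moderator {f.moderator}: window without both criteria met"
                )


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of maximal runs of True."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _pick_run(runs: list[tuple[int, int]]) -> tuple[int, int]:
    """Longest run; ties broken toward the later run."""
    best = runs[0]
    for r in runs[1:]:
        if (r[1] - r[0]) >= (best[1] - best[0]):
            best = r
    return best


def _window_from_rows(table: pd.DataFrame, i: int, j: int, basis: str) -> DecisionWindow:
    return DecisionWindow(
        start_t=int(table["t"].iloc[i]),
        end_t=int(table["t"].iloc[j]),
        start_label=str(table["hour"].iloc[i]),
        end_label=str(table["hour"].iloc[j]),
        basis=basis,
    )


def peak_hazard_window(table: pd.DataFrame, rel_tolerance: float = 0.0) -> DecisionWindow:
    """Maximal contiguous run of rows with hazard >= (1-tol) * max hazard."""
    if table.empty:
        raise ValueError("empty effect table")
    if not 0 <= rel_tolerance < 1:
        raise ValueError("rel_tolerance must lie in [0, 1)")
    h = table["hazard_prob"].to_numpy(dtype=float)
    mask = h >= (1.0 - rel_tolerance) * h.max() - 1e-12
    i, j = _pick_run(_contiguous_runs(mask))
    return _window_from_rows(table, i, j, basis="peak_hazard")


def steepest_survival_decline(table: pd.DataFrame, span: int = 3) -> DecisionWindow:
    """Span-length row window maximizing S(start) - S(end); later ties win."""
    if table.empty:
        raise ValueError("empty effect table")
    s = table["survival_prob"].to_numpy(dtype=float)
    if not 1 <= span < s.size:
        raise ValueError("span must satisfy 1 <= span < number of rows")
    drops = s[:-span] - s[span:]
    best = 0
    for i in range(1, drops.size):
        if drops[i] >= drops[best] - 1e-12:
            best = i
    return _window_from_rows(table, best, best + span, basis="steepest_survival_decline")


def moderator_decision_points(
    comparisons: dict[str, dict],
    hypotheses: dict[str, str] | None = None,
    overall_table: pd.DataFrame | None = None,
    basis: str = "peak_hazard",
    rel_tolerance: float = 0.10,
    span: int = 3,
) -> DecisionReport:
    """Apply the two decision criteria per moderator and assemble the report.

    ``comparisons`` maps moderator name to a dict with keys:

    * ``comparison`` — output of :func:`~mvpatiming.effects.ci_overlap_compare`
      (side a = the moderator's named/indicator group, side b = reference);
    * ``group_a`` / ``group_b`` — display names of the two groups.

    ``overall_table`` (base-model effect table) provides the overall window;
    ``basis`` chooses between ``peak_hazard`` and
    ``steepest_survival_decline``.
    """
    hypotheses = dict(DEFAULT_HYPOTHESES if hypotheses is None else hypotheses)
    if overall_table is None:
        raise ValueError("overall effect table is required")
    if basis == "peak_hazard":
        overall = peak_hazard_window(overall_table, rel_tolerance)
    elif basis == "steepest_survival_decline":
        overall = steepest_survival_decline(overall_table, span)
    else:
        raise ValueError(f"unknown basis {basis!r}")

    findings: dict[str, ModeratorFinding] = {}
    for mod, data in comparisons.items():
        if mod not in hypotheses:
            raise ValueError(f"no registered hypothesis for moderator {mod!r}")
        comp = data["comparison"]
        group_a = data.get("group_a", f"{mod}=1")
        group_b = data.get("group_b", f"{mod}=0")
        sig = comp["significant"].to_numpy(dtype=bool)
        sig_hours = [int(t) for t in comp["t"].to_numpy()[sig]]
        criterion1 = bool(sig.any())

        # split significant hours into maximal contiguous runs with a
        # consistent direction (which group's OR is higher)
        or_a = comp["or_a"].to_numpy(dtype=float)
        or_b = comp["or_b"].to_numpy(dtype=float)
        direction = np.where(or_a > or_b, 1, -1)
        runs: list[tuple[int, int, str]] = []
        for i, j in _contiguous_runs(sig):
            k = i
            while k <= j:
                m = k
                while m + 1 <= j and direction[m + 1] == direction[k]:
                    m += 1
                runs.append((k, m, group_a if direction[k] == 1 else group_b))
                k = m + 1

        hyp = hypotheses[mod]
        hyp_group = data.get("hypothesized_group", hyp)
        favored = None
        criterion2 = False
        rationale_parts = []
        if criterion1:
            if hyp == "exploratory":
                candidates = runs
                criterion2 = bool(candidates)
                rationale_parts.append(
                    "exploratory moderator: direction criterion auto-met at "
                    f"significant hours {sig_hours}"
                )
            else:
                candidates = [r for r in runs if r[2] == hyp_group]
                criterion2 = bool(candidates)
                observed = sorted({r[2] for r in runs})
                rationale_parts.append(
                    f"hypothesized favored group {hyp_group!r}; observed "
                    f"favored {observed} at significant hours {sig_hours}"
                )
        else:
            candidates = []
            rationale_parts.append("no hour with nonoverlapping 95% CIs")

        window = None
        if criterion1 and criterion2:
            i, j, favored = max(
                candidates, key=lambda r: (r[1] - r[0], r[0])
            )  # longest run, later ties win
            window = _window_from_rows(comp, i, j, basis="ci_nonoverlap")
            rationale_parts.append(
                f"window {window.start_label} .. {window.end_label} for {favored}"
            )

        findings[mod] = ModeratorFinding(
            moderator=mod,
            criterion1_met=criterion1,
            criterion2_met=criterion2,
            favored_group=favored,
            significant_hours=sig_hours,
            window=window,
            rationale="; ".join(rationale_parts),
        )

    return DecisionReport(
        overall_window=overall,
        basis=basis,
        moderator_findings=findings,
        hypotheses=hypotheses,
    )
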