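"""File formats, configuration and the four-stage pipeline runner.

All interchange is plain CSV.  The epoch dialect carries ActiGraph-style
exports: columns ``participant_id, timestamp, epoch_s, axis1[, axis2, axis3]
[, vm]``; when ``vm`` is absent and three axes are present, the vector
magnitude is the rounded Euclidean norm.  Every output file starts with
``#``-prefixed header comments stating the interval-labelling convention and
the parameter values used, so each run is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decide, effects, events, hazard, preprocess, synthesize
from .preprocess import AlgorithmParams, EpochSeries

__all__ = [
    "PipelineConfig",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_covariates",
    "read_calendar",
    "write_day_summaries",
    "read_day_summaries",
    "write_person_period",
    "run_pipeline",
    "CONVENTION_NOTE",
]

CONVENTION_NOTE = (
    "row label 'Before t' = the clock interval (t-1:00, t:00]; "
    "survival at a row multiplies (1 - hazard) over strictly earlier rows"
)


@dataclass
class PipelineConfig:
    """Paths, algorithm constants and analysis settings for one run."""

    epoch_csv: str = "scratch/cohort/epochs.csv"
    covariate_csv: str = "scratch/cohort/covariates.csv"
    calendar_csv: str = "scratch/cohort/calendar.csv"
    out_dir: str = "results"
    params: AlgorithmParams = field(default_factory=AlgorithmParams)
    risk_window: tuple = events.DEFAULT_RISK_WINDOW
    reference_hour: int = 8
    max_degree: int = 3
    alpha: float = 0.05
    n_quad: int = 9
    moderators: tuple = ("sex", "bmi_category", "sports", "school_day")
    hypotheses: dict = field(default_factory=lambda: dict(decide.DEFAULT_HYPOTHESES))
    rel_tolerance: float = 0.10
    survival_span: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = raw.pop("params", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if params:
            sleep = params.pop("sleep", None)
            cuts = params.pop("cutpoints", None)
            kwargs = dict(params)
            if sleep:
                kwargs["sleep"] = preprocess.SleepParams(**sleep)
            if cuts:
                kwargs["cutpoints"] = preprocess.Cutpoints(**cuts)
            cfg.params = AlgorithmParams(**kwargs)
        cfg.risk_window = tuple(cfg.risk_window)
        cfg.moderators = tuple(cfg.moderators)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["risk_window"] = list(self.risk_window)
        d["moderators"] = list(self.moderators)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# epoch CSV


def write_epoch_csv(series: list[EpochSeries], path: str | Path) -> None:
    """Stream series to disk one at a time (epoch files can be tens of
    millions of rows; nothing here materialises them all at once)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("participant_id,timestamp,epoch_s,vm\n")
        for s in series:
            ts = (
                np.datetime64(s.start.to_pydatetime(), "s")
                + np.arange(s.n_epochs) * np.timedelta64(s.epoch_s, "s")
            ).astype(str)
            block = pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": ts,
                    "epoch_s": s.epoch_s,
                    "vm": s.counts,
                }
            )
            block.to_csv(fh, header=False, index=False)


def read_epoch_csv(path: str | Path) -> tuple[list[EpochSeries], list[dict]]:
    """Parse the epoch dialect into per participant-day series.

    Malformed rows (unparseable timestamps, negative counts) are collected
    into the returned error report, not silently dropped.  Missing mandatory
    columns and non-monotone timestamps within a participant-day are
    rejected outright.
    """
    errors: list[dict] = []
    parts: dict[tuple, list] = {}
    offset = 0
    checked_cols = False
    for df in pd.read_csv(path, comment="#", chunksize=2_000_000):
        if not checked_cols:
            for col in ("participant_id", "timestamp", "epoch_s"):
                if col not in df.columns:
                    raise ValueError(f"epoch CSV lacks mandatory column {col!r}")
            if "vm" not in df.columns and "axis1" not in df.columns:
                raise ValueError("epoch CSV lacks mandatory column 'axis1' (or 'vm')")
            checked_cols = True
        if "vm" not in df.columns:
            if all(c in df.columns for c in ("axis1", "axis2", "axis3")):
                df["vm"] = np.rint(
                    np.sqrt(df["axis1"] ** 2 + df["axis2"] ** 2 + df["axis3"] ** 2)
                ).astype(np.int64)
            else:
                df["vm"] = df["axis1"]

        ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
        vm = pd.to_numeric(df["vm"], errors="coerce")
        bad_ts = ts.isna()
        bad = bad_ts | vm.isna() | (vm < 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                {
                    "row": offset + int(i),
                    "reason": "bad timestamp" if bad_ts.iloc[i] else "bad count",
                }
            )
        offset += len(df)
        df = df[~bad]
        ts = ts[~bad]
        for (pid, day), idx in df.groupby(
            [df["participant_id"], ts.dt.date], sort=False
        ).indices.items():
            parts.setdefault((str(pid), day), []).append(
                (
                    ts.iloc[idx].to_numpy(),
                    df["vm"].iloc[idx].to_numpy(dtype=np.int64),
                    int(df["epoch_s"].iloc[idx[0]]),
                )
            )

    series: list[EpochSeries] = []
    for (pid, day) in sorted(parts):
        chunks = parts[(pid, day)]
        tstamps = np.concatenate([c[0] for c in chunks])
        counts = np.concatenate([c[1] for c in chunks])
        epoch_s = chunks[0][2]
        if np.any(np.diff(tstamps).astype("timedelta64[s]").astype(int) <= 0):
            raise ValueError(f"non-monotone timestamps for participant {pid} on {day}")
        series.append(
            EpochSeries(
                participant_id=pid,
                start=pd.Timestamp(tstamps[0]),
                epoch_s=epoch_s,
                counts=counts,
            )
        )
    return series, errors


# ---------------------------------------------------------------------------
# small tables


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"participant_id", "sex", "bmi_category", "sports"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"covariate CSV lacks column(s) {sorted(missing)}")
    return df


def read_calendar(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"date", "is_school_day"} <= set(df.columns):
        raise ValueError("calendar CSV needs columns date, is_school_day")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["is_school_day"] = df["is_school_day"].astype(bool)
    return df


def _write_with_header(df: pd.DataFrame, path: Path, note_lines: list[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in note_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_day_summaries(
    summaries: list[preprocess.DaySummary], path: str | Path, params: AlgorithmParams
) -> None:
    recs = []
    for s in summaries:
        rec = {
            "participant_id": s.participant_id,
            "date": s.date.isoformat(),
            "wear_minutes": s.wear_minutes,
            "mvpa_minutes": s.mvpa_minutes,
            "is_valid": int(s.is_valid),
            "is_school_day": int(s.is_school_day),
        }
        rec.update({f"mvpa_h{h:02d}": s.hourly_mvpa[h] for h in range(24)})
        rec.update({f"wear_h{h:02d}": s.hourly_wear[h] for h in range(24)})
        recs.append(rec)
    note = [
        CONVENTION_NOTE,
        f"min_wear_min={params.min_wear_min}; reactivity_trim_days={params.reactivity_trim_days}; "
        f"min_valid_days={params.min_valid_days}",
        f"nonwear: >={params.nonwear_window_min} min zeros, <= {params.nonwear_spike_max} "
        f"interrupt min < {params.nonwear_spike_ceiling} counts",
        f"cutpoints (per {params.cutpoints.native_epoch_s}s {params.cutpoints.channel}): "
        f"light>={params.cutpoints.light}, moderate>={params.cutpoints.moderate}, "
        f"vigorous>={params.cutpoints.vigorous}",
    ]
    _write_with_header(pd.DataFrame(recs), Path(path), note)


def read_day_summaries(path: str | Path) -> list[preprocess.DaySummary]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(
            preprocess.DaySummary(
                participant_id=str(r["participant_id"]),
                date=pd.Timestamp(r["date"]).date(),
                wear_minutes=float(r["wear_minutes"]),
                mvpa_minutes=float(r["mvpa_minutes"]),
                hourly_mvpa=np.array([r[f"mvpa_h{h:02d}"] for h in range(24)]),
                hourly_wear=np.array([r[f"wear_h{h:02d}"] for h in range(24)]),
                is_valid=bool(r["is_valid"]),
                is_school_day=bool(r["is_school_day"]),
                reactivity_screened=True,
            )
        )
    return out


def write_person_period(table: pd.DataFrame, path: str | Path, risk_window: tuple) -> None:
    _write_with_header(
        table,
        Path(path),
        [CONVENTION_NOTE, f"risk window: intervals ending {risk_window[0]}..{risk_window[1]}"],
    )


# ---------------------------------------------------------------------------
# pipeline stages


def stage_preprocess(cfg: PipelineConfig) -> tuple[list, list[dict]]:
    series, errors = read_epoch_csv(cfg.epoch_csv)
    if not series:
        raise RuntimeError("preprocess: no epoch data found in input")
    calendar = read_calendar(cfg.calendar_csv)
    summaries = [preprocess.process_series(s, calendar, cfg.params) for s in series]
    kept, log = preprocess.apply_inclusion_rules(summaries, cfg.params)
    log = [{"stage": "read", **e} for e in errors] + log
    return kept, log


def stage_events(cfg: PipelineConfig, kept: list) -> tuple[pd.DataFrame, dict, list[dict]]:
    covariates = read_covariates(cfg.covariate_csv)
    by_pid: dict[str, list] = {}
    for s in kept:
        by_pid.setdefault(s.participant_id, []).append(s)
    means = {pid: events.person_mean_mvpa(days) for pid, days in by_pid.items()}
    table, log = events.build_person_period(
        kept, means, covariates, risk_window=cfg.risk_window
    )
    return table, means, log


def stage_analyze(cfg: PipelineConfig, table: pd.DataFrame) -> dict:
    degree, fits, trail = hazard.select_time_polynomial(
        table, max_degree=cfg.max_degree, alpha=cfg.alpha, n_quad=cfg.n_quad
    )
    moderated = {
        mod: hazard.fit_moderator_model(table, mod, degree, n_quad=cfg.n_quad)
        for mod in cfg.moderators
    }
    return {
        "degree": degree,
        "base_fit": fits[degree],
        "fits_by_degree": fits,
        "lrt_trail": trail,
        "moderated": moderated,
    }


_GROUP_PROFILES = {
    "sex": [("male", {"male": 1}), ("female", {})],
    "sports": [("sports", {"sports": 1}), ("no_sports", {})],
    "school_day": [("school_day", {"school_day": 1}), ("nonschool_day", {})],
    "bmi_category": [
        ("overweight", {"bmi_overweight": 1}),
        ("obese", {"bmi_obese": 1}),
        ("normal", {}),
    ],
}


def stage_report(cfg: PipelineConfig, analysis: dict, out_dir: str | Path | None = None):
    """Effect tables, group comparisons and the decision report; writes files."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = cfg.risk_window
    hours = np.arange(cfg.reference_hour, hi + 1)

    base = analysis["base_fit"]
    overall = effects.effect_table(base, cfg.reference_hour, None, hours)
    _write_with_header(
        overall.drop(columns=[]), out / "hazard_survival.csv",
        [CONVENTION_NOTE, "base model, covariates at reference levels, random intercept = 0"],
    )

    comparisons: dict[str, dict] = {}
    for mod, fit in analysis["moderated"].items():
        groups = _GROUP_PROFILES[mod]
        tables = {
            name: effects.effect_table(fit, cfg.reference_hour, prof, hours)
            for name, prof in groups
        }
        for name, tbl in tables.items():
            _write_with_header(
                tbl, out / f"or_table_{mod}_{name}.csv",
                [CONVENTION_NOTE, f"moderated model: {mod}; profile {name}"],
            )
        # compare the indicator group against the reference group (for BMI,
        # each non-reference category against normal; first significant one
        # drives the finding)
        name_a, _ = groups[0]
        name_b, _ = groups[-1]
        comp = effects.ci_overlap_compare(tables[name_a], tables[name_b])
        comparisons[mod] = {
            "comparison": comp,
            "group_a": name_a,
            "group_b": name_b,
            "hypothesized_group": cfg.hypotheses.get(mod, "exploratory"),
            "tables": tables,
        }

    report = decide.moderator_decision_points(
        {m: {k: v for k, v in c.items() if k != "tables"} for m, c in comparisons.items()},
        hypotheses=cfg.hypotheses,
        overall_table=overall,
        basis="peak_hazard",
        rel_tolerance=cfg.rel_tolerance,
        span=cfg.survival_span,
    )

    rows = [
        {
            "moderator": "(overall)",
            "criterion1_met": "",
            "criterion2_met": "",
            "window_start": report.overall_window.start_label,
            "window_end": report.overall_window.end_label,
            "basis": report.basis,
            "rationale": "",
        }
    ]
    for mod, f in report.moderator_findings.items():
        rows.append(
            {
                "moderator": mod,
                "criterion1_met": int(f.criterion1_met),
                "criterion2_met": int(f.criterion2_met),
                "window_start": f.window.start_label if f.window else "",
                "window_end": f.window.end_label if f.window else "",
                "basis": f.window.basis if f.window else "",
                "rationale": f.rationale,
            }
        )
    _write_with_header(pd.DataFrame(rows), out / "decision_points.csv", [CONVENTION_NOTE])

    with open(out / "report.txt", "w") as fh:
        fh.write("Decision-point report\n")
        fh.write(f"Convention: {CONVENTION_NOTE}\n\n")
        w = report.overall_window
        fh.write(
            f"Overall window ({report.basis}): {w.start_label} .. {w.end_label}\n"
        )
        for mod, f in report.moderator_findings.items():
            fh.write(f"\n{mod}: c1={f.criterion1_met} c2={f.criterion2_met}\n  {f.rationale}\n")
    return report, overall, comparisons


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """preprocess -> events -> hazard -> effects -> decide, writing all files."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    kept, ex_log = stage_preprocess(cfg)
    write_day_summaries(kept, out / "day_summaries.csv", cfg.params)

    table, means, ev_log = stage_events(cfg, kept)
    write_person_period(table, out / "person_period.csv", cfg.risk_window)

    analysis = stage_analyze(cfg, table)
    with open(out / "model_fit.json", "w") as fh:
        json.dump(
            {
                "chosen_degree": analysis["degree"],
                "lrt_trail": analysis["lrt_trail"],
                "base": analysis["base_fit"].to_record(),
                "moderated": {m: f.to_record() for m, f in analysis["moderated"].items()},
            },
            fh,
            indent=2,
        )

    report, overall, comparisons = stage_report(cfg, analysis, out)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"convention: {CONVENTION_NOTE}\n")
        fh.write(f"risk window: {cfg.risk_window}; reference hour: {cfg.reference_hour}\n")
        fh.write(f"seed: {cfg.seed}\n")
        for e in ex_log + ev_log:
            fh.write(json.dumps(e, default=str) + "\n")

    return {
        "summaries": kept,
        "person_period": table,
        "means": means,
        "analysis": analysis,
        "overall_table": overall,
        "comparisons": comparisons,
        "report": report,
        "exclusion_log": ex_log + ev_log,
    }


def simulate_to_files(config: synthesize.SimConfig, out_dir: str | Path) -> None:
    """Simulate a cohort and write the epoch/covariate/calendar/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = synthesize.simulate_cohort(config)
    write_epoch_csv(cohort.series, out / "epochs.csv")
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    cal = cohort.calendar.copy()
    cal["date"] = [d.isoformat() for d in cal["date"]]
    cal["is_school_day"] = cal["is_school_day"].astype(int)
    cal.to_csv(out / "calendar.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=str)
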