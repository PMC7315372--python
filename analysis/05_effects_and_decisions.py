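"""Odds-ratio / hazard / survival tables and intervention decision points.

Translates the fitted models into the reporting surfaces: per-hour ORs vs
the 8 AM reference with 95% CIs (overall and per moderator level), hazard
and survival probabilities, CI-overlap group comparisons, and the final
decision-point report (overall window plus per-moderator windows gated on
the two decision criteria).

Reads results/person_period.csv (refits the models — they are cheap relative
to simulation), writes or_table_*.csv, hazard_survival.csv,
decision_points.csv and report.txt under results/.
"""

import pandas as pd

from mvpatiming.io import CONVENTION_NOTE, PipelineConfig, stage_analyze, stage_report

CFG = PipelineConfig()


def main() -> None:
    table = pd.read_csv("results/person_period.csv", comment="#")
    analysis = stage_analyze(CFG, table)
    report, overall, comparisons = stage_report(CFG, analysis, "results")

    print(f"interval convention: {CONVENTION_NOTE}")
    print(overall[["hour", "odds_ratio", "hazard_prob", "survival_prob"]]
          .round(3).to_string(index=False))
    w = report.overall_window
    print(f"\noverall decision window ({report.basis}): "
          f"{w.start_label} .. {w.end_label}")
    for mod, f in report.moderator_findings.items():
        status = "window emitted" if f.window else "no window"
        print(f"  {mod}: criterion1={f.criterion1_met} criterion2={f.criterion2_met}"
              f" -> {status}")
        print(f"    {f.rationale}")


if __name__ == "__main__":
    main()
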