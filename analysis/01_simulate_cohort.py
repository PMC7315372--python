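"""Generate the synthetic adolescent cohort used by the downstream analyses.

Emulates the emulated study design: 113 adolescents, 20 days of wrist
accelerometry at 5 s epochs, evening-peaked activity with a morning-active
day-type mixture, population mean daily MVPA ~31 min (between-person SD ~31).
Writes the raw epoch CSV plus covariates/calendar/truth under
scratch/cohort/ (epoch data are large and regenerable, so they live outside
results/).

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
import time

from mvpatiming.io import simulate_to_files
from mvpatiming.synthesize import SimConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = "scratch/cohort"


def main() -> None:
    t0 = time.time()
    cfg = SimConfig(seed=SEED)
    simulate_to_files(cfg, OUT)
    print(
        f"simulated {cfg.n_participants} participants x {cfg.n_days} days "
        f"({cfg.epoch_s}s epochs) in {time.time() - t0:.1f}s -> {OUT}/"
    )
    print(
        f"population MVPA target: mean {cfg.mvpa_mean_minutes} min/day, "
        f"between-person SD {cfg.mvpa_between_sd}"
    )


if __name__ == "__main__":
    main()
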