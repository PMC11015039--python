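#!/usr/bin/env python
"""Generate the synthetic study data: instability timecourses.

Simulates confluent-culture repeat-expansion experiments at the study
conditions (10k molecules per culture, ~115 starting repeats, weekly
sampling over 4 weeks, 8 replicate cultures), under three designs:

  * a drift panel (0, 0.5, 1.0, 2.0 repeats/week) probing rate recovery,
  * a two-arm treatment design (vehicle vs a half-rate drug arm),
  * a 50/50 mixture of non-expanding and fast-expanding cells, the
    signature of a heterogeneously edited pool.

Writes peak tables and sample sheets under results/simulated/.
"""

from pathlib import Path

from repeatgain.peak_io import write_peak_table
from repeatgain.simulate import SimulationConfig, TimecourseDesign, simulate_timecourse

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20240412


def emit(name: str, cfg: SimulationConfig, design: TimecourseDesign) -> None:
    table, sheet = simulate_timecourse(cfg, design)
    write_peak_table(table, OUT / f"{name}.peaks.tsv")
    sheet.to_csv(OUT / f"{name}.samples.csv", index=False)
    print(f"{name}: {len(table)} traces -> {OUT / (name + '.peaks.tsv')}")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for drift in (0.0, 0.5, 1.0, 2.0):
        emit(
            f"drift_{str(drift).replace('.', 'p')}",
            SimulationConfig(seed=SEED + int(drift * 10), drift_per_week=drift),
            TimecourseDesign(n_replicates=8),
        )
    emit(
        "treated",
        SimulationConfig(seed=SEED + 100, drift_per_week=1.0),
        TimecourseDesign(
            clones=("clone1", "clone2"),
            treatments={"DMSO": 1.0, "drugA_high": 0.5},
            n_replicates=8,
        ),
    )
    emit(
        "edited_pool",
        SimulationConfig(seed=SEED + 200, mixture=((0.5, 0.0), (0.5, 2.0))),
        TimecourseDesign(n_replicates=8, timepoints_days=(0, 7, 14, 21, 28, 35, 42)),
    )


if __name__ == "__main__":
    main()
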