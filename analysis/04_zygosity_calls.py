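#!/usr/bin/env python
"""Zygosity calling on simulated CRISPR clone outcome tables.

Simulates amplicon outcome tables for 100 homozygous and 100 heterozygous
clones at 2% sequencing noise, applies the 85%-of-top-two rule, and
reports call accuracy against the simulation truth.  A 20% noise stress
run is reported alongside (not asserted anywhere) to show where the rule
starts to erode.
"""

from pathlib import Path

from repeatgain.simulate import EditingTruth, simulate_editing_outcomes
from repeatgain.zygosity import call_zygosity_table

OUT = Path(__file__).resolve().parents[1] / "results" / "zygosity"
SEED = 20240412


def run(error_rate: float, name: str) -> None:
    truths = []
    for i in range(100):
        truths.append(EditingTruth(f"hom{i}", "homozygous", ("+1A",)))
        truths.append(EditingTruth(f"het{i}", "heterozygous", ("+1A", "-2del")))
    table = simulate_editing_outcomes(truths, error_rate=error_rate, seed=SEED)
    calls = call_zygosity_table(table)
    calls.to_csv(OUT / f"{name}.calls.csv", index=False)
    truth = {t.clone_id: t.zygosity for t in truths}
    correct = sum(truth[r.clone_id] == r.call for r in calls.itertuples())
    print(
        f"noise {error_rate:.0%}: {correct}/{len(truths)} clones called "
        f"correctly -> {OUT / (name + '.calls.csv')}"
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    run(0.02, "noise_2pct")
    run(0.20, "noise_20pct_stress")


if __name__ == "__main__":
    main()
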