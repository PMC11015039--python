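#!/usr/bin/env python
"""Vehicle-normalized treatment contrasts on the simulated treated study.

Normalizes each lineage's gain per week to its clone's DMSO mean, then
contrasts the drug arm against vehicle with a two-tailed Welch t-test on
the fold-change scale.  The simulated drug halves the expansion rate, so
the expected fold change is 0.5.
"""

from pathlib import Path

import pandas as pd

from repeatgain.cohort import compare_groups, contrast_table, normalize_to_vehicle

METRICS = Path(__file__).resolve().parents[1] / "results" / "metrics"
OUT = Path(__file__).resolve().parents[1] / "results" / "contrasts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lineages = pd.read_csv(METRICS / "treated.gain_per_week.csv")
    norm = normalize_to_vehicle(lineages, vehicle_label="DMSO")
    norm.to_csv(OUT / "treated.normalized.csv", index=False)

    vehicle = norm.loc[norm["treatment"] == "DMSO", "relative_gain_per_week"]
    contrasts = []
    for treatment, grp in norm.groupby("treatment"):
        if treatment == "DMSO":
            continue
        res = compare_groups(
            grp["relative_gain_per_week"], vehicle,
            scale="ratio", label_a=str(treatment), label_b="DMSO",
        )
        contrasts.append(res)
        print(
            f"{treatment} vs DMSO: fold change {res.estimate:.3f} "
            f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), p = {res.p_value:.2e}"
        )
    contrast_table(contrasts).to_csv(OUT / "treated.contrasts.csv", index=False)


if __name__ == "__main__":
    main()
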