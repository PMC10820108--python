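#!/usr/bin/env python
"""Assemble the survey-style report tables and check parameter recovery.

Reads the scored table and the generator's truth table, then writes to
results/: the launch-year composition matrix (counts and row percentages),
the bubble-plot data (mean NRF6.4 vs mean energy density, sized by n), and
a recovery table comparing pipeline-estimated per-category means of energy
density, added sugar and fiber against the configured generative values
(difference in units of the standard error).  A bubble-plot image goes to
scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snackprofiler import reporting, synthetic_data

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    src = SCRATCH / "scored.csv"
    if not src.exists():
        raise SystemExit("scratch/scored.csv not found - run analysis/03_score.py first")
    scored = pd.read_csv(src)
    summary = reporting.summarize_by_category(scored)

    launch = reporting.launch_matrix(scored)
    launch.counts.to_csv(RESULTS / "launch_matrix_counts.csv")
    launch.row_percent.to_csv(RESULTS / "launch_matrix_percent.csv")

    bubble = reporting.bubble_plot_data(summary)
    bubble.to_csv(RESULTS / "bubble_data.csv", index=False)
    reporting.bubble_plot(summary, SCRATCH / "bubble_plot.png")

    targets = {
        "energy_density_100g": synthetic_data.REFERENCE_ENERGY_100G,
        "added_sugar_100g": synthetic_data.REFERENCE_ADDED_SUGAR_100G,
        "fiber_100g": synthetic_data.REFERENCE_FIBER_100G,
    }
    rows = []
    for metric, table in targets.items():
        for category, (target_mean, _) in table.items():
            row = summary.set_index("category").loc[category]
            se = row[f"{metric}_sd"] / np.sqrt(row["n"])
            rows.append(
                {
                    "metric": metric,
                    "category": category,
                    "configured_mean": target_mean,
                    "recovered_mean": round(float(row[f"{metric}_mean"]), 2),
                    "abs_error_in_se": round(abs(row[f"{metric}_mean"] - target_mean) / se, 2) if se > 0 else 0.0,
                }
            )
    recovery = pd.DataFrame(rows)
    recovery.to_csv(RESULTS / "recovery_check.csv", index=False)

    print(launch.counts.to_string())
    print("\nworst recovery cells (error in SE units):")
    print(recovery.sort_values("abs_error_in_se", ascending=False).head(8).to_string(index=False))
    n_within = int((recovery["abs_error_in_se"] <= 2.0).sum())
    print(f"\n{n_within}/{len(recovery)} category means within 2 SE of configured values")


if __name__ == "__main__":
    main()
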