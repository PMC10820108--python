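#!/usr/bin/env python
"""Generate the synthetic fruit-snack market snapshot.

Draws a market table under the default generative configuration — nine
categories at their surveyed launch counts (2,405 core products), label
coding artifacts, duplicates and contaminants — and writes the raw product
table plus the hidden truth table to scratch/ (large intermediates) and a
compact coding-rate summary to results/.
"""

from pathlib import Path

import pandas as pd

from snackprofiler import gnpd_io, synthetic_data

SEED = 17
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = synthetic_data.default_config(seed=SEED)
    records, truth = synthetic_data.generate(cfg)
    gnpd_io.write_products(records, SCRATCH / "products.csv")
    truth.to_csv(SCRATCH / "truth_table.csv", index=False)

    n = len(records)
    coding = pd.DataFrame(
        [
            ("records_emitted", n),
            ("fiber_cells_censored", sum(r.panel["fiber"].is_censored for r in records)),
            ("records_missing_a_required_nutrient",
             sum(any(r.panel[x].is_missing for x in ("added_sugar", "vitamin_d", "calcium", "iron"))
                 for r in records if r.has_label())),
            ("out_of_scope_rows", int((truth["role"] == "out_of_scope").sum())),
            ("no_label_rows", int((truth["role"] == "no_label").sum())),
            ("duplicate_rows", int((truth["role"] == "duplicate").sum())),
            ("dual_label_rows", int((truth["role"] == "dual_sibling").sum())),
        ],
        columns=["quantity", "count"],
    )
    coding.to_csv(RESULTS / "simulation_coding_summary.csv", index=False)
    print(f"wrote {n} records (seed {SEED}) to {SCRATCH / 'products.csv'}")
    print(coding.to_string(index=False))


if __name__ == "__main__":
    main()
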