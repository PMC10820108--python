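#!/usr/bin/env python
"""Score the cleaned products with the NRF6.4 model.

Reads scratch/cleaned.csv, re-derives each product's category (the rule set
is deterministic), computes NR, LIM, NRF6.4, energy density and per-100 g /
per-RACC added sugar and fiber, and writes the scored table to scratch/ and
the per-category mean/SD summary (display-rounded to 1 decimal) to results/.
"""

from pathlib import Path

from snackprofiler import categorize, gnpd_io, nrf_scoring, reporting

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    src = SCRATCH / "cleaned.csv"
    if not src.exists():
        raise SystemExit("scratch/cleaned.csv not found - run analysis/02_clean_classify.py first")
    records = gnpd_io.read_products(src)
    in_scope, out_of_scope = categorize.classify_all(records)
    assert not out_of_scope, "cleaned table should contain only in-scope products"

    scored, excluded = nrf_scoring.score_table(in_scope)
    if excluded:
        print(f"note: {len(excluded)} products excluded at scoring (non-positive energy)")
    scored.to_csv(SCRATCH / "scored.csv", index=False)

    summary = reporting.summarize_by_category(scored)
    reporting.display_round(summary).to_csv(RESULTS / "category_summary.csv", index=False)
    cols = ["category", "n", "nr_mean", "lim_mean", "nrf64_mean",
            "energy_density_100g_mean", "added_sugar_100g_mean", "fiber_100g_mean"]
    print(reporting.display_round(summary)[cols].to_string(index=False))
    print(f"scored {len(scored)} products -> {SCRATCH / 'scored.csv'}")


if __name__ == "__main__":
    main()
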