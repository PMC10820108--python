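#!/usr/bin/env python
"""Screen, classify and clean the raw product table.

Reads scratch/products.csv (from 01_simulate.py), removes out-of-scope and
unlabeled products, deduplicates, averages dual labels, imputes "<x" label
codes, drops records missing the newly mandated nutrients, and normalizes
serving sizes.  Writes the cleaned table to scratch/ and the exclusion
ledger (the screening audit trail) to results/.
"""

from pathlib import Path

from snackprofiler import categorize, cleaning, gnpd_io

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    src = SCRATCH / "products.csv"
    if not src.exists():
        raise SystemExit("scratch/products.csv not found - run analysis/01_simulate.py first")
    records = gnpd_io.read_products(src)
    ledger = gnpd_io.ExclusionLedger(len(records))

    in_scope, out_of_scope = categorize.classify_all(records)
    ledger.record("out_of_scope", len(out_of_scope))
    result = cleaning.clean(in_scope, ledger=ledger)

    gnpd_io.write_products(result.records, SCRATCH / "cleaned.csv")
    result.ledger.to_csv(RESULTS / "exclusion_ledger.csv")
    print(result.ledger.log_block())
    print(f"cleaned table: {len(result.records)} products -> {SCRATCH / 'cleaned.csv'}")


if __name__ == "__main__":
    main()
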