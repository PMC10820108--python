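#!/usr/bin/env python
"""Compare the nine categories metric by metric.

Reads scratch/scored.csv and, for NRF6.4, energy density, and per-100 g /
per-RACC added sugar and fiber, runs the tie-corrected Kruskal-Wallis
omnibus test, Dunn's pairwise post hoc z-tests with Holm adjustment, and
derives compact letter displays.  Writes the omnibus table, the long-format
pairwise table, and the letters to results/.
"""

from pathlib import Path

import pandas as pd

from snackprofiler import reporting

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    src = SCRATCH / "scored.csv"
    if not src.exists():
        raise SystemExit("scratch/scored.csv not found - run analysis/03_score.py first")
    scored = pd.read_csv(src)

    kw_rows, pair_frames, letters = [], [], {}
    for metric in reporting.LETTER_METRICS:
        lmap, kw, pairwise = reporting.metric_letters(scored, metric)
        letters[metric] = lmap
        kw_rows.append({"metric": metric, "h": kw.h, "df": kw.df, "p": kw.p})
        pair_frames.append(
            pd.DataFrame(
                [
                    {"metric": metric, "group_a": r.pair[0], "group_b": r.pair[1],
                     "z": r.z, "p_raw": r.p_raw, "p_adj": r.p_adj, "significant": r.significant}
                    for r in pairwise
                ]
            )
        )

    kw_df = pd.DataFrame(kw_rows)
    kw_df.to_csv(RESULTS / "kruskal_wallis.csv", index=False)
    pd.concat(pair_frames, ignore_index=True).to_csv(RESULTS / "dunn_pairwise.csv", index=False)
    letters_df = pd.DataFrame(letters)
    letters_df.index.name = "category"
    letters_df.to_csv(RESULTS / "letters.csv")

    print(kw_df.to_string(index=False))
    print("\ncompact letters (share a letter <=> not significantly different):")
    print(letters_df.to_string())


if __name__ == "__main__":
    main()
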