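"""Pipeline orchestration and survey-style reporting.

Produces the study's summary artifacts from a scored product table:
per-category mean/SD summaries with significance letters, the launch-year
composition matrix, bubble-plot data (mean NRF6.4 against mean energy
density, sized by category count), the exclusion ledger, and a run manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import categorize, cleaning, gnpd_io, group_stats, nrf_scoring, synthetic_data

logger = logging.getLogger(__name__)

#: metrics summarized per category, in display order
SUMMARY_METRICS = (
    "nr",
    "lim",
    "nrf64",
    "energy_density_100g",
    "energy_racc",
    "added_sugar_100g",
    "added_sugar_racc",
    "fiber_100g",
    "fiber_racc",
)

#: metrics for which pairwise letters are computed (score and content columns)
LETTER_METRICS = (
    "nrf64",
    "energy_density_100g",
    "added_sugar_100g",
    "added_sugar_racc",
    "fiber_100g",
    "fiber_racc",
)


def metric_letters(
    scored: pd.DataFrame,
    metric: str,
    alpha: float = group_stats.DEFAULT_ALPHA,
) -> tuple[dict[str, str], group_stats.KruskalResult, list[group_stats.PairwiseResult]]:
    """Omnibus test, pairwise post hoc and letter display for one metric."""
    groups = [
        group_stats.GroupSample(cat, sub[metric].to_numpy())
        for cat, sub in scored.groupby("category", sort=True)
        if len(sub) > 0
    ]
    kw = group_stats.kruskal_wallis(groups)
    pairwise = group_stats.dunn_posthoc(groups, alpha=alpha)
    letters = group_stats.compact_letters(pairwise, [g.label for g in groups])
    return letters, kw, pairwise


def summarize_by_category(
    scored: pd.DataFrame,
    letters: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-category n and mean/SD (sample SD, n-1 denominator) per metric.

    ``letters`` maps metric -> {category -> letter string}; when given, a
    ``<metric>_letters`` column is attached.  Empty categories are omitted
    with a warning.  Means/SDs are reported at full precision; display
    rounding is the caller's concern.
    """
    if scored.empty:
        return pd.DataFrame()
    rows = []
    for cat in categorize.CATEGORIES:
        sub = scored[scored["category"] == cat]
        if sub.empty:
            logger.warning("category %s has no scored products; omitted from summary", cat)
            continue
        row: dict[str, object] = {"category": cat, "n": int(len(sub))}
        for metric in SUMMARY_METRICS:
            row[f"{metric}_mean"] = float(sub[metric].mean())
            row[f"{metric}_sd"] = float(sub[metric].std(ddof=1)) if len(sub) > 1 else 0.0
        if len(sub) == 1:
            row["n1_flag"] = True
        if letters:
            for metric, lmap in letters.items():
                row[f"{metric}_letters"] = lmap.get(cat, "")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LaunchMatrix:
    counts: pd.DataFrame       # category x year counts with row/col totals
    row_percent: pd.DataFrame  # whole-percent share of each year within category


def launch_matrix(
    scored: pd.DataFrame,
    years: Sequence[int] = synthetic_data.YEARS,
) -> LaunchMatrix:
    """Category-by-launch-year composition with row percentages.

    Rows sum to the category total; the grand total equals both the row and
    column total sums.  Records launched outside ``years`` are excluded with
    a warning.
    """
    if scored.empty:
        return LaunchMatrix(pd.DataFrame(), pd.DataFrame())
    df = scored.dropna(subset=["launch_year"]).copy()
    df["launch_year"] = df["launch_year"].astype(int)
    outside = ~df["launch_year"].isin(years)
    if outside.any():
        logger.warning("%d records launched outside the study window excluded", int(outside.sum()))
        df = df[~outside]
    counts = (
        df.pivot_table(index="category", columns="launch_year", values="record_id", aggfunc="count", fill_value=0)
        .reindex(columns=list(years), fill_value=0)
    )
    counts = counts.reindex([c for c in categorize.CATEGORIES if c in counts.index])
    row_totals = counts.sum(axis=1)
    pct = (counts.div(row_totals.replace(0, np.nan), axis=0) * 100).round(0).fillna(0).astype(int)
    counts["total"] = row_totals
    counts.loc["total"] = counts.sum(axis=0)
    return LaunchMatrix(counts=counts, row_percent=pct)


def bubble_plot_data(summary: pd.DataFrame) -> pd.DataFrame:
    """One row per category: mean energy density vs mean NRF6.4, sized by n."""
    if summary.empty:
        return pd.DataFrame(columns=["category", "energy_density_100g_mean", "nrf64_mean", "n"])
    return summary[["category", "energy_density_100g_mean", "nrf64_mean", "n"]].copy()


def bubble_plot(summary: pd.DataFrame, path: str | Path) -> Path:
    """Optional rendering of the bubble data (data CSV is the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = bubble_plot_data(summary)
    fig, ax = plt.subplots(figsize=(7, 5))
    sizes = 2000 * data["n"] / data["n"].sum()
    ax.scatter(data["energy_density_100g_mean"], data["nrf64_mean"], s=sizes, alpha=0.6)
    for _, row in data.iterrows():
        ax.annotate(row["category"], (row["energy_density_100g_mean"], row["nrf64_mean"]), fontsize=7)
    ax.set_xlabel("mean energy density (kcal/100 g)")
    ax.set_ylabel("mean NRF6.4 score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    records: list  # cleaned ProductRecords
    scored: pd.DataFrame
    summary: pd.DataFrame
    ledger: gnpd_io.ExclusionLedger
    launch: LaunchMatrix
    kruskal: pd.DataFrame
    pairwise: pd.DataFrame
    letters: dict[str, dict[str, str]]
    truth: pd.DataFrame | None = None


def run_pipeline(
    input_path: str | Path | None = None,
    *,
    simulate: bool = False,
    sim_config: synthetic_data.SimConfig | None = None,
    cleaning_config: cleaning.CleaningConfig | None = None,
    ruleset=None,
    daily_values: Mapping[str, float] | None = None,
    racc: Mapping[str, float] | None = None,
    alpha: float = group_stats.DEFAULT_ALPHA,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    schema: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run ingestion -> classification -> cleaning -> scoring -> statistics.

    Either ``input_path`` (a product CSV) or ``simulate=True`` (with an
    optional ``sim_config``; ``seed`` overrides its seed) must be given.
    When ``out_dir`` is set, all artifacts are written there.
    """
    truth = None
    if simulate:
        cfg = sim_config or synthetic_data.default_config()
        if seed is not None:
            cfg.seed = seed
        records, truth = synthetic_data.generate(cfg)
    elif input_path is not None:
        records = gnpd_io.read_products(input_path, schema=schema)
    else:
        raise ValueError("provide input_path or simulate=True")

    ledger = gnpd_io.ExclusionLedger(len(records))
    in_scope, out_of_scope = categorize.classify_all(records, ruleset)
    ledger.record("out_of_scope", len(out_of_scope))

    cleaned = cleaning.clean(in_scope, cleaning_config, ledger)
    scored, scoring_exclusions = nrf_scoring.score_table(cleaned.records, daily_values, racc)
    ledger.record("nonpositive_energy", len(scoring_exclusions))
    ledger.check_conservation()
    if scored.empty:
        raise RuntimeError("no products survived screening; nothing to score")

    letters: dict[str, dict[str, str]] = {}
    kw_rows = []
    pair_frames = []
    n_categories = scored["category"].nunique()
    for metric in LETTER_METRICS:
        if n_categories < 2:
            break
        lmap, kw, pairwise = metric_letters(scored, metric, alpha)
        letters[metric] = lmap
        kw_rows.append({"metric": metric, "h": kw.h, "df": kw.df, "p": kw.p})
        pair_frames.append(group_stats.pairwise_frame(pairwise, metric))
    kruskal = pd.DataFrame(kw_rows)
    pairwise_df = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()

    summary = summarize_by_category(scored, letters)
    launch = launch_matrix(scored)
    result = PipelineResult(
        records=cleaned.records,
        scored=scored,
        summary=summary,
        ledger=ledger,
        launch=launch,
        kruskal=kruskal,
        pairwise=pairwise_df,
        letters=letters,
        truth=truth,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir), seed=seed, sim_config=sim_config if simulate else None)
    return result


def _config_hash(obj: object) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _write_artifacts(result: PipelineResult, out_dir: Path, seed: int | None, sim_config) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    gnpd_io.write_products(result.records, out_dir / "cleaned_products.csv")
    result.scored.to_csv(out_dir / "scored_products.csv", index=False)
    result.summary.to_csv(out_dir / "category_summary.csv", index=False)
    result.ledger.to_csv(out_dir / "exclusion_ledger.csv")
    if not result.launch.counts.empty:
        result.launch.counts.to_csv(out_dir / "launch_matrix_counts.csv")
        result.launch.row_percent.to_csv(out_dir / "launch_matrix_percent.csv")
    result.kruskal.to_csv(out_dir / "kruskal_wallis.csv", index=False)
    if not result.pairwise.empty:
        result.pairwise.to_csv(out_dir / "dunn_pairwise.csv", index=False)
    letters_df = pd.DataFrame(result.letters).fillna("")
    letters_df.index.name = "category"
    letters_df.to_csv(out_dir / "letters.csv")
    bubble_plot_data(result.summary).to_csv(out_dir / "bubble_data.csv", index=False)
    if result.truth is not None:
        result.truth.to_csv(out_dir / "truth_table.csv", index=False)
    manifest = {
        "seed": seed,
        "n_input": result.ledger.initial_count,
        "n_scored": int(len(result.scored)),
        "config_hash": _config_hash(sim_config),
        "ledger": {s.label: s.n_removed for s in result.ledger.steps},
    }
    with open(out_dir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    logger.info("pipeline artifacts written to %s", out_dir)


def display_round(summary: pd.DataFrame) -> pd.DataFrame:
    """Summary rounded for display: one decimal for means/SDs."""
    out = summary.copy()
    for col in out.columns:
        if col.endswith("_mean") or col.endswith("_sd"):
            out[col] = out[col].round(1)
    return out
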