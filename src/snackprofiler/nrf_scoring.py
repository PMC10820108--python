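"""Nutrient Rich Food scoring (NRF6.4) and serving normalizations.

The NRF *n.m* family scores a food as the sum of capped percent daily values
of *n* qualifying nutrients minus the sum of capped %DV of *m* disqualifying
nutrients, on a fixed energy basis:

    NRF6.4 = NR6 - LIM4
    NR6    = sum_i min(100, 100 * content_i / DV_i)   per 100 kcal
    LIM4   = sum_j min(100, 100 * content_j / DV_j)   per 100 kcal

with qualifying nutrients protein, dietary fiber, potassium, vitamin D,
calcium and iron, and disqualifying nutrients saturated fat, cholesterol,
added sugar and sodium — the ten nutrients mandatory on the post-2016 US
Nutrition Facts label.  Daily values follow the updated label basis
(2000 kcal diet); protein uses the FDA adult value of 50 g, which the updated
label tables omit because protein %DV is rarely printed.

Capping is applied per nutrient, after conversion to the 100 kcal basis, to
qualifying and disqualifying nutrients alike, so NR6 is bounded by 600 and
LIM4 by 400.

Besides the score the module normalizes nutrient content to 100 g and to the
FDA Reference Amount Customarily Consumed (RACC) of the product's category,
and computes energy density (kcal per 100 g of the labelled serving mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .gnpd_io import ProductRecord

#: qualifying ("nutrients to encourage") set for NR6
QUALIFYING: tuple[str, ...] = ("protein", "fiber", "potassium", "vitamin_d", "calcium", "iron")
#: disqualifying ("nutrients to limit") set for LIM4
DISQUALIFYING: tuple[str, ...] = ("saturated_fat", "cholesterol", "added_sugar", "sodium")

#: Daily values on the updated US label basis (2000 kcal diet); protein is
#: the FDA adult value.  Units match gnpd_io.NUTRIENT_UNITS.
DEFAULT_DAILY_VALUES: dict[str, float] = {
    "saturated_fat": 20.0,   # g
    "cholesterol": 300.0,    # mg
    "sodium": 2300.0,        # mg
    "fiber": 28.0,           # g
    "added_sugar": 50.0,     # g
    "potassium": 4700.0,     # mg
    "vitamin_d": 20.0,       # mcg
    "iron": 18.0,            # mg
    "calcium": 1300.0,       # mg
    "protein": 50.0,         # g
}

#: FDA Reference Amounts Customarily Consumed (grams per eating occasion)
DEFAULT_RACC_G: dict[str, float] = {
    "dried_fruit": 40.0,
    "dried_flavored_fruit": 40.0,
    "fruit_based_bar": 40.0,
    "formed_fruit": 30.0,
    "fruit_flavored_snack": 30.0,
    "fruit_chips": 30.0,
    "canned_fruit": 140.0,
    "canned_fruit_with_juice": 140.0,
    "fruit_puree": 125.0,
}


class ScoringExclusion(Exception):
    """Raised when a product cannot enter scoring (e.g. energy <= 0)."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record {record_id}: {reason}")


def validate_daily_values(dv: Mapping[str, float]) -> None:
    for nutrient in QUALIFYING + DISQUALIFYING:
        if nutrient not in dv:
            raise KeyError(f"daily-value table missing {nutrient!r}")
        if dv[nutrient] <= 0:
            raise ValueError(f"daily value for {nutrient} must be > 0")


def per_100kcal(content_per_serving: float, energy_per_serving: float) -> float:
    """Rescale a per-serving amount to the 100 kcal basis."""
    if energy_per_serving <= 0:
        raise ScoringExclusion("?", "non-positive energy per serving")
    return content_per_serving * 100.0 / energy_per_serving


def capped_percent_dv(
    content_per_100kcal: float,
    nutrient: str,
    dv: Mapping[str, float] | None = None,
) -> float:
    """%DV supplied per 100 kcal, capped at 100."""
    dv = dv if dv is not None else DEFAULT_DAILY_VALUES
    if nutrient not in dv:
        raise KeyError(f"no daily value for nutrient {nutrient!r}")
    if content_per_100kcal < 0:
        raise ValueError("content must be >= 0")
    return min(100.0, 100.0 * content_per_100kcal / dv[nutrient])


def per_100g(content_per_serving: float, serving_g: float) -> float:
    """Rescale a per-serving amount to 100 g of product."""
    if serving_g <= 0:
        raise ScoringExclusion("?", "non-positive serving mass")
    return content_per_serving * 100.0 / serving_g


def per_racc(
    content_per_100g: float,
    category: str,
    racc: Mapping[str, float] | None = None,
) -> float:
    """Rescale a per-100 g amount to the category's RACC."""
    racc = racc if racc is not None else DEFAULT_RACC_G
    if category not in racc:
        raise KeyError(f"no RACC for category {category!r}")
    return content_per_100g * racc[category] / 100.0


@dataclass(frozen=True)
class NRFResult:
    """NRF6.4 decomposition for one product (all on the 100 kcal basis)."""

    nr: float
    lim: float
    nrf64: float
    energy_density_100g: float
    breakdown: dict[str, float]  # nutrient -> capped %DV per 100 kcal

    def __post_init__(self) -> None:
        assert abs(self.nrf64 - (self.nr - self.lim)) < 1e-9


def score_nrf64(
    record: ProductRecord,
    dv: Mapping[str, float] | None = None,
) -> NRFResult:
    """Score one cleaned product.

    Requires a fully numeric panel for the ten scored nutrients plus energy,
    a positive energy per serving and a positive serving mass; cleaning is
    expected to have excluded anything else.
    """
    dv = dv if dv is not None else DEFAULT_DAILY_VALUES
    validate_daily_values(dv)
    for nutrient in ("energy",) + QUALIFYING + DISQUALIFYING:
        if not record.panel[nutrient].is_numeric:
            raise ValueError(
                f"record {record.record_id}: {nutrient} is "
                f"{record.panel[nutrient].state.value}; clean the data first"
            )
    energy = record.numeric("energy")
    if energy <= 0:
        raise ScoringExclusion(record.record_id, "non-positive energy per serving")
    if record.serving_g is None or record.serving_g <= 0:
        raise ScoringExclusion(record.record_id, "non-positive serving mass")

    breakdown: dict[str, float] = {}
    for nutrient in QUALIFYING + DISQUALIFYING:
        amount = per_100kcal(record.numeric(nutrient), energy)
        breakdown[nutrient] = capped_percent_dv(amount, nutrient, dv)
    nr = sum(breakdown[n] for n in QUALIFYING)
    lim = sum(breakdown[n] for n in DISQUALIFYING)
    return NRFResult(
        nr=nr,
        lim=lim,
        nrf64=nr - lim,
        energy_density_100g=per_100g(energy, record.serving_g),
        breakdown=breakdown,
    )


def score_table(
    records: Sequence[ProductRecord],
    dv: Mapping[str, float] | None = None,
    racc: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[ScoringExclusion]]:
    """Score a cleaned, categorized record list into a tidy table.

    Returns the scored table (one row per product) and the exclusions hit
    (non-positive energy or serving mass).  Per-100 g and per-RACC columns
    are provided for energy, added sugar and fiber.
    """
    racc = racc if racc is not None else DEFAULT_RACC_G
    rows = []
    excluded: list[ScoringExclusion] = []
    for r in records:
        if r.category is None:
            raise ValueError(f"record {r.record_id} has no category; classify first")
        try:
            res = score_nrf64(r, dv)
        except ScoringExclusion as exc:
            excluded.append(exc)
            continue
        row = {
            "record_id": r.record_id,
            "category": r.category,
            "launch_year": r.launch_date.year if r.launch_date else None,
            "serving_g": r.serving_g,
            "nr": res.nr,
            "lim": res.lim,
            "nrf64": res.nrf64,
            "energy_density_100g": res.energy_density_100g,
        }
        for metric, nutrient in (("added_sugar", "added_sugar"), ("fiber", "fiber")):
            v100g = per_100g(r.numeric(nutrient), r.serving_g)
            row[f"{metric}_100g"] = v100g
            row[f"{metric}_racc"] = per_racc(v100g, r.category, racc)
        row["energy_racc"] = per_racc(res.energy_density_100g, r.category, racc)
        rows.append(row)
    return pd.DataFrame(rows), excluded
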