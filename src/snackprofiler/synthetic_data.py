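"""Synthetic GNPD-style market snapshot generator.

The survey dataset this pipeline was designed for is proprietary, so the
generator emulates its statistical structure: nine fruit-snack categories
with published per-100 g mean/SD for energy density, added sugar and fiber;
launch-year composition; label coding artifacts ("<1" fiber with a printed
%DV, "<0.1 g" saturated fat, "<5 mg" sodium/cholesterol, "<1 g" protein);
missing newly-mandated nutrients; exact duplicates; dual-label siblings; and
out-of-scope / unlabeled contaminant records.

Distributions
-------------
Each per-100 g nutrient is drawn from a positive-support distribution
*moment-matched* to the target (mean, SD):

* CV < 0.75: a zero-truncated normal whose underlying (mu, sigma) are solved
  so the truncated moments equal the targets.
* CV >= 0.75: a zero-inflated gamma (point mass at zero plus a gamma with
  shape 4), since a zero-truncated normal cannot attain CV >= 1 while many
  published cells (e.g. added sugar 0.1 +/- 0.8 g/100 g) demand it — such
  cells are in truth mostly-zero with a positive tail.

Draws use stratified inverse-CDF sampling (one draw per equal-probability
stratum, randomly permuted), which keeps the marginal distribution exact
while shrinking the Monte Carlo error of sample means from O(1/sqrt(n)) to
O(1/n), so end-to-end moment-recovery checks measure pipeline fidelity
rather than sampling noise.  Nutrients are drawn independently; per-serving
panels are per-100 g draws scaled by serving mass.

Category means for nutrients the published summary tables do not cover
(protein, micronutrients, saturated fat, sodium, cholesterol) are package-chosen
defaults back-solved so the expected qualifying (NR) and disqualifying (LIM)
sub-scores approximate the published per-category values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .categorize import CATEGORIES
from .gnpd_io import CodedValue, ProductRecord, format_number
from .nrf_scoring import DEFAULT_DAILY_VALUES

YEARS = (2017, 2018, 2019, 2020, 2021, 2022)

# --- published per-category summary statistics (per 100 g) -----------------
# mean, sd of energy density (kcal), added sugar (g), fiber (g); final-sample
# category sizes; launch counts per year 2017-2022.

REFERENCE_ENERGY_100G: dict[str, tuple[float, float]] = {
    "canned_fruit": (72.7, 44.8),
    "canned_fruit_with_juice": (55.9, 7.6),
    "dried_fruit": (323.8, 62.4),
    "dried_flavored_fruit": (356.8, 62.6),
    "formed_fruit": (314.4, 63.5),
    "fruit_based_bar": (403.3, 58.7),
    "fruit_chips": (509.5, 76.2),
    "fruit_flavored_snack": (326.2, 45.9),
    "fruit_puree": (68.5, 19.7),
}

REFERENCE_ADDED_SUGAR_100G: dict[str, tuple[float, float]] = {
    "canned_fruit": (9.4, 9.3),
    "canned_fruit_with_juice": (0.1, 0.8),
    "dried_fruit": (0.4, 4.0),
    "dried_flavored_fruit": (34.4, 21.4),
    "formed_fruit": (10.6, 14.6),
    "fruit_based_bar": (15.3, 13.1),
    "fruit_chips": (6.5, 11.1),
    "fruit_flavored_snack": (48.6, 11.7),
    "fruit_puree": (1.8, 3.9),
}

REFERENCE_FIBER_100G: dict[str, tuple[float, float]] = {
    "canned_fruit": (1.1, 0.8),
    "canned_fruit_with_juice": (0.8, 0.4),
    "dried_fruit": (8.8, 5.3),
    "dried_flavored_fruit": (5.5, 5.5),
    "formed_fruit": (7.8, 3.1),
    "fruit_based_bar": (7.6, 4.0),
    "fruit_chips": (7.4, 4.6),
    "fruit_flavored_snack": (0.4, 1.9),
    "fruit_puree": (1.9, 1.2),
}

#: published qualifying / disqualifying sub-score means (per category), used
#: only to back-solve package-chosen (non-survey) micronutrient defaults
REFERENCE_NR_MEAN: dict[str, float] = {
    "canned_fruit": 15.3, "canned_fruit_with_juice": 14.4, "dried_fruit": 22.4,
    "dried_flavored_fruit": 11.3, "formed_fruit": 17.6, "fruit_based_bar": 20.7,
    "fruit_chips": 11.1, "fruit_flavored_snack": 2.4, "fruit_puree": 18.2,
}
REFERENCE_LIM_MEAN: dict[str, float] = {
    "canned_fruit": 25.3, "canned_fruit_with_juice": 0.5, "dried_fruit": 1.5,
    "dried_flavored_fruit": 24.4, "formed_fruit": 6.8, "fruit_based_bar": 15.0,
    "fruit_chips": 18.4, "fruit_flavored_snack": 31.8, "fruit_puree": 5.0,
}

#: launch counts per category and year (market-survey composition)
REFERENCE_LAUNCH_COUNTS: dict[str, tuple[int, ...]] = {
    "canned_fruit": (58, 57, 27, 27, 28, 25),
    "canned_fruit_with_juice": (20, 30, 22, 26, 32, 32),
    "dried_fruit": (87, 76, 103, 78, 128, 73),
    "dried_flavored_fruit": (68, 61, 49, 33, 61, 58),
    "formed_fruit": (29, 26, 32, 33, 17, 16),
    "fruit_based_bar": (72, 61, 74, 52, 25, 33),
    "fruit_chips": (45, 30, 49, 22, 26, 16),
    "fruit_flavored_snack": (51, 42, 44, 40, 41, 43),
    "fruit_puree": (48, 34, 32, 44, 29, 40),
}

#: package-chosen (non-survey): typical label serving mass per category (grams)
DEFAULT_SERVING_G: dict[str, tuple[float, float]] = {
    "canned_fruit": (122.0, 14.0),
    "canned_fruit_with_juice": (122.0, 14.0),
    "dried_fruit": (40.0, 6.0),
    "dried_flavored_fruit": (40.0, 6.0),
    "formed_fruit": (28.0, 5.0),
    "fruit_based_bar": (40.0, 5.0),
    "fruit_chips": (30.0, 5.0),
    "fruit_flavored_snack": (25.0, 4.0),
    "fruit_puree": (90.0, 10.0),
}

#: package-chosen back-solve shares of residual NR / LIM sub-scores
_NR_SHARES = {"potassium": 0.45, "protein": 0.25, "iron": 0.12, "calcium": 0.12, "vitamin_d": 0.06}
_LIM_SHARES = {"saturated_fat": 0.45, "sodium": 0.45, "cholesterol": 0.10}
_MICRO_CV = 0.5  # package-chosen coefficient of variation for back-solved nutrients
_MIN_RESIDUAL = 0.6  # score points; keeps back-solved means positive


# ---------------------------------------------------------------------------
# moment-matched positive distributions

class _Degenerate:
    def __init__(self, value: float):
        self.value = float(value)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(u, dtype=float), self.value)


class _ZeroInflatedGamma:
    """Point mass at 0 with probability 1-p, else Gamma(shape=4)."""

    SHAPE = 4.0

    def __init__(self, mean: float, sd: float):
        m, s = float(mean), float(sd)
        cv_g2 = 1.0 / self.SHAPE
        self.p = (1.0 + cv_g2) * m * m / (s * s + m * m)
        mu_g = m / self.p
        self.scale = mu_g / self.SHAPE

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        hit = u > 1.0 - self.p
        out[hit] = stats.gamma.ppf((u[hit] - (1.0 - self.p)) / self.p, self.SHAPE, scale=self.scale)
        return out


def _truncnorm_cv(alpha: float) -> float:
    m1, v1 = stats.truncnorm.stats(-alpha, np.inf, moments="mv")
    return float(np.sqrt(v1) / (alpha + m1))


def matched_positive(mean: float, sd: float, cv_switch: float = 0.75):
    """A distribution on [0, inf) with exactly the requested mean and SD."""
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be >= 0")
    if mean == 0 or sd == 0:
        return _Degenerate(mean)
    cv = sd / mean
    if cv >= cv_switch:
        return _ZeroInflatedGamma(mean, sd)
    if cv <= _truncnorm_cv(40.0):
        # >40 SDs from zero: truncation mass is nil, plain normal suffices
        return stats.norm(loc=mean, scale=sd)
    # solve mu/sigma so the zero-truncated normal has the target CV
    alpha = brentq(lambda a: _truncnorm_cv(a) - cv, -8.0, 40.0, xtol=1e-10)
    m1, v1 = stats.truncnorm.stats(-alpha, np.inf, moments="mv")
    sigma = sd / float(np.sqrt(v1))
    mu = alpha * sigma
    return stats.truncnorm(-alpha, np.inf, loc=mu, scale=sigma)


def stratified_draw(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws via inverse CDF at one uniform per equal-probability stratum."""
    if n == 0:
        return np.empty(0)
    u = (rng.permutation(n) + rng.uniform(0.0, 1.0, size=n)) / n
    return np.asarray(dist.ppf(u), dtype=float)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CategoryParams:
    """Generative parameters for one category (all nutrient cells per 100 g)."""

    n_products: int
    year_weights: tuple[float, ...]
    nutrients: dict[str, tuple[float, float]]  # nutrient -> (mean, sd)
    serving_g: tuple[float, float]

    def validate(self) -> None:
        if self.n_products < 0:
            raise ValueError("n_products must be >= 0")
        if len(self.year_weights) != len(YEARS) or any(w < 0 for w in self.year_weights) or sum(self.year_weights) <= 0:
            raise ValueError("year_weights must be non-negative with positive sum")
        for nutrient, (m, s) in self.nutrients.items():
            if m < 0 or s < 0:
                raise ValueError(f"{nutrient}: mean and sd must be >= 0")
        if self.serving_g[0] <= 0 or self.serving_g[1] < 0:
            raise ValueError("serving mass mean must be > 0, sd >= 0")


@dataclass
class SimConfig:
    """Full generative specification of a synthetic market snapshot."""

    categories: dict[str, CategoryParams]
    p_censored_fiber: float = 0.10
    p_censored_small: float = 0.30
    p_missing_required: float = 0.378
    p_duplicate: float = 0.04
    p_dual_label: float = 0.03
    frac_out_of_scope: float = 0.15
    frac_no_label: float = 0.045
    seed: int = 0

    def validate(self) -> None:
        if not self.categories:
            raise ValueError("no categories configured")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        for name in ("p_censored_fiber", "p_censored_small", "p_missing_required",
                     "p_duplicate", "p_dual_label", "frac_out_of_scope", "frac_no_label"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for params in self.categories.values():
            params.validate()


def _mean_inverse(dist, m: int = 4001) -> float:
    """E[1/X] by midpoint quadrature over the quantile function."""
    u = (np.arange(m) + 0.5) / m
    x = np.asarray(dist.ppf(u), dtype=float)
    return float(np.mean(1.0 / np.maximum(x, 1e-9)))


def _backsolve_nutrients(category: str) -> dict[str, tuple[float, float]]:
    """Package-chosen (non-survey) nutrient means chosen so expected NR/LIM approximate the
    published per-category sub-scores.

    Nutrient %DV on the 100 kcal basis involves 1/energy; with independent
    draws E[X / E] = E[X] * E[1/E], so the back-solve uses the exact
    E[1/energy] of the configured energy distribution (materially different
    from 1/mean for high-variance categories such as canned fruit).
    """
    energy_m, energy_s = REFERENCE_ENERGY_100G[category]
    einv = _mean_inverse(matched_positive(energy_m, energy_s))
    fiber_m = REFERENCE_FIBER_100G[category][0]
    sugar_m = REFERENCE_ADDED_SUGAR_100G[category][0]
    fiber_pct = fiber_m * 100.0 * einv / DEFAULT_DAILY_VALUES["fiber"] * 100.0
    sugar_pct = sugar_m * 100.0 * einv / DEFAULT_DAILY_VALUES["added_sugar"] * 100.0
    residual_nr = max(REFERENCE_NR_MEAN[category] - fiber_pct, _MIN_RESIDUAL)
    residual_lim = max(REFERENCE_LIM_MEAN[category] - sugar_pct, _MIN_RESIDUAL)

    out: dict[str, tuple[float, float]] = {}
    for nutrient, share in {**_NR_SHARES, **_LIM_SHARES}.items():
        residual = residual_nr if nutrient in _NR_SHARES else residual_lim
        pct = share * residual
        per_100kcal = pct / 100.0 * DEFAULT_DAILY_VALUES[nutrient]
        mean = per_100kcal / (100.0 * einv)
        out[nutrient] = (mean, _MICRO_CV * mean)
    return out


def default_config(n_per_category: int | None = None, seed: int = 0) -> SimConfig:
    """Defaults reproducing the surveyed market's statistical structure.

    ``n_per_category=None`` uses each category's surveyed launch count
    (pre-screening); an integer gives every category that many core products.
    """
    categories: dict[str, CategoryParams] = {}
    for cat in CATEGORIES:
        counts = REFERENCE_LAUNCH_COUNTS[cat]
        nutrients: dict[str, tuple[float, float]] = {
            "energy": REFERENCE_ENERGY_100G[cat],
            "added_sugar": REFERENCE_ADDED_SUGAR_100G[cat],
            "fiber": REFERENCE_FIBER_100G[cat],
            "trans_fat": (0.0, 0.0),
        }
        nutrients.update(_backsolve_nutrients(cat))
        categories[cat] = CategoryParams(
            n_products=n_per_category if n_per_category is not None else sum(counts),
            year_weights=tuple(float(c) for c in counts),
            nutrients=nutrients,
            serving_g=DEFAULT_SERVING_G[cat],
        )
    return SimConfig(categories=categories, seed=seed)


# ---------------------------------------------------------------------------
# naming templates (cue words match the shipped classification rule set)

_FRUITS = (
    "Apple", "Mango", "Strawberry", "Peach", "Pear", "Pineapple", "Banana",
    "Cherry", "Apricot", "Blueberry", "Cranberry", "Raspberry",
)

_NAME_TEMPLATES: dict[str, list[tuple[str, str, str]]] = {
    # (name template, description template, package type)
    "canned_fruit": [
        ("{fruit} Slices in Heavy Syrup", "Canned {fruit} slices preserved in syrup", "Can"),
        ("{fruit} Chunks in Light Syrup", "Canned {fruit} chunks in light syrup", "Can"),
        ("{fruit} Fruit Cup in Water", "Cut {fruit} in salt water", "Cup"),
    ],
    "canned_fruit_with_juice": [
        ("{fruit} Slices in Juice", "{fruit} slices packed in 100% juice", "Can"),
        ("{fruit} Chunks in Pear Juice", "Cut {fruit} preserved in pear juice", "Cup"),
        ("{fruit} Halves in 100% Juice", "{fruit} halves in fruit juice", "Can"),
    ],
    "dried_fruit": [
        ("Dried {fruit}", "Shelf-stable dehydrated {fruit}, nothing added", "Bag"),
        ("Freeze-Dried {fruit}", "Dehydrated {fruit} pieces", "Pouch Bag"),
        ("Sun-Dried {fruit}", "Dried {fruit} with no additives", "Bag"),
    ],
    "dried_flavored_fruit": [
        ("Sweetened Dried {fruit}", "Dried {fruit} with added cane sugar", "Bag"),
        ("Yogurt Coated Dried {fruit}", "Dried {fruit} with a yogurt coating", "Bag"),
        ("Chili Dried {fruit}", "Dried {fruit} dusted with chili seasoning", "Bag"),
    ],
    "formed_fruit": [
        ("{fruit} Fruit Leather", "Pressed {fruit} snack made from fruit", "Wrapper"),
        ("{fruit} Fruit Roll", "Rolled {fruit} snack, all fruit ingredients", "Wrapper"),
        ("{fruit} Fruit Strips", "{fruit} strips made from whole fruit", "Box"),
        ("{fruit} Fruit Twists", "Twisted {fruit} snack", "Wrapper"),
    ],
    "fruit_chips": [
        ("{fruit} Chips", "Real {fruit} in a chip format", "Bag"),
        ("Crispy {fruit} Chips", "Crunchy chips made from real {fruit}", "Bag"),
    ],
    "fruit_based_bar": [
        ("{fruit} & Oat Bar", "Chewy bar with {fruit}, oats and nuts", "Wrapper"),
        ("{fruit} Nut Bar", "Fruit and nut bar with {fruit} pieces", "Wrapper"),
    ],
    "fruit_puree": [
        ("{fruit} Puree", "Smooth {fruit} puree snack", "Pouch"),
        ("Organic {fruit} Applesauce", "{fruit} apple sauce blend", "Pouch"),
        ("{fruit} Smoothie", "Blended {fruit} smoothie snack", "Pouch"),
    ],
    "fruit_flavored_snack": [
        ("{fruit} Gummies", "Chewy gummies made with real fruit flavor", "Bag"),
        ("{fruit} Fruit Snacks", "Fruit snacks with fruit flavor and cane sugar", "Box"),
    ],
}

_INGREDIENTS: dict[str, str] = {
    "canned_fruit": "{lfruit}, water, sugar, citric acid",
    "canned_fruit_with_juice": "{lfruit}, {lfruit} juice, ascorbic acid",
    "dried_fruit": "{lfruit}",
    "dried_flavored_fruit": "{lfruit}, cane sugar, sunflower oil, natural flavor",
    "formed_fruit": "{lfruit} puree, apple puree, lemon juice concentrate",
    "fruit_chips": "{lfruit}, coconut oil, sea salt",
    "fruit_based_bar": "dates, almonds, oats, {lfruit} puree, honey",
    "fruit_puree": "{lfruit} puree, apple juice concentrate, vitamin c",
    "fruit_flavored_snack": "corn syrup, sugar, {lfruit} juice concentrate, gelatin, citric acid",
}

_CLAIM_POOL = ("Gluten Free", "Organic", "No Artificial Colors", "Good Source of Fiber", "Kosher")

_OUT_OF_SCOPE_NAMES = (
    "Chocolate Sandwich Cookies", "Salted Caramel Popcorn", "Cheese Crackers",
    "Granola Bar", "Potato Chips", "Vanilla Wafer Cookies", "Sea Salt Pretzels",
    "Milk Chocolate Bar", "Onion Rings", "Cheddar Snack Mix",
)

_PANEL_NUTRIENTS = (
    "energy", "saturated_fat", "trans_fat", "cholesterol", "sodium",
    "total_sugar", "added_sugar", "fiber", "protein", "potassium",
    "vitamin_d", "calcium", "iron",
)

_REQUIRED = ("added_sugar", "vitamin_d", "calcium", "iron")


# ---------------------------------------------------------------------------
# generation

def _round_sig(x: float, digits: int = 6) -> float:
    return float(f"{x:.{digits}g}")


def generate(config: SimConfig) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Generate a market snapshot and its hidden truth table.

    Returns the (shuffled) record list and a truth table with one row per
    emitted record: true category, role, and pre-coding per-100 g values for
    energy, added sugar and fiber.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ProductRecord] = []
    truth_rows: list[dict] = []
    next_id = iter(range(1, 10**7))

    def new_id() -> str:
        return f"R{next(next_id):06d}"

    for cat in CATEGORIES:
        if cat not in config.categories:
            continue
        params = config.categories[cat]
        n = params.n_products
        if n == 0:
            continue

        draws = {
            nutrient: stratified_draw(matched_positive(m, s), n, rng)
            for nutrient, (m, s) in params.nutrients.items()
        }
        # natural (non-added) sugar, only feeds the unscored total-sugar cell
        nat_mean = 0.1 * params.nutrients["energy"][0] / 4.0
        natural = stratified_draw(matched_positive(nat_mean, 0.3 * nat_mean), n, rng) if nat_mean > 0 else np.zeros(n)
        serving = np.clip(
            np.round(rng.normal(params.serving_g[0], params.serving_g[1], size=n)),
            10.0, None,
        )
        weights = np.asarray(params.year_weights, dtype=float)
        years = rng.choice(YEARS, size=n, p=weights / weights.sum())

        for i in range(n):
            fruit = _FRUITS[rng.integers(len(_FRUITS))]
            name_t, desc_t, package = _NAME_TEMPLATES[cat][rng.integers(len(_NAME_TEMPLATES[cat]))]
            per100g = {nu: draws[nu][i] for nu in draws}
            per100g["total_sugar"] = per100g["added_sugar"] + natural[i]
            record = _make_record(
                new_id(),
                name=name_t.format(fruit=fruit),
                brand=f"Brand {chr(65 + int(rng.integers(26)))}{int(rng.integers(100)):02d}",
                description=desc_t.format(fruit=fruit),
                package=package,
                ingredients=_INGREDIENTS[cat].format(lfruit=fruit.lower()),
                claims=[c for c in _CLAIM_POOL if rng.uniform() < 0.15],
                year=int(years[i]),
                rng=rng,
                per100g=per100g,
                serving_g=float(serving[i]),
            )
            siblings = [record]
            if rng.uniform() < config.p_dual_label:
                # two printed panels of the same product: jitter both
                _jitter_panel(record, rng)
                twin = record.copy()
                twin.record_id = new_id()
                _jitter_panel(twin, rng)
                siblings.append(twin)
            for j, sib in enumerate(siblings):
                _inject_coding(sib, config, rng)
                records.append(sib)
                truth_rows.append(_truth_row(sib, cat, "dual_sibling" if j else "core", per100g, float(serving[i])))
                if rng.uniform() < config.p_duplicate:
                    dup = sib.copy()  # exact duplicate row, same record id
                    records.append(dup)
                    truth_rows.append(_truth_row(dup, cat, "duplicate", per100g, float(serving[i])))

    n_core = len(records)
    n_out = int(round(config.frac_out_of_scope * n_core))
    for _ in range(n_out):
        name = _OUT_OF_SCOPE_NAMES[rng.integers(len(_OUT_OF_SCOPE_NAMES))]
        r = _make_record(
            new_id(), name=name, brand="Brand X00", description="", package="Bag",
            ingredients="", claims=[], year=int(rng.choice(YEARS)), rng=rng,
            per100g={"energy": 450.0, "added_sugar": 20.0, "fiber": 1.0,
                     "saturated_fat": 5.0, "trans_fat": 0.0, "cholesterol": 0.0,
                     "sodium": 300.0, "total_sugar": 25.0, "protein": 5.0,
                     "potassium": 100.0, "vitamin_d": 0.0, "calcium": 20.0, "iron": 1.0},
            serving_g=30.0,
        )
        records.append(r)
        truth_rows.append(_truth_row(r, None, "out_of_scope", {}, 30.0))

    n_nolabel = int(round(config.frac_no_label * n_core))
    in_scope_cats = [c for c in CATEGORIES if config.categories.get(c) and config.categories[c].n_products > 0]
    for _ in range(n_nolabel):
        cat = in_scope_cats[rng.integers(len(in_scope_cats))]
        fruit = _FRUITS[rng.integers(len(_FRUITS))]
        name_t, desc_t, package = _NAME_TEMPLATES[cat][0]
        r = ProductRecord(
            record_id=new_id(),
            name=name_t.format(fruit=fruit),
            brand="Brand N00",
            description=desc_t.format(fruit=fruit),
            package_type=package,
            launch_date=date(int(rng.choice(YEARS)), int(rng.integers(1, 13)), int(rng.integers(1, 29))),
            serving_g=None,
            panel={},  # entirely missing: no nutrition label
        )
        records.append(r)
        truth_rows.append(_truth_row(r, cat, "no_label", {}, None))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return records, truth


def _truth_row(record: ProductRecord, category: str | None, role: str,
               per100g: dict, serving_g: float | None) -> dict:
    return {
        "record_id": record.record_id,
        "true_category": category,
        "role": role,
        "energy_100g": per100g.get("energy", np.nan),
        "added_sugar_100g": per100g.get("added_sugar", np.nan),
        "fiber_100g": per100g.get("fiber", np.nan),
        "serving_g": serving_g,
    }


def _make_record(
    record_id: str, *, name: str, brand: str, description: str, package: str,
    ingredients: str, claims: list[str], year: int, rng: np.random.Generator,
    per100g: dict[str, float], serving_g: float,
) -> ProductRecord:
    launch = date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
    panel: dict[str, CodedValue] = {}
    for nutrient in _PANEL_NUTRIENTS:
        per_serving = _round_sig(per100g[nutrient] * serving_g / 100.0)
        panel[nutrient] = CodedValue.numeric(per_serving)
    record = ProductRecord(
        record_id=record_id,
        name=name,
        brand=brand,
        description=description,
        launch_date=launch,
        storage_type="Shelf stable",
        package_type=package,
        claims=claims,
        ingredients=ingredients,
        serving_size_text=f"{format_number(serving_g)} g",
        serving_g=serving_g,
        panel=panel,
    )
    # labels commonly print the fiber %DV; kept for censored-cell recovery
    fiber_serv = record.numeric("fiber")
    record.percent_dv["fiber"] = float(round(fiber_serv / 28.0 * 100.0))
    return record


def _jitter_panel(record: ProductRecord, rng: np.random.Generator) -> None:
    """Symmetric +/-4% panel jitter emulating two printings of one label."""
    for nutrient, cv in record.panel.items():
        if cv.is_numeric and cv.value > 0:
            record.panel[nutrient] = CodedValue.numeric(_round_sig(cv.value * (1.0 + rng.uniform(-0.04, 0.04))))
    record.percent_dv["fiber"] = float(round(record.numeric("fiber") / 28.0 * 100.0))


def _inject_coding(record: ProductRecord, config: SimConfig, rng: np.random.Generator) -> None:
    """Apply label coding artifacts: "<x" codes and missing required cells."""
    if rng.uniform() < config.p_censored_fiber:
        record.panel["fiber"] = CodedValue.censored(1.0, "<1")
        # printed %DV already present; it is what imputation will invert
    if rng.uniform() < config.p_censored_small:
        if record.panel["saturated_fat"].is_numeric and record.numeric("saturated_fat") < 0.1:
            record.panel["saturated_fat"] = CodedValue.censored(0.1, "<0.1")
        if record.panel["sodium"].is_numeric and record.numeric("sodium") < 5.0:
            record.panel["sodium"] = CodedValue.censored(5.0, "<5")
        if record.panel["cholesterol"].is_numeric and record.numeric("cholesterol") < 5.0:
            record.panel["cholesterol"] = CodedValue.censored(5.0, "<5")
        if record.panel["protein"].is_numeric and record.numeric("protein") < 1.0:
            record.panel["protein"] = CodedValue.censored(1.0, "<1")
    if rng.uniform() < config.p_missing_required:
        nutrient = _REQUIRED[rng.integers(len(_REQUIRED))]
        record.panel[nutrient] = CodedValue.missing()
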