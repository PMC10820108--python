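"""Label-data cleaning: deduplication, dual-label averaging, censored-value
imputation, completeness screening, serving-size normalization.

The rules mirror common practice for label-transcribed nutrient panels:
"<1" fiber is back-calculated from the printed %DV against the 28 g daily
value (falling back to half the bound when no %DV is printed), "<0.1 g"
saturated fat is taken at 0.1 g, "<5 mg" sodium/cholesterol at 5 mg, and
"<1 g" protein at 0.75 g.  Any other "<x" code is imputed at x/2 and logged.
Products missing any of the newly mandated label nutrients (added sugar,
vitamin D, calcium, iron) are excluded, since their panels predate the
current label and cannot be scored on its basis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from .gnpd_io import (
    CodedValue,
    ExclusionLedger,
    ProductRecord,
)

logger = logging.getLogger(__name__)

_BOUND_TOL = 1e-9


@dataclass
class CleaningConfig:
    """Imputation constants and screening keys.

    fiber_dv_g is the daily value used to invert a printed fiber %DV; the
    substitution constants are the values entered for the enumerated "<x"
    label codes.
    """

    fiber_dv_g: float = 28.0
    protein_sub_g: float = 0.75
    satfat_sub_g: float = 0.1
    sodium_sub_mg: float = 5.0
    cholesterol_sub_mg: float = 5.0
    required_nutrients: tuple[str, ...] = ("added_sugar", "vitamin_d", "calcium", "iron")
    duplicate_key: tuple[str, ...] = ("record_id",)
    dual_label_key: tuple[str, ...] = ("brand", "name", "launch_date")
    second_pass_key: tuple[str, ...] = ("brand", "name", "serving_g")

    def __post_init__(self) -> None:
        for name in ("fiber_dv_g", "protein_sub_g", "satfat_sub_g", "sodium_sub_mg", "cholesterol_sub_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.required_nutrients:
            raise ValueError("required_nutrients must be non-empty")


def _key_of(record: ProductRecord, fields: Sequence[str]) -> tuple:
    return tuple(getattr(record, f) for f in fields)


def dedupe(
    records: Sequence[ProductRecord],
    key: Sequence[str] = ("record_id",),
) -> tuple[list[ProductRecord], int]:
    """Drop repeated entries, keeping the first occurrence in file order."""
    seen: set[tuple] = set()
    kept: list[ProductRecord] = []
    for r in records:
        k = _key_of(r, key)
        if k in seen:
            continue
        seen.add(k)
        kept.append(r)
    return kept, len(records) - len(kept)


def average_dual_labels(group: Sequence[ProductRecord]) -> ProductRecord:
    """Collapse multiple printed panels of one product into their mean.

    Each numeric nutrient becomes the arithmetic mean across panels; a
    nutrient missing (or still censored) on any panel is missing in the
    result.  Metadata comes from the first record.
    """
    if not group:
        raise ValueError("empty dual-label group")
    if len(group) == 1:
        return group[0]
    out = group[0].copy()
    for nutrient in out.panel:
        cells = [r.panel[nutrient] for r in group]
        if all(c.is_numeric for c in cells):
            mean = sum(c.value for c in cells) / len(cells)
            out.panel[nutrient] = CodedValue.numeric(mean)
        elif any(c.is_missing for c in cells):
            out.panel[nutrient] = CodedValue.missing()
        # censored on some panel, numeric/censored elsewhere: keep first cell
    return out


def collapse_dual_labels(
    records: Sequence[ProductRecord],
    key: Sequence[str] = ("brand", "name", "launch_date"),
) -> tuple[list[ProductRecord], int]:
    """Group records sharing one product identity and average each group."""
    groups: dict[tuple, list[ProductRecord]] = {}
    order: list[tuple] = []
    for r in records:
        k = _key_of(r, key)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)
    out = [average_dual_labels(groups[k]) for k in order]
    return out, len(records) - len(out)


def impute_censored(record: ProductRecord, config: CleaningConfig | None = None) -> ProductRecord:
    """Replace enumerated "<x" codes with their conventional estimates.

    Total: numeric cells are untouched, missing cells stay missing, and every
    censored cell resolves to a number.
    """
    config = config or CleaningConfig()
    out = record.copy()
    for nutrient, cv in out.panel.items():
        if not cv.is_censored:
            continue
        b = cv.bound
        if nutrient == "fiber" and abs(b - 1.0) < _BOUND_TOL:
            pct = out.percent_dv.get("fiber")
            value = pct / 100.0 * config.fiber_dv_g if pct is not None else b / 2.0
        elif nutrient == "saturated_fat" and abs(b - 0.1) < _BOUND_TOL:
            value = config.satfat_sub_g
        elif nutrient == "sodium" and abs(b - 5.0) < _BOUND_TOL:
            value = config.sodium_sub_mg
        elif nutrient == "cholesterol" and abs(b - 5.0) < _BOUND_TOL:
            value = config.cholesterol_sub_mg
        elif nutrient == "protein" and abs(b - 1.0) < _BOUND_TOL:
            value = config.protein_sub_g
        else:
            value = b / 2.0
            logger.info(
                "record %s: unenumerated censored %s cell %r imputed at bound/2 = %s",
                out.record_id, nutrient, cv.raw_text, value,
            )
        out.panel[nutrient] = CodedValue.numeric(value, raw_text=cv.raw_text)
    return out


def filter_complete(
    records: Sequence[ProductRecord],
    config: CleaningConfig | None = None,
) -> tuple[list[ProductRecord], int]:
    """Drop records with any required nutrient still missing (zero is a value)."""
    config = config or CleaningConfig()
    kept = [
        r
        for r in records
        if all(not r.panel[n].is_missing for n in config.required_nutrients)
    ]
    return kept, len(records) - len(kept)


def filter_labeled(records: Sequence[ProductRecord]) -> tuple[list[ProductRecord], int]:
    """Drop records whose entire panel is missing (no nutrition label)."""
    kept = [r for r in records if r.has_label()]
    return kept, len(records) - len(kept)


_SERVING_G_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(?:g|grams?)\b", re.IGNORECASE)


def normalize_serving(record: ProductRecord) -> ProductRecord | None:
    """Ensure ``serving_g`` holds the serving mass in grams.

    Returns the (possibly updated) record, or None when no gram measure can
    be recovered — the caller excludes such records with a ledger reason.
    """
    if record.serving_g is not None and record.serving_g > 0:
        return record
    m = _SERVING_G_RE.search(record.serving_size_text or "")
    if m:
        out = record.copy()
        out.serving_g = float(m.group(1))
        return out
    logger.info("record %s: serving size %r not expressible in grams", record.record_id, record.serving_size_text)
    return None


@dataclass
class CleaningResult:
    records: list[ProductRecord]
    ledger: ExclusionLedger
    excluded_serving: list[ProductRecord] = field(default_factory=list)


def clean(
    records: Sequence[ProductRecord],
    config: CleaningConfig | None = None,
    ledger: ExclusionLedger | None = None,
) -> CleaningResult:
    """Full cleaning pass in screening order.

    Steps: no-label screen, exact-duplicate removal, dual-label averaging,
    second-pass duplicate removal, censored-value imputation, completeness
    screen, serving normalization.  Each removal is recorded in the ledger.
    The pass is idempotent: cleaning cleaned output changes nothing.
    """
    config = config or CleaningConfig()
    ledger = ledger if ledger is not None else ExclusionLedger(len(records))

    recs, n_nolabel = filter_labeled(records)
    ledger.record("no_nutrition_label", n_nolabel)

    recs, n_dup = dedupe(recs, config.duplicate_key)
    recs, n_dual = collapse_dual_labels(recs, config.dual_label_key)
    recs, n_dup2 = dedupe(recs, config.second_pass_key)
    ledger.record("duplicate", n_dup + n_dual + n_dup2)

    recs = [impute_censored(r, config) for r in recs]

    recs, n_incomplete = filter_complete(recs, config)
    ledger.record("missing_new_label_nutrients", n_incomplete)

    kept: list[ProductRecord] = []
    dropped: list[ProductRecord] = []
    for r in recs:
        nr = normalize_serving(r)
        (kept if nr is not None else dropped).append(nr if nr is not None else r)
    ledger.record("unparseable_serving", len(dropped))

    ledger.check_conservation()
    return CleaningResult(records=kept, ledger=ledger, excluded_serving=dropped)
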